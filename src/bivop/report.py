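"""Estimation-table rendering.

Reproduces the layout of the published results table: per-equation blocks
(front vehicle first) with coefficient, significance stars, standard
error, z value and — for random coefficients only — the share of the
population with a positive / negative effect, followed by the thresholds,
the correlation parameter and the final log-likelihood.  Coefficients are
printed with 4 decimals, z values and percents with 2.
"""

from __future__ import annotations

import io
import json

from .estimation import FitResult
from .model import FRONT, REAR, EQUATION_NAMES

__all__ = ["significance_stars", "render_report"]


def significance_stars(p: float | None) -> str:
    """***, **, * at the 1%, 5% and 10% two-sided levels."""
    if p is None:
        return ""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


_HEAD = ("Variable", "Coefficient", "Std.Error", "Z Value",
         "Above 0", "Below 0")


def _row(fit: FitResult, label: str, display: str,
         percent_label: str | None = None) -> tuple:
    info = fit[label]
    coef = f"{info['estimate']:.4f}{significance_stars(info['p'])}"
    se = "—" if info["se"] is None else f"{info['se']:.4f}"
    z = "—" if info["z"] is None else f"{info['z']:.2f}"
    if percent_label is not None and percent_label in fit.percent_obs:
        above, below = fit.percent_obs[percent_label]
        pa, pb = f"{above:.2f}%", f"{below:.2f}%"
    else:
        pa = pb = "—"
    return (display, coef, se, z, pa, pb)


def _block_rows(fit: FitResult, j: int) -> list[tuple]:
    eq = EQUATION_NAMES[j]
    spec = fit.spec
    rows = [(f"Driver in the {eq} vehicle",)]
    for name in spec.coef_names(j):
        label = f"{eq}:{name}"
        display = "Constant" if name == "const" else name
        is_random = f"{eq}:sd({name})" in fit.names
        rows.append(_row(fit, label, display,
                         percent_label=label if is_random else None))
        if is_random:
            rows.append(_row(fit, f"{eq}:sd({name})", "  Standard deviation"))
    first = 1 if spec.include_constant[j] else 0
    for c in range(first, spec.n_categories[j] - 1):
        rows.append(_row(fit, f"{eq}:mu_{c}", f"mu_{c}"))
    return rows


def _all_rows(fit: FitResult) -> list[tuple]:
    # front block first, mirroring the published table
    rows = _block_rows(fit, FRONT) + _block_rows(fit, REAR)
    rows.append(_row(fit, "rho", "rho (correlation parameter)"))
    rows.append(("Final log-likelihood", f"{fit.loglik:.1f}", "", "", "", ""))
    return rows


def _diagnostics(fit: FitResult) -> list[str]:
    lines = [f"n = {fit.n_obs} crashes; iterations = {fit.n_iter}; "
             f"converged = {fit.converged}"]
    if fit.draw_config.get("R"):
        lines.append(f"Halton draws R = {fit.draw_config['R']} "
                     f"(seed {fit.draw_config['seed']})")
    if fit.clamp_count:
        lines.append(f"warning: {fit.clamp_count} clamped cell probabilities")
    if not fit.converged:
        lines.append(f"NOT CONVERGED: {fit.message}")
    return lines


def render_report(fit: FitResult, format: str = "text") -> str:
    """Render a fitted model as ``text``, ``tsv`` or ``json``.

    The JSON form carries unrounded numbers and parses back to the same
    values; the text/tsv forms follow the published table layout.  A fit
    that did not converge renders its diagnostics block first.
    """
    if format == "json":
        payload = {
            "estimates": {
                name: {"estimate": float(fit.estimates[i]),
                       "se": None if fit.se is None else float(fit.se[i]),
                       "z": None if fit.z is None else float(fit.z[i]),
                       "p": None if fit.p is None else float(fit.p[i]),
                       "stars": significance_stars(
                           None if fit.p is None else float(fit.p[i]))}
                for i, name in enumerate(fit.names)},
            "percent_observations": {k: list(v)
                                     for k, v in fit.percent_obs.items()},
            "loglik": fit.loglik,
            "converged": fit.converged,
            "n_obs": fit.n_obs,
            "n_iter": fit.n_iter,
            "draw_config": fit.draw_config,
            "message": fit.message,
        }
        return json.dumps(payload, indent=1)
    rows = _all_rows(fit)
    if format == "tsv":
        out = io.StringIO()
        if not fit.converged:
            for line in _diagnostics(fit):
                out.write(f"# {line}\n")
        out.write("\t".join(_HEAD) + "\n")
        for r in rows:
            out.write("\t".join(r) + "\n")
        return out.getvalue()
    if format != "text":
        raise ValueError(f"unknown report format {format!r}")
    widths = [36, 14, 10, 8, 9, 9]
    out = io.StringIO()
    for line in _diagnostics(fit):
        out.write(line + "\n")
    out.write("\n")
    fmt = "".join(f"{{:<{w}}}" if i == 0 else f"{{:>{w}}}"
                  for i, w in enumerate(widths))
    out.write(fmt.format(*_HEAD) + "\n")
    out.write("-" * sum(widths) + "\n")
    for r in rows:
        if len(r) == 1:
            out.write(f"== {r[0]} ==\n")
        else:
            out.write(fmt.format(*r) + "\n")
    out.write("Note: ***, **, * mean significance at 1%, 5%, 10% level\n")
    return out.getvalue()
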