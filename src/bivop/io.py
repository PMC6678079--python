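"""Data ingestion and fit serialisation.

Flat-table convention: one CSV row per crash; ``injury__rear`` /
``injury__front`` hold 1-based severity levels (L1..LK); dummy covariates
are ``<name>`` when shared by both drivers and ``<name>__rear`` /
``<name>__front`` when driver-specific.  Police-reported severities on the
KABCO scale are regrouped to four levels before modelling: O -> L1,
C -> L2, B -> L3, A and K -> L4 (fatalities and incapacitating injuries
are pooled because both are rare).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import FitResult
from .model import (FRONT, REAR, EQUATION_NAMES, CrashRecord, ModelSpec,
                    Parameters)
from .synthetic import resolve_column

__all__ = [
    "KABCO_TO_LEVEL",
    "regroup_kabco",
    "dummy_encode",
    "read_crash_csv",
    "write_crash_csv",
    "load_model_config",
    "fit_to_dict",
    "fit_from_dict",
    "ReadReport",
    "SchemaError",
]

log = logging.getLogger("bivop")

KABCO_TO_LEVEL = {"O": 0, "C": 1, "B": 2, "A": 3, "K": 3}

OUTCOME_COLUMNS = ("injury__rear", "injury__front")


class SchemaError(ValueError):
    """The file or configuration does not match the declared model."""


def regroup_kabco(code: str, row_id=None) -> int:
    """Map a KABCO severity code to the regrouped 0-based level L1-L4.

    Codes outside {O, C, B, A, K} (e.g. "injured, severity unknown") are
    rejected; such crashes are excluded from analysis.
    """
    try:
        return KABCO_TO_LEVEL[code]
    except (KeyError, TypeError):
        where = "" if row_id is None else f" (row {row_id})"
        raise ValueError(f"unknown KABCO code {code!r}{where}") from None


def dummy_encode(column: pd.Series, reference_level,
                 levels=None) -> pd.DataFrame:
    """0/1 dummy columns for every non-reference level of a categorical.

    ``levels`` fixes the admissible categories (training-time vocabulary);
    values outside it raise, which catches unseen levels at predict time.
    Exactly one of the emitted dummies, or the implicit reference, is
    active per row.
    """
    col = pd.Series(column)
    observed = pd.unique(col.dropna())
    if levels is None:
        levels = list(observed)
        if len(levels) < 2:
            raise ValueError("need at least 2 observed levels to dummy-code")
    unseen = set(observed) - set(levels)
    if unseen:
        raise ValueError(f"unseen level(s) {sorted(map(str, unseen))} not in "
                         f"declared levels {sorted(map(str, levels))}")
    if reference_level not in levels:
        raise ValueError(f"reference level {reference_level!r} not among "
                         f"levels {levels}")
    name = col.name if col.name is not None else "var"
    out = {}
    for lev in levels:
        if lev == reference_level:
            continue
        out[f"{name}__{lev}"] = (col == lev).astype(float)
    return pd.DataFrame(out, index=col.index)


@dataclass
class ReadReport:
    """Row bookkeeping of one CSV ingestion."""

    n_read: int
    n_kept: int
    drop_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return self.n_read - self.n_kept


def read_crash_csv(path, spec: ModelSpec,
                   outcome_columns: tuple[str, str] = OUTCOME_COLUMNS
                   ) -> tuple[list[CrashRecord], ReadReport]:
    """Read a flat crash table into validated :class:`CrashRecord` objects.

    Missing columns raise :class:`SchemaError`; malformed rows (missing
    values, outcomes outside 1..K, dummies not 0/1) are dropped with
    per-reason counts surfaced in the returned :class:`ReadReport` and via
    the package logger.  Row order is preserved.
    """
    df = pd.read_csv(path)
    needed = list(outcome_columns)
    cols_per_eq = []
    for j in (REAR, FRONT):
        try:
            cols = [resolve_column(df, nm, j) for nm in spec.covariates[j]]
        except KeyError as exc:
            raise SchemaError(str(exc)) from None
        cols_per_eq.append(cols)
        needed.extend(cols)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    n_read = len(df)
    reasons: dict[str, int] = {}

    def drop(mask: np.ndarray, reason: str):
        k = int(mask.sum())
        if k:
            reasons[reason] = reasons.get(reason, 0) + k
        return mask

    used = sorted(set(needed))
    num = df[used].apply(pd.to_numeric, errors="coerce")
    bad = drop(num.isna().any(axis=1).to_numpy(), "missing or non-numeric value")
    for j, col in enumerate(outcome_columns):
        K = spec.n_categories[j]
        vals = num[col].to_numpy()
        with np.errstate(invalid="ignore"):
            out_of_range = (~np.isnan(vals)) & (
                (vals < 1) | (vals > K) | (vals != np.round(vals)))
        bad |= drop(out_of_range & ~bad,
                    f"{col} outside 1..{K}")
    dummy_cols = sorted(set(cols_per_eq[0]) | set(cols_per_eq[1]))
    dvals = num[dummy_cols].to_numpy()
    with np.errstate(invalid="ignore"):
        not01 = np.nansum((dvals != 0) & (dvals != 1), axis=1) > 0
    bad |= drop(not01 & ~bad, "dummy covariate not 0/1")
    keep = ~bad
    kept = num.loc[keep]
    ids = (df.loc[keep, "crash_id"].to_numpy()
           if "crash_id" in df.columns else df.index[keep].to_numpy())
    X1 = kept[cols_per_eq[REAR]].to_numpy(dtype=float)
    X2 = kept[cols_per_eq[FRONT]].to_numpy(dtype=float)
    y1 = kept[outcome_columns[REAR]].to_numpy(dtype=int) - 1
    y2 = kept[outcome_columns[FRONT]].to_numpy(dtype=int) - 1
    records = [CrashRecord(ids[i], int(y1[i]), int(y2[i]),
                           X1[i].copy(), X2[i].copy())
               for i in range(len(kept))]
    report = ReadReport(n_read=n_read, n_kept=len(records),
                        drop_reasons=reasons)
    if report.n_dropped:
        log.warning("dropped %d of %d rows: %s", report.n_dropped, n_read,
                    reasons)
    log.info("read %d crash records from %s", report.n_kept, path)
    return records, report


def write_crash_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_model_config(path) -> tuple[ModelSpec, tuple[str, str]]:
    """Build a :class:`ModelSpec` from a YAML model configuration.

    Layout::

        outcomes: {rear: injury__rear, front: injury__front, n_categories: 4}
        equations:
          rear:
            constant: {random: true}
            covariates:
              - {name: age_le24, random: true}
              - sex_male
          front: ...
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        out = cfg.get("outcomes", {})
        ncat = int(out.get("n_categories", 4))
        outcome_cols = (out.get("rear", OUTCOME_COLUMNS[0]),
                        out.get("front", OUTCOME_COLUMNS[1]))
        covs, flags, consts = [], [], []
        for eq in EQUATION_NAMES:
            block = cfg["equations"][eq]
            names, rand = [], []
            for item in block.get("covariates", []):
                if isinstance(item, str):
                    names.append(item)
                    rand.append(False)
                else:
                    names.append(item["name"])
                    rand.append(bool(item.get("random", False)))
            const_cfg = block.get("constant", {})
            include = (const_cfg is not False)
            const_rand = bool(const_cfg.get("random", False)) if include else False
            covs.append(tuple(names))
            flags.append(((const_rand,) if include else ()) + tuple(rand))
            consts.append(include)
        spec = ModelSpec(covariates=tuple(covs),
                         n_categories=(ncat, ncat),
                         random_flags=tuple(flags),
                         include_constant=tuple(consts))
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"invalid model configuration {path}: {exc}") from None
    return spec, outcome_cols


# ---------------------------------------------------------------------------
# fit artifact serialisation


def _spec_to_dict(spec: ModelSpec) -> dict:
    return {"covariates": [list(c) for c in spec.covariates],
            "n_categories": list(spec.n_categories),
            "random_flags": [list(f) for f in spec.random_flags],
            "include_constant": list(spec.include_constant)}


def _spec_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(covariates=tuple(tuple(c) for c in d["covariates"]),
                     n_categories=tuple(d["n_categories"]),
                     random_flags=tuple(tuple(f) for f in d["random_flags"]),
                     include_constant=tuple(d["include_constant"]))


def fit_to_dict(fit: FitResult) -> dict:
    arr = lambda a: None if a is None else np.asarray(a).tolist()
    return {
        "spec": _spec_to_dict(fit.spec),
        "theta": arr(fit.theta),
        "names": list(fit.names),
        "estimates": arr(fit.estimates),
        "se": arr(fit.se),
        "z": arr(fit.z),
        "p": arr(fit.p),
        "percent_obs": {k: list(v) for k, v in fit.percent_obs.items()},
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "n_obs": fit.n_obs,
        "clamp_count": fit.clamp_count,
        "draw_config": fit.draw_config,
        "message": fit.message,
        "params": {"beta": [b.tolist() for b in fit.params.beta],
                   "sigma": [s.tolist() for s in fit.params.sigma],
                   "thresholds": [t.tolist() for t in fit.params.thresholds],
                   "rho": fit.params.rho},
    }


def fit_from_dict(d: dict) -> FitResult:
    arr = lambda a: None if a is None else np.asarray(a, dtype=float)
    pr = d["params"]
    params = Parameters(beta=tuple(np.asarray(b) for b in pr["beta"]),
                        thresholds=tuple(np.asarray(t) for t in pr["thresholds"]),
                        rho=pr["rho"],
                        sigma=tuple(np.asarray(s) for s in pr["sigma"]))
    return FitResult(
        spec=_spec_from_dict(d["spec"]), params=params,
        theta=arr(d["theta"]), names=tuple(d["names"]),
        estimates=arr(d["estimates"]), se=arr(d["se"]), z=arr(d["z"]),
        p=arr(d["p"]),
        percent_obs={k: tuple(v) for k, v in d["percent_obs"].items()},
        loglik=d["loglik"], converged=d["converged"], n_iter=d["n_iter"],
        n_obs=d["n_obs"], clamp_count=d["clamp_count"],
        draw_config=d["draw_config"], message=d.get("message", ""))


def save_fit(fit: FitResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_to_dict(fit), fh, indent=1)


def load_fit(path) -> FitResult:
    with open(path) as fh:
        return fit_from_dict(json.load(fh))
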