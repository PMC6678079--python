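"""Synthetic paired-outcome crash data with known ground truth.

The real estimation target of this package is a national crash-database
extract (car-car rear-end crashes, two drivers per crash) that cannot be
redistributed.  This module generates datasets with the same statistical
skeleton: ~15k crashes, dummy-coded covariates at the prevalences of the
published summary table, some covariates shared by both drivers of a crash
(light condition, region, season, hour), some driver-specific (age, sex,
airbag, belt, model year), and paired ordinal outcomes drawn from the
bivariate ordered probit latent model with normally distributed random
coefficients.

Two fixtures package the published tables: the 4x4 joint severity
contingency table, and the published coefficient estimates as a
ground-truth parameter set for realistic simulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (FRONT, REAR, EQUATION_NAMES, CrashRecord, ModelSpec,
                    Parameters)

__all__ = [
    "Covariate",
    "CovariateScheme",
    "TruthManifest",
    "generate_covariates",
    "simulate_outcomes",
    "simulate_dataset",
    "table1_fixture",
    "table3_truth_fixture",
    "recovery_truth_fixture",
    "default_scheme",
]

N_CRASHES_REFERENCE = 15159  # crashes in the source extract
N_DRIVERS_REFERENCE = 2 * N_CRASHES_REFERENCE


class SchemeError(ValueError):
    pass


@dataclass(frozen=True)
class Covariate:
    """One dummy covariate of the generator.

    ``scope`` is ``"shared"`` (one draw per crash, copied to both drivers)
    or ``"driver"`` (independent draws per driver; ``prevalence`` may then
    be a ``(rear, front)`` pair).  Covariates sharing a ``group`` are
    mutually exclusive levels of one categorical variable and are drawn
    jointly; their prevalences must sum to at most 1.
    """

    name: str
    prevalence: float | tuple[float, float]
    scope: str = "driver"
    group: str | None = None

    def prev(self, j: int) -> float:
        if isinstance(self.prevalence, (tuple, list)):
            return float(self.prevalence[j])
        return float(self.prevalence)


@dataclass(frozen=True)
class CovariateScheme:
    covariates: tuple[Covariate, ...]
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise SchemeError("duplicate covariate names in scheme")
        for c in self.covariates:
            for j in (REAR, FRONT):
                if not 0.0 <= c.prev(j) <= 1.0:
                    raise SchemeError(f"prevalence of '{c.name}' outside [0, 1]")
        for gname, members in self.groups().items():
            for j in (REAR, FRONT):
                tot = sum(c.prev(j) for c in members)
                if tot > 1.0 + 1e-12:
                    raise SchemeError(
                        f"group '{gname}' prevalences sum to {tot:.4f} > 1")
            scopes = {c.scope for c in members}
            if len(scopes) > 1:
                raise SchemeError(f"group '{gname}' mixes scopes")

    def groups(self) -> dict[str, list[Covariate]]:
        out: dict[str, list[Covariate]] = {}
        for c in self.covariates:
            if c.group is not None:
                out.setdefault(c.group, []).append(c)
        return out

    def to_dict(self) -> dict:
        return {"seed": self.seed,
                "covariates": [asdict(c) for c in self.covariates]}

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateScheme":
        covs = []
        for c in d["covariates"]:
            prev = c["prevalence"]
            if isinstance(prev, list):
                prev = tuple(prev)
            covs.append(Covariate(c["name"], prev, c["scope"], c["group"]))
        return cls(tuple(covs), d["seed"])


def _draw_categorical(rng, n, probs):
    """Index draws for a group: members 0..m-1, reference level m."""
    edges = np.cumsum(probs)
    u = rng.random(n)
    return np.searchsorted(edges, u, side="right")


def generate_covariates(n: int, scheme: CovariateScheme,
                        seed: int | None = None) -> pd.DataFrame:
    """Draw an n-crash dummy covariate table.

    Shared covariates get a single column ``<name>``; driver-specific ones
    get ``<name>__rear`` and ``<name>__front``.  Deterministic given the
    seed (``scheme.seed`` unless overridden).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(scheme.seed if seed is None else seed)
    cols: dict[str, np.ndarray] = {}
    grouped = {c.name for g in scheme.groups().values() for c in g}
    for gname, members in sorted(scheme.groups().items()):
        shared = members[0].scope == "shared"
        roles = (None,) if shared else (REAR, FRONT)
        for role in roles:
            j = REAR if role is None else role
            idx = _draw_categorical(rng, n, [c.prev(j) for c in members])
            for m, cov in enumerate(members):
                suffix = "" if shared else f"__{EQUATION_NAMES[role]}"
                cols[cov.name + suffix] = (idx == m).astype(float)
    for cov in scheme.covariates:
        if cov.name in grouped:
            continue
        if cov.scope == "shared":
            cols[cov.name] = (rng.random(n) < cov.prev(REAR)).astype(float)
        else:
            for j in (REAR, FRONT):
                cols[f"{cov.name}__{EQUATION_NAMES[j]}"] = (
                    rng.random(n) < cov.prev(j)).astype(float)
    df = pd.DataFrame(cols)
    df.insert(0, "crash_id", np.arange(n))
    return df


def resolve_column(df: pd.DataFrame, name: str, j: int) -> str:
    """Column lookup honouring the shared / per-driver suffix convention."""
    suffixed = f"{name}__{EQUATION_NAMES[j]}"
    if suffixed in df.columns:
        return suffixed
    if name in df.columns:
        return name
    raise KeyError(f"covariate '{name}' ({EQUATION_NAMES[j]}) not found "
                   "in data columns")


@dataclass
class TruthManifest:
    """Everything needed to regenerate a simulated dataset bit-exactly."""

    params: Parameters
    spec: ModelSpec
    n_crashes: int
    seed: int
    scheme: CovariateScheme | None = None

    def to_dict(self) -> dict:
        return {
            "n_crashes": self.n_crashes,
            "seed": self.seed,
            "params": {
                "beta": [b.tolist() for b in self.params.beta],
                "sigma": [s.tolist() for s in self.params.sigma],
                "thresholds": [t.tolist() for t in self.params.thresholds],
                "rho": self.params.rho,
            },
            "spec": {
                "covariates": [list(c) for c in self.spec.covariates],
                "n_categories": list(self.spec.n_categories),
                "random_flags": [list(f) for f in self.spec.random_flags],
                "include_constant": list(self.spec.include_constant),
            },
            "scheme": None if self.scheme is None else self.scheme.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthManifest":
        spec = ModelSpec(
            covariates=tuple(tuple(c) for c in d["spec"]["covariates"]),
            n_categories=tuple(d["spec"]["n_categories"]),
            random_flags=tuple(tuple(f) for f in d["spec"]["random_flags"]),
            include_constant=tuple(d["spec"]["include_constant"]))
        pr = d["params"]
        params = Parameters(
            beta=tuple(np.asarray(b) for b in pr["beta"]),
            thresholds=tuple(np.asarray(t) for t in pr["thresholds"]),
            rho=pr["rho"],
            sigma=tuple(np.asarray(s) for s in pr["sigma"]))
        scheme = (None if d.get("scheme") is None
                  else CovariateScheme.from_dict(d["scheme"]))
        return cls(params, spec, d["n_crashes"], d["seed"], scheme)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def simulate_outcomes(covariates: pd.DataFrame, params: Parameters,
                      spec: ModelSpec, seed: int
                      ) -> tuple[list[CrashRecord], TruthManifest]:
    """Draw paired ordinal outcomes from the latent bivariate model.

    Per crash: coefficient heterogeneity is drawn for every coefficient
    (scaled by its SD, zero for fixed ones, so a zero-SD model reproduces
    the fixed-parameter generator draw for draw), the latent propensities
    are formed, correlated errors are added through the Cholesky factor of
    the correlation matrix, and the thresholds censor the latents into
    levels using half-open intervals ``mu_{c-1} < y* <= mu_c``.
    """
    params.validate(spec)
    n = len(covariates)
    rng = np.random.default_rng(seed)
    Xs = []
    for j in (REAR, FRONT):
        cols = [resolve_column(covariates, nm, j) for nm in spec.covariates[j]]
        X = covariates[cols].to_numpy(dtype=float)
        if spec.include_constant[j]:
            X = np.column_stack([np.ones(n), X])
        Xs.append(X)
    etas = []
    for j in (REAR, FRONT):
        gam = rng.standard_normal((n, spec.n_coefs(j))) * params.sigma[j]
        etas.append(Xs[j] @ params.beta[j] + np.einsum("ij,ij->i", Xs[j], gam))
    rho = params.rho
    z = rng.standard_normal((n, 2))
    eps1 = z[:, 0]
    eps2 = rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1]
    levels = []
    for j, eps in ((REAR, eps1), (FRONT, eps2)):
        ystar = etas[j] + eps
        levels.append(np.searchsorted(params.thresholds[j], ystar,
                                      side="left"))
    ids = (covariates["crash_id"].to_numpy()
           if "crash_id" in covariates.columns else np.arange(n))
    off = (1 if spec.include_constant[REAR] else 0,
           1 if spec.include_constant[FRONT] else 0)
    records = [
        CrashRecord(crash_id=ids[i],
                    outcome_rear=int(levels[REAR][i]),
                    outcome_front=int(levels[FRONT][i]),
                    x_rear=Xs[REAR][i, off[0]:].copy(),
                    x_front=Xs[FRONT][i, off[1]:].copy())
        for i in range(n)
    ]
    manifest = TruthManifest(params=params, spec=spec, n_crashes=n, seed=seed)
    return records, manifest


def simulate_dataset(n: int, spec: ModelSpec, params: Parameters,
                     scheme: CovariateScheme, seed: int
                     ) -> tuple[pd.DataFrame, list[CrashRecord], TruthManifest]:
    """Covariates + outcomes in one call; returns the flat table too.

    The flat table carries one row per crash with ``injury__rear`` /
    ``injury__front`` as 1-based severity levels (L1..LK) alongside the
    dummy covariates, which is also the CSV layout of :mod:`bivop.io`.
    """
    cov = generate_covariates(n, scheme, seed=seed)
    records, manifest = simulate_outcomes(cov, params, spec, seed=seed + 1)
    manifest.scheme = scheme
    df = cov.copy()
    df["injury__rear"] = [r.outcome_rear + 1 for r in records]
    df["injury__front"] = [r.outcome_front + 1 for r in records]
    return df, records, manifest


# ---------------------------------------------------------------------------
# published-table fixtures


@dataclass(frozen=True)
class Table1:
    """Joint severity contingency table (front level rows, rear columns)."""

    counts: np.ndarray

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def front_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def rear_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def injured_share(self, equation: str) -> float:
        """Share of drivers above L1 (possible injury or worse)."""
        tot = (self.front_totals() if equation == "front"
               else self.rear_totals())
        return float(tot[1:].sum() / tot.sum())

    def expand_to_outcome_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """One (rear level, front level) pair per crash, 0-based."""
        rear, front = [], []
        K, L = self.counts.shape
        for f in range(K):
            for r in range(L):
                c = int(self.counts[f, r])
                rear.extend([r] * c)
                front.extend([f] * c)
        return np.asarray(rear), np.asarray(front)


def table1_fixture() -> Table1:
    """The published 4x4 joint injury-severity counts (15,159 crashes)."""
    counts = np.array([
        [8723, 576, 585, 209],   # front L1
        [1683, 548, 220, 80],    # front L2
        [1374, 188, 264, 47],    # front L3
        [437, 60, 59, 106],      # front L4
    ])
    return Table1(counts)


_FRONT_ROWS = [
    # name, mean, sd (0 -> fixed coefficient)
    ("age_le24", -0.3182, 0.1657),
    ("sex_male", -0.4426, 0.5292),
    ("airbag_undeployed", 0.8767, 0.2692),
    ("belt_unused", 0.5594, 0.0),
    ("speed_related", -0.3872, 0.0),
    ("mdlyr_2001_2005", -0.1392, 0.0945),
    ("mdlyr_2006_2010", -0.3648, 0.1559),
    ("mdlyr_2011_2015", -0.3569, 0.1255),
    ("bodytype_4door", 0.0839, 0.1164),
    ("week_monday", 0.0592, 0.0),
    ("hour_day", -0.1753, 0.0713),
    ("trafway_div_nomedian", 0.1414, 0.2967),
    ("trafway_ramp", 0.0971, 0.4995),
    ("region_midwest", 0.0876, 0.5032),
    ("light_daylight", 0.1237, 0.0306),
    ("light_dark", 0.1215, 0.0),
]
_FRONT_CONST = (-0.2028, 0.0)
_FRONT_MU = (0.6191, 1.4814)

_REAR_ROWS = [
    ("age_le24", -0.4894, 0.3615),
    ("age_25_63", -0.2780, 0.0754),
    ("sex_male", -0.3822, 0.3554),
    ("alcohol", 0.2452, 0.0),
    ("drugs", 0.5898, 0.6645),
    ("airbag_undeployed", 1.0486, 0.0),
    ("belt_unused", 1.1682, 0.8390),
    ("mdlyr_1996_2000", -0.1192, 0.0774),
    ("mdlyr_2001_2005", -0.1669, 0.1782),
    ("mdlyr_2006_2010", -0.2833, 0.4353),
    ("mdlyr_2011_2015", -0.2049, 0.0),
    ("season_summer", 0.0933, 0.0575),
    ("hour_day", -0.2304, 0.0),
    ("surface_snow", -0.6991, 0.5531),
    ("trafway_div_nomedian", 0.1426, 0.0613),
    ("trafway_div_median", 0.2466, 0.0),
    ("trafway_oneway", 0.2140, 0.0),
    ("align_straight", 0.1703, 0.0),
    ("region_midwest", -0.1221, 0.0),
    ("region_south", -0.0916, 0.0),
    ("light_daylight", 0.1929, 0.0),
]
_REAR_CONST = (-0.7899, 0.2067)
_REAR_MU = (0.5090, 1.3173)
_RHO = 0.2440


def table3_truth_fixture() -> tuple[ModelSpec, Parameters]:
    """The published coefficient estimates as a ground-truth parameter set.

    Means, random-coefficient SDs, thresholds and the correlation are the
    printed values; the rear equation's constant is itself random.  Used to
    simulate datasets with realistic effect sizes.
    """
    spec = ModelSpec(
        covariates=(tuple(r[0] for r in _REAR_ROWS),
                    tuple(r[0] for r in _FRONT_ROWS)),
        n_categories=(4, 4),
        random_flags=(
            (_REAR_CONST[1] > 0,) + tuple(r[2] > 0 for r in _REAR_ROWS),
            (_FRONT_CONST[1] > 0,) + tuple(r[2] > 0 for r in _FRONT_ROWS)),
    )
    params = Parameters(
        beta=(np.array([_REAR_CONST[0]] + [r[1] for r in _REAR_ROWS]),
              np.array([_FRONT_CONST[0]] + [r[1] for r in _FRONT_ROWS])),
        thresholds=(np.array([0.0, *_REAR_MU]), np.array([0.0, *_FRONT_MU])),
        rho=_RHO,
        sigma=(np.array([_REAR_CONST[1]] + [r[2] for r in _REAR_ROWS]),
               np.array([_FRONT_CONST[1]] + [r[2] for r in _FRONT_ROWS])),
    )
    params.validate(spec)
    return spec, params


def _f(count: int, total: int = N_CRASHES_REFERENCE) -> float:
    return count / total


def default_scheme(seed: int = 0) -> CovariateScheme:
    """Covariate prevalences matching the published summary statistics.

    Driver-specific prevalences are ``(rear, front)`` pairs computed from
    the per-driver count columns of the published summary table; shared
    prevalences pool both drivers.  Variables the source summarises only
    graphically (season, traffic-way class, weekday) use round
    field-plausible shares.
    """
    drivers = N_DRIVERS_REFERENCE
    covs = (
        # driver-specific, mutually exclusive age bands (65+ reference)
        Covariate("age_le24", (_f(5567), _f(3133)), "driver", "age"),
        Covariate("age_25_63", (_f(8352), _f(10515)), "driver", "age"),
        Covariate("sex_male", (_f(7528), _f(6683)), "driver"),
        Covariate("alcohol", (_f(410), _f(42)), "driver"),
        Covariate("drugs", (_f(139), _f(14)), "driver"),
        Covariate("airbag_undeployed", (_f(3185), _f(706)), "driver"),
        Covariate("belt_unused", (_f(237), _f(138)), "driver"),
        Covariate("speed_related", (_f(3222), _f(147)), "driver"),
        Covariate("mdlyr_pre1996", (_f(1122), _f(632)), "driver", "mdlyr"),
        Covariate("mdlyr_1996_2000", (_f(2895), _f(1883)), "driver", "mdlyr"),
        Covariate("mdlyr_2001_2005", (_f(4530), _f(3768)), "driver", "mdlyr"),
        Covariate("mdlyr_2006_2010", (_f(4392), _f(5331)), "driver", "mdlyr"),
        Covariate("mdlyr_2011_2015", (_f(2220), _f(3545)), "driver", "mdlyr"),
        Covariate("bodytype_4door", (_f(10763), _f(10873)), "driver"),
        # crash-shared conditions
        Covariate("hour_day", _f(25080, drivers), "shared"),
        Covariate("week_monday", 1.0 / 7.0, "shared"),
        Covariate("season_summer", 0.25, "shared"),
        Covariate("surface_snow", _f(402, drivers), "shared"),
        Covariate("align_straight", _f(28772, drivers), "shared"),
        Covariate("trafway_div_nomedian", 0.15, "shared", "trafway"),
        Covariate("trafway_div_median", 0.25, "shared", "trafway"),
        Covariate("trafway_oneway", 0.05, "shared", "trafway"),
        Covariate("trafway_ramp", 0.03, "shared", "trafway"),
        Covariate("region_northeast", _f(6076, drivers), "shared", "region"),
        Covariate("region_midwest", _f(5522, drivers), "shared", "region"),
        Covariate("region_south", _f(15174, drivers), "shared", "region"),
        Covariate("light_daylight", _f(23232, drivers), "shared", "light"),
        Covariate("light_dark", _f(6072, drivers), "shared", "light"),
    )
    return CovariateScheme(covs, seed=seed)


def recovery_truth_fixture(rho: float = 0.25
                           ) -> tuple[ModelSpec, Parameters, CovariateScheme]:
    """A compact ground truth for parameter-recovery studies.

    Both equations keep a constant plus the two strongest demographic
    dummies of the published model; one coefficient per equation is random
    (rear age<=24, front male) with the published means and SDs, the
    thresholds are the published cutoffs, and the latent correlation
    defaults to 0.25.
    """
    spec = ModelSpec(
        covariates=(("age_le24", "sex_male"), ("age_le24", "sex_male")),
        n_categories=(4, 4),
        random_flags=((False, True, False), (False, False, True)),
    )
    params = Parameters(
        beta=(np.array([-0.7899, -0.4894, -0.3822]),
              np.array([-0.2028, -0.3182, -0.4426])),
        thresholds=(np.array([0.0, *_REAR_MU]), np.array([0.0, *_FRONT_MU])),
        rho=rho,
        sigma=(np.array([0.0, 0.3615, 0.0]), np.array([0.0, 0.0, 0.5292])),
    )
    params.validate(spec)
    scheme = CovariateScheme((
        Covariate("age_le24", (_f(5567), _f(3133)), "driver"),
        Covariate("sex_male", (_f(7528), _f(6683)), "driver"),
    ))
    return spec, params, scheme
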