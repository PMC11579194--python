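"""Synthetic NHANES-like covariate tables for development and testing.

The generator emulates the published summary statistics of the adult NHANES
covariate panel (sex, race-ethnicity, age, body weight, height, fat mass,
serum creatinine, ALT, AST, ALP, albumin, total bilirubin): truncated-normal
margins for the anthropometrics and albumin, moment-matched lognormal margins
for the biochemical measurements and fat mass, category frequencies for sex
and race-ethnicity.  Dependence is injected through a latent Gaussian copula
(sex enters as a thresholded latent coordinate, so it shifts height, serum
creatinine and bilirubin), and missingness reproduces the survey's pattern:
fat mass is structurally missing for everyone aged 60 or older (the DXA
examination age-eligibility rule) plus a random block, and the laboratory
panel has a few percent missing completely at random.

This is a fixture, not a re-creation of the survey: only first and second
moments, category frequencies and a plausible correlation pattern are
emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .table import CATEGORICAL, CONTINUOUS, ColumnSpec, CovariateTable

#: target mean, SD and range of each continuous covariate (natural scale)
CONTINUOUS_MARGINS: dict[str, dict] = {
    "age": {"mean": 46.05, "sd": 17.21, "range": (18.0, 79.0), "family": "truncnorm", "log_scale": False, "unit": "year"},
    "weight": {"mean": 82.02, "sd": 22.17, "range": (32.3, 242.6), "family": "truncnorm", "log_scale": False, "unit": "kg"},
    "height": {"mean": 167.16, "sd": 10.09, "range": (123.3, 204.5), "family": "truncnorm", "log_scale": False, "unit": "cm"},
    "albumin": {"mean": 4.28, "sd": 0.35, "range": (2.0, 5.6), "family": "truncnorm", "log_scale": False, "unit": "g/dL"},
    "fat": {"mean": 27.11, "sd": 11.93, "family": "lognormal", "log_scale": True, "unit": "kg"},
    "scr": {"mean": 0.88, "sd": 0.45, "family": "lognormal", "log_scale": True, "unit": "mg/dL"},
    "alt": {"mean": 25.57, "sd": 20.42, "family": "lognormal", "log_scale": True, "unit": "U/L"},
    "ast": {"mean": 25.93, "sd": 17.13, "family": "lognormal", "log_scale": True, "unit": "U/L"},
    "alp": {"mean": 69.34, "sd": 24.59, "family": "lognormal", "log_scale": True, "unit": "U/L"},
    "bilirubin": {"mean": 0.62, "sd": 0.31, "family": "lognormal", "log_scale": True, "unit": "mg/dL"},
}

SEX_PROBS = {"male": 0.485, "female": 0.515}
RACE_PROBS = {
    "hispanic": 0.266,
    "white": 0.369,
    "african_american": 0.228,
    "asian": 0.106,
    "other": 0.031,
}

#: default latent-Gaussian correlations (sex coded so that high latent = male)
DEFAULT_CORRELATIONS: dict[tuple[str, str], float] = {
    ("weight", "height"): 0.45,
    ("weight", "fat"): 0.70,
    ("height", "fat"): 0.15,
    ("age", "scr"): 0.25,
    ("age", "alp"): 0.15,
    ("alt", "ast"): 0.60,
    ("sex", "height"): 0.55,
    ("sex", "scr"): 0.45,
    ("sex", "bilirubin"): 0.30,
    ("sex", "fat"): -0.35,
    ("weight", "alt"): 0.25,
}

#: MCAR missingness rates emulating the survey's per-variable % missing
DEFAULT_MCAR_RATES: dict[str, float] = {
    "weight": 0.010,
    "height": 0.010,
    "scr": 0.063,
    "alt": 0.063,
    "ast": 0.064,
    "alp": 0.063,
    "albumin": 0.063,
    "bilirubin": 0.063,
    # random block of missing fat-mass measurements among the age-eligible
    # (on top of the structural age >= 60 rule below)
    "fat": 0.45,
}

#: structural rule: fat mass unobserved at and above this age (DXA eligibility)
FAT_AGE_CUTOFF = 60.0


@dataclass
class StructuredMissingRule:
    """Set ``target`` missing wherever ``anchor`` >= threshold."""

    target: str = "fat"
    anchor: str = "age"
    threshold: float = FAT_AGE_CUTOFF

    def mask(self, table: CovariateTable) -> np.ndarray:
        return np.asarray(table.values(self.anchor), dtype=float) >= self.threshold


@dataclass
class FixtureSpec:
    """Configuration of the synthetic population generator."""

    n: int = 1000
    seed: int = 0
    continuous: dict[str, dict] = field(default_factory=lambda: dict(CONTINUOUS_MARGINS))
    sex_probs: dict = field(default_factory=lambda: dict(SEX_PROBS))
    race_probs: dict = field(default_factory=lambda: dict(RACE_PROBS))
    correlations: dict = field(default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    mcar_rates: dict = field(default_factory=lambda: dict(DEFAULT_MCAR_RATES))
    structured_rules: list[StructuredMissingRule] = field(
        default_factory=lambda: [StructuredMissingRule()]
    )
    include_race: bool = True
    with_weights: bool = False
    weight_sigma: float = 0.5  # lognormal sampling-weight spread
    covariates: list[str] | None = None  # subset of continuous covariates to keep

    def complete(self) -> "FixtureSpec":
        """Copy of the spec with all missingness switched off."""
        return replace(self, mcar_rates={}, structured_rules=[])


def _correlation_matrix(names: list[str], pairs: dict) -> np.ndarray:
    k = len(names)
    R = np.eye(k)
    idx = {n: i for i, n in enumerate(names)}
    for (a, b), r in pairs.items():
        if a in idx and b in idx:
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    # nudge to the nearest positive-definite matrix if needed
    w, V = np.linalg.eigh(R)
    if w.min() <= 1e-8:
        w = np.clip(w, 1e-6, None)
        R = V @ np.diag(w) @ V.T
        s = np.sqrt(np.diag(R))
        R = R / np.outer(s, s)
        w2 = np.linalg.eigvalsh(R)
        if w2.min() <= 0:
            raise ValueError("correlation specification is not positive definite")
    return R


def _truncnorm_match(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """loc/scale of a truncated normal whose *truncated* moments hit mean/sd."""
    from scipy.optimize import least_squares

    def resid(p):
        loc, scale = p
        a, b = (lo - loc) / scale, (hi - loc) / scale
        return [
            stats.truncnorm.mean(a, b, loc=loc, scale=scale) - mean,
            stats.truncnorm.std(a, b, loc=loc, scale=scale) - sd,
        ]

    sol = least_squares(
        resid, x0=[mean, sd], bounds=([lo, sd / 10.0], [hi, 50.0 * sd]), xtol=1e-12
    )
    return float(sol.x[0]), float(sol.x[1])


_TRUNCNORM_CACHE: dict[tuple, tuple[float, float]] = {}


def _margin_ppf(name: str, cfg: dict, u: np.ndarray) -> np.ndarray:
    if cfg["family"] == "truncnorm":
        lo, hi = cfg["range"]
        key = (cfg["mean"], cfg["sd"], lo, hi)
        if key not in _TRUNCNORM_CACHE:
            _TRUNCNORM_CACHE[key] = _truncnorm_match(cfg["mean"], cfg["sd"], lo, hi)
        loc, scale = _TRUNCNORM_CACHE[key]
        a = (lo - loc) / scale
        b = (hi - loc) / scale
        return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)
    if cfg["family"] == "lognormal":
        m, s = cfg["mean"], cfg["sd"]
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        return stats.lognorm.ppf(u, np.sqrt(sigma2), scale=np.exp(mu))
    raise ValueError(f"unknown margin family {cfg['family']!r} for {name!r}")


def generate(spec: FixtureSpec) -> CovariateTable:
    """Draw a complete table from the latent-Gaussian joint, then apply the
    configured missingness.  Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    cont_names = list(spec.continuous)
    if spec.covariates is not None:
        cont_names = [c for c in cont_names if c in spec.covariates]
    latent = ["sex"] + cont_names
    R = _correlation_matrix(latent, spec.correlations)
    Z = rng.multivariate_normal(np.zeros(len(latent)), R, size=spec.n, method="cholesky")
    U = stats.norm.cdf(Z)

    data: dict = {}
    p_male = spec.sex_probs["male"] / sum(spec.sex_probs.values())
    data["sex"] = np.where(U[:, 0] <= p_male, "male", "female").astype(object)
    for j, name in enumerate(cont_names, start=1):
        data[name] = _margin_ppf(name, spec.continuous[name], U[:, j])

    columns = [ColumnSpec("sex", CATEGORICAL)]
    if spec.include_race:
        levels = list(spec.race_probs)
        probs = np.array([spec.race_probs[lv] for lv in levels], dtype=float)
        probs /= probs.sum()
        data["race_ethnicity"] = rng.choice(np.array(levels, dtype=object), size=spec.n, p=probs)
        columns.append(ColumnSpec("race_ethnicity", CATEGORICAL))
    for name in cont_names:
        cfg = spec.continuous[name]
        columns.append(
            ColumnSpec(name, CONTINUOUS, log_scale=bool(cfg.get("log_scale", False)), unit=cfg.get("unit"))
        )

    weight_column = None
    if spec.with_weights:
        data["sample_weight"] = rng.lognormal(mean=0.0, sigma=spec.weight_sigma, size=spec.n)
        weight_column = "sample_weight"

    order = [c.name for c in columns] + ([weight_column] if weight_column else [])
    table = CovariateTable(
        df=pd.DataFrame(data, columns=order),
        columns=columns,
        weight_column=weight_column,
        meta={"seed": spec.seed, "generator": "vinepop.fixtures"},
    )
    return apply_missingness(table, spec, rng=rng)


def apply_missingness(
    table: CovariateTable, spec: FixtureSpec, rng: np.random.Generator | None = None
) -> CovariateTable:
    """Apply structured rules then MCAR rates; returns a new table.

    The missingness mask is stored in ``table.meta['missing_mask']`` keyed by
    covariate name.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    df = table.df.copy()
    masks: dict[str, np.ndarray] = {}
    for rule in spec.structured_rules:
        if rule.target not in df.columns or rule.anchor not in df.columns:
            continue
        m = rule.mask(table)
        masks[rule.target] = masks.get(rule.target, np.zeros(table.n, bool)) | m
    for name, rate in spec.mcar_rates.items():
        if name not in df.columns:
            continue
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"MCAR rate for {name!r} must be in [0, 1]")
        m = rng.uniform(size=table.n) < rate
        masks[name] = masks.get(name, np.zeros(table.n, bool)) | m
    for name, m in masks.items():
        df.loc[m, name] = np.nan
    out = CovariateTable(
        df=df, columns=list(table.columns), weight_column=table.weight_column, meta=dict(table.meta)
    )
    out.meta["missing_mask"] = {k: v.copy() for k, v in masks.items()}
    return out


def default_spec(n: int = 1000, seed: int = 0, complete: bool = False, **kwargs) -> FixtureSpec:
    spec = FixtureSpec(n=n, seed=seed, **kwargs)
    return spec.complete() if complete else spec
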