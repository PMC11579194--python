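"""Univariate marginal models and the probability integral transform (PIT).

Continuous covariates are modelled by a Gaussian kernel density estimate,
optionally on the log scale so that back-transformed simulations are strictly
positive (the usual treatment of biochemical measurements).  The fitted CDF is
tabulated on a fixed grid spanning the data range plus four bandwidths, which
makes PIT and quantile exact inverses of each other by construction and lets a
fitted marginal be serialized and shared without subject-level data.

Categorical covariates are described by level probabilities; they are mapped
to the uniform scale with a randomized PIT (a uniform draw within the level's
probability interval), which is the standard identifiability device for
discrete variables entering a copula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr  # standard normal CDF, vectorized

from .table import CATEGORICAL, CONTINUOUS

#: pseudo-observations are clamped to [CLAMP_EPS, 1 - CLAMP_EPS]
CLAMP_EPS = 1e-10
#: number of grid points used to tabulate the continuous CDF
GRID_SIZE = 512
#: grid extends this many bandwidths beyond the observed range
GRID_PAD_BW = 4.0


class EstimationError(ValueError):
    """Raised when a marginal cannot be estimated from the data given."""


@dataclass
class MarginalModel:
    covariate_name: str
    kind: str  # CONTINUOUS | CATEGORICAL
    log_scale: bool = False
    weighted: bool = False
    n_used: int = 0
    # continuous fields (grid lives on the modelling scale: log if log_scale)
    bandwidth: float | None = None
    grid: np.ndarray | None = None
    cdf_grid: np.ndarray | None = None
    pdf_grid: np.ndarray | None = None
    # categorical fields
    levels: list = field(default_factory=list)
    probs: np.ndarray | None = None

    # -- continuous ----------------------------------------------------
    def _require_continuous(self):
        if self.kind != CONTINUOUS:
            raise TypeError(
                f"{self.covariate_name!r} is categorical; use pit_categorical/decode_categorical"
            )

    def pit(self, x) -> np.ndarray:
        """CDF of ``x`` (natural scale), clamped strictly inside (0, 1)."""
        self._require_continuous()
        x = np.asarray(x, dtype=float)
        if self.log_scale:
            with np.errstate(divide="ignore", invalid="ignore"):
                x = np.log(x)
        u = np.interp(x, self.grid, self.cdf_grid)
        return np.clip(u, CLAMP_EPS, 1.0 - CLAMP_EPS)

    def quantile(self, u) -> np.ndarray:
        """Inverse CDF back to the natural scale."""
        self._require_continuous()
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0.0) | (u >= 1.0)):
            raise ValueError("quantile requires u strictly inside (0, 1)")
        x = np.interp(u, self.cdf_grid, self.grid)
        if self.log_scale:
            x = np.exp(x)
        return x

    # -- categorical ---------------------------------------------------
    def level_index(self, label) -> int:
        try:
            return self.levels.index(label)
        except ValueError:
            raise ValueError(
                f"unknown level {label!r} for {self.covariate_name!r}; known: {self.levels}"
            ) from None

    def cum_probs(self) -> np.ndarray:
        """Cumulative level probabilities F(level) under the model ordering."""
        return np.cumsum(self.probs)

    def reordered(self, level_order: list) -> "MarginalModel":
        """Same categorical model with levels listed in a different order."""
        if sorted(map(str, level_order)) != sorted(map(str, self.levels)):
            raise ValueError("level_order must be a permutation of the fitted levels")
        idx = [self.levels.index(lv) for lv in level_order]
        return MarginalModel(
            covariate_name=self.covariate_name,
            kind=self.kind,
            weighted=self.weighted,
            n_used=self.n_used,
            levels=list(level_order),
            probs=self.probs[idx],
        )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "covariate_name": self.covariate_name,
            "kind": self.kind,
            "log_scale": self.log_scale,
            "weighted": self.weighted,
            "n_used": int(self.n_used),
        }
        if self.kind == CONTINUOUS:
            d.update(
                bandwidth=float(self.bandwidth),
                grid=self.grid.tolist(),
                cdf_grid=self.cdf_grid.tolist(),
                pdf_grid=self.pdf_grid.tolist(),
            )
        else:
            d.update(levels=list(self.levels), probs=self.probs.tolist())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MarginalModel":
        m = cls(
            covariate_name=d["covariate_name"],
            kind=d["kind"],
            log_scale=bool(d.get("log_scale", False)),
            weighted=bool(d.get("weighted", False)),
            n_used=int(d.get("n_used", 0)),
        )
        if m.kind == CONTINUOUS:
            m.bandwidth = float(d["bandwidth"])
            m.grid = np.asarray(d["grid"], dtype=float)
            m.cdf_grid = np.asarray(d["cdf_grid"], dtype=float)
            m.pdf_grid = np.asarray(d["pdf_grid"], dtype=float)
        else:
            m.levels = list(d["levels"])
            m.probs = np.asarray(d["probs"], dtype=float)
        return m


def _weighted_sd(x: np.ndarray, w: np.ndarray) -> float:
    mu = np.average(x, weights=w)
    return math.sqrt(np.average((x - mu) ** 2, weights=w))


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    """Type-1 (inverse empirical CDF) weighted quantile.

    Frequency-weight semantics: duplicating an observation and doubling its
    weight give identical results, which keeps the fitted model invariant
    under that exchange.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    cw = np.cumsum(w[order])
    return float(xs[np.searchsorted(cw, q * cw[-1], side="left")])


def _silverman_bandwidth(x: np.ndarray, w: np.ndarray) -> float:
    """Silverman rule of thumb under frequency-weight semantics (n_eff = sum w)."""
    n_eff = w.sum()
    sd = _weighted_sd(x, w)
    iqr = _weighted_quantile(x, w, 0.75) - _weighted_quantile(x, w, 0.25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(abs(np.mean(x)), 1.0) * 1e-3
    return 0.9 * spread * n_eff ** (-0.2)


def fit_marginal(
    values,
    weights=None,
    log_scale: bool = False,
    kind: str = CONTINUOUS,
    name: str = "",
    level_order: list | None = None,
) -> MarginalModel:
    """Fit a univariate marginal model.

    Missing values (NaN/None) are excluded; weights, if given, rescale each
    observation's contribution to the density (or level frequencies).
    """
    values = np.asarray(values, dtype=object if kind == CATEGORICAL else float)
    if kind == CONTINUOUS:
        miss = np.isnan(np.asarray(values, dtype=float))
    else:
        miss = np.array([v is None or (isinstance(v, float) and math.isnan(v)) for v in values])
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != np.shape(values):
            raise ValueError("weights must align with values")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
    if miss.all():
        raise EstimationError(f"covariate {name!r}: all values missing")

    keep = ~miss
    v = values[keep]
    w = np.ones(keep.sum()) if weights is None else weights[keep]
    if w.sum() <= 0:
        raise ValueError(f"covariate {name!r}: weights sum to zero on non-missing rows")
    n_used = int(keep.sum())

    if kind == CATEGORICAL:
        levels = level_order if level_order is not None else sorted(set(v), key=str)
        probs = np.zeros(len(levels))
        for i, lv in enumerate(levels):
            probs[i] = w[np.array([x == lv for x in v])].sum()
        if np.any(probs == 0) and level_order is None:
            pass  # sorted(set(v)) guarantees every level is observed
        probs = probs / probs.sum()
        return MarginalModel(
            covariate_name=name,
            kind=CATEGORICAL,
            weighted=weights is not None,
            n_used=n_used,
            levels=list(levels),
            probs=probs,
        )

    if n_used < 10:
        raise EstimationError(f"covariate {name!r}: needs >= 10 non-missing values, got {n_used}")
    x = np.asarray(v, dtype=float)
    if log_scale:
        bad = np.nonzero(x <= 0)[0]
        if bad.size:
            orig_idx = np.nonzero(keep)[0][bad[0]]
            raise ValueError(
                f"covariate {name!r}: log_scale requires strictly positive values; "
                f"value {x[bad[0]]!r} at row {orig_idx}"
            )
        x = np.log(x)

    h = _silverman_bandwidth(x, w)
    grid = np.linspace(x.min() - GRID_PAD_BW * h, x.max() + GRID_PAD_BW * h, GRID_SIZE)
    wsum = w.sum()
    cdf = np.zeros(GRID_SIZE)
    pdf = np.zeros(GRID_SIZE)
    # chunk over observations to bound memory on large samples
    for lo in range(0, x.size, 4096):
        xs = x[lo : lo + 4096, None]
        ws = w[lo : lo + 4096, None]
        z = (grid[None, :] - xs) / h
        cdf += (ws * ndtr(z)).sum(axis=0)
        pdf += (ws * np.exp(-0.5 * z**2)).sum(axis=0)
    cdf /= wsum
    pdf /= wsum * h * math.sqrt(2.0 * math.pi)
    # enforce strict monotonicity against floating accumulation
    cdf = np.maximum.accumulate(cdf)
    cdf += np.arange(GRID_SIZE) * 1e-15

    return MarginalModel(
        covariate_name=name,
        kind=CONTINUOUS,
        log_scale=log_scale,
        weighted=weights is not None,
        n_used=n_used,
        bandwidth=h,
        grid=grid,
        cdf_grid=cdf,
        pdf_grid=pdf,
    )


def pit(model: MarginalModel, x) -> np.ndarray:
    """Probability integral transform of continuous value(s) ``x``."""
    return model.pit(x)


def quantile(model: MarginalModel, u) -> np.ndarray:
    """Inverse PIT of uniform value(s) ``u`` back to the natural scale."""
    return model.quantile(u)


def pit_categorical(model: MarginalModel, labels, rng: np.random.Generator) -> np.ndarray:
    """Randomized PIT: u ~ Uniform(F(level-), F(level)] per observation.

    Deterministic given the generator state; averaging over the jitter, the
    output is exactly Uniform(0, 1) when labels follow the model frequencies.
    """
    if model.kind != CATEGORICAL:
        raise TypeError(f"{model.covariate_name!r} is continuous; use pit()")
    scalar = np.isscalar(labels) or isinstance(labels, str)
    labels = [labels] if scalar else list(labels)
    cum = model.cum_probs()
    lo_edges = np.concatenate([[0.0], cum[:-1]])
    idx = np.array([model.level_index(lb) for lb in labels])
    jitter = rng.uniform(size=len(labels))
    u = lo_edges[idx] + jitter * model.probs[idx]
    u = np.clip(u, CLAMP_EPS, 1.0 - CLAMP_EPS)
    return u[0] if scalar else u


def pit_categorical_jittered(model: MarginalModel, labels, jitter: np.ndarray) -> np.ndarray:
    """Randomized PIT with caller-supplied jitter uniforms (one per row).

    Re-using the same jitter across candidate level orderings makes their
    fitted likelihoods comparable during the categorical ordering search.
    """
    cum = model.cum_probs()
    lo_edges = np.concatenate([[0.0], cum[:-1]])
    out = np.full(len(labels), np.nan)
    for i, lb in enumerate(labels):
        if lb is None or (isinstance(lb, float) and math.isnan(lb)):
            continue
        k = model.level_index(lb)
        out[i] = lo_edges[k] + jitter[i] * model.probs[k]
    return np.clip(out, CLAMP_EPS, 1.0 - CLAMP_EPS)


def decode_categorical(model: MarginalModel, u: np.ndarray) -> np.ndarray:
    """Map uniforms back to level labels via cumulative level probabilities."""
    cum = model.cum_probs()
    idx = np.searchsorted(cum, np.asarray(u, dtype=float), side="left")
    idx = np.clip(idx, 0, len(model.levels) - 1)
    return np.array([model.levels[i] for i in idx], dtype=object)
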