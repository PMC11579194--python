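"""Realism metrics for simulated virtual populations.

Marginal fidelity is quantified by the relative error RE = (M_sim - M_obs) /
M_obs of the metrics M in {mean, SD, 5th/50th/95th percentile} per continuous
covariate, and by level-frequency comparison for categoricals.  Dependence
fidelity is quantified per continuous pair by (a) the absolute difference of
Pearson correlations on the modelling scale and (b) the Jaccard overlap of
the 95% highest-density-region contours of observed versus simulated data: a
binned 2D kernel density estimate is thresholded at the density level whose
superlevel set holds 95% of the mass, the contour rings are polygonized, and
the overlap is 100 * area(intersection) / area(union).

``evaluate_model`` repeats the simulation many times and summarizes each
metric by its median and coefficient of variation across replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon
from shapely.ops import unary_union
from skimage import measure

from .simulate import simulate, simulate_subgroup
from .table import CATEGORICAL, CONTINUOUS, CovariateTable
from .vine import VineCopulaModel, fit_vine

log = logging.getLogger(__name__)

MARGINAL_METRICS = ("mean", "sd", "p5", "p50", "p95")

#: KDE grid resolution for density contours
CONTOUR_GRID = 256
#: grid padding in bandwidths beyond the data range
CONTOUR_PAD_BW = 3.0


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator (reference value) vanishes."""


# ---------------------------------------------------------------------------
# marginal metrics
# ---------------------------------------------------------------------------


def relative_error(m_sim: float, m_obs: float) -> float:
    """RE = (M_sim - M_obs) / M_obs."""
    if m_obs == 0:
        raise UndefinedMetricError("relative error undefined for M_obs = 0")
    return (m_sim - m_obs) / m_obs


def marginal_metrics(column) -> dict[str, float]:
    """Sample mean, SD and 5/50/95th percentiles (linear interpolation)."""
    x = np.asarray(column, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("need at least 2 non-missing values")
    p5, p50, p95 = np.percentile(x, [5, 50, 95])  # linear interpolation default
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "p5": float(p5),
        "p50": float(p50),
        "p95": float(p95),
    }


# ---------------------------------------------------------------------------
# density contours and overlap
# ---------------------------------------------------------------------------


@dataclass
class DensityContour:
    """95% (by default) highest-density region of a covariate pair."""

    x_name: str
    y_name: str
    level: float  # probability mass
    region: object  # shapely (Multi)Polygon
    density_threshold: float
    enclosed_mass: float

    @property
    def area(self) -> float:
        return self.region.area


def _kde2d(x, y, grid=CONTOUR_GRID, pad_bw=CONTOUR_PAD_BW):
    """Binned Gaussian KDE on a regular grid; returns (density, xc, yc)."""
    n = x.size
    hx = np.std(x, ddof=1) * n ** (-1.0 / 6.0)  # normal-reference, 2D
    hy = np.std(y, ddof=1) * n ** (-1.0 / 6.0)
    if hx <= 0 or hy <= 0:
        raise ValueError("degenerate (zero-variance) input")
    x0, x1 = x.min() - pad_bw * hx, x.max() + pad_bw * hx
    y0, y1 = y.min() - pad_bw * hy, y.max() + pad_bw * hy
    H, xe, ye = np.histogram2d(x, y, bins=grid, range=[[x0, x1], [y0, y1]])
    dx = xe[1] - xe[0]
    dy = ye[1] - ye[0]
    dens = ndimage.gaussian_filter(H, sigma=(hx / dx, hy / dy), mode="constant")
    dens /= dens.sum() * dx * dy
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    return dens, xc, yc


def _hdr_threshold(dens: np.ndarray, cell_area: float, mass: float) -> float:
    """Smallest density level whose superlevel set encloses >= ``mass``."""
    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat) * cell_area
    idx = int(np.searchsorted(cum, mass))
    idx = min(idx, flat.size - 1)
    return float(flat[idx])


def _rings_to_region(rings):
    """Assemble contour rings into a polygon set with even-odd nesting."""
    polys = []
    for ring in rings:
        if len(ring) < 4:
            continue
        if not np.allclose(ring[0], ring[-1]):
            ring = np.vstack([ring, ring[0]])  # close rings cut at the border
        p = Polygon(ring)
        if not p.is_valid:
            p = p.buffer(0)
        if not p.is_empty and p.area > 0:
            polys.append(p)
    if not polys:
        return Polygon()
    region = polys[0]
    for p in polys[1:]:
        region = region.symmetric_difference(p)
    return region


def density_contour(x, y, mass: float = 0.95, x_name: str = "x", y_name: str = "y") -> DensityContour:
    """Highest-density-region contour containing ``mass`` of the 2D KDE."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 100:
        raise ValueError(f"need >= 100 paired observations, got {x.size}")
    dens, xc, yc = _kde2d(x, y)
    dx = xc[1] - xc[0]
    dy = yc[1] - yc[0]
    thr = _hdr_threshold(dens, dx * dy, mass)
    enclosed = float(dens[dens >= thr].sum() * dx * dy)
    rings_idx = measure.find_contours(dens, thr)
    rings = [
        np.column_stack([np.interp(r[:, 0], np.arange(xc.size), xc),
                         np.interp(r[:, 1], np.arange(yc.size), yc)])
        for r in rings_idx
    ]
    region = _rings_to_region(rings)
    return DensityContour(
        x_name=x_name,
        y_name=y_name,
        level=mass,
        region=region,
        density_threshold=thr,
        enclosed_mass=enclosed,
    )


def overlap_metric(obs_pair, sim_pair, mass: float = 0.95) -> float:
    """Jaccard overlap (percent) of the two samples' HDR contour regions.

    Each argument is an (x, y) tuple of paired observations, or an already
    computed :class:`DensityContour`.
    """
    a = obs_pair if isinstance(obs_pair, DensityContour) else density_contour(*obs_pair, mass=mass)
    b = sim_pair if isinstance(sim_pair, DensityContour) else density_contour(*sim_pair, mass=mass)
    ra, rb = a.region, b.region
    # canonical operand order: floating-point results become exactly symmetric
    if (ra.area, tuple(ra.bounds)) > (rb.area, tuple(rb.bounds)):
        ra, rb = rb, ra
    union = ra.union(rb).area
    if union == 0:
        raise UndefinedMetricError("both contour regions are empty")
    inter = ra.intersection(rb).area
    return 100.0 * inter / union


# ---------------------------------------------------------------------------
# correlation comparison
# ---------------------------------------------------------------------------


def _modelling_scale(table: CovariateTable, name: str) -> np.ndarray:
    v = np.asarray(table.values(name), dtype=float)
    if table.spec(name).log_scale:
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.log(v)
    return v


def correlation_comparison(obs_table: CovariateTable, sim_table: CovariateTable) -> pd.DataFrame:
    """Per-pair |Pearson r_sim - r_obs| on the modelling (log where set) scale."""
    shared = [c for c in obs_table.continuous if c in sim_table.continuous]
    rows = []
    for i in range(len(shared)):
        for j in range(i + 1, len(shared)):
            a, b = shared[i], shared[j]
            r = {}
            skip = False
            for tag, tab in (("obs", obs_table), ("sim", sim_table)):
                x = _modelling_scale(tab, a)
                y = _modelling_scale(tab, b)
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                    log.warning("correlation_comparison: skipping pair (%s, %s): constant column", a, b)
                    skip = True
                    break
                r[tag] = float(np.corrcoef(x[ok], y[ok])[0, 1])
            if skip:
                continue
            rows.append({"x": a, "y": b, "r_obs": r["obs"], "r_sim": r["sim"],
                         "error": abs(r["sim"] - r["obs"])})
    return pd.DataFrame(rows, columns=["x", "y", "r_obs", "r_sim", "error"])


# ---------------------------------------------------------------------------
# full evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Per-replicate realism metrics plus median / CoV summaries."""

    n_replicates: int
    marginal_re: pd.DataFrame  # columns: replicate, covariate, metric, m_obs, m_sim, re
    category_freq: pd.DataFrame  # replicate, covariate, level, f_obs, f_sim
    correlation: pd.DataFrame  # replicate, x, y, r_obs, r_sim, error
    overlap: pd.DataFrame  # replicate, x, y, overlap_pct
    summary: dict = field(default_factory=dict)

    def summarize(self) -> dict:
        s: dict = {"n_replicates": self.n_replicates}
        if len(self.marginal_re):
            re_med = self.marginal_re.groupby(["covariate", "metric"])["re"].median()
            s["median_abs_re"] = float(self.marginal_re["re"].abs().median())
            s["max_abs_median_re"] = float(re_med.abs().max())
            # CoV of each metric value across replicates, then the worst case
            cov = (
                self.marginal_re.groupby(["covariate", "metric"])["m_sim"]
                .agg(lambda v: np.std(v, ddof=1) / abs(np.mean(v)) if (len(v) > 1 and np.mean(v) != 0) else np.nan)
            )
            s["max_cov"] = float(np.nanmax(cov)) if len(cov) and not cov.isna().all() else None
        if len(self.correlation):
            s["median_corr_error"] = float(self.correlation["error"].median())
            s["max_corr_error"] = float(
                self.correlation.groupby(["x", "y"])["error"].median().max()
            )
        if len(self.overlap):
            s["median_overlap_pct"] = float(self.overlap["overlap_pct"].median())
            s["min_pair_median_overlap_pct"] = float(
                self.overlap.groupby(["x", "y"])["overlap_pct"].median().min()
            )
            s["n_pairs"] = int(self.overlap.groupby(["x", "y"]).ngroups)
        if len(self.category_freq):
            s["max_freq_error"] = float(
                (self.category_freq["f_sim"] - self.category_freq["f_obs"]).abs().max()
            )
        self.summary = s
        return s


def _level_freqs(values, levels) -> dict:
    vals = [v for v in values if not (v is None or (isinstance(v, float) and math.isnan(v)))]
    n = len(vals)
    return {lv: sum(v == lv for v in vals) / n for lv in levels} if n else {lv: np.nan for lv in levels}


def evaluate_model(
    obs_table: CovariateTable,
    model: VineCopulaModel,
    n_replicates: int = 100,
    seed=None,
    exclusions: dict | None = None,
    contour_mass: float = 0.95,
) -> EvaluationReport:
    """Simulate ``n_replicates`` virtual populations of the observed size and
    compare marginal and dependency metrics against the observed table.

    ``exclusions`` maps a covariate name to ``callable(table) -> bool mask``
    of simulated rows whose value for that covariate must be dropped before
    comparison.  This mirrors removing extrapolated values: when a covariate
    was systematically unobserved in a stratum (e.g. a measurement never taken
    above an age cut-off), its simulated values in that stratum have no
    observed counterpart and are excluded from the metrics.
    """
    exclusions = exclusions or {}
    rng = np.random.default_rng(seed)
    cont = obs_table.continuous
    cat = obs_table.categorical

    obs_metrics = {c: marginal_metrics(obs_table.values(c)) for c in cont}
    obs_levels = {c: model.marginals[c].levels for c in cat}
    obs_freqs = {c: _level_freqs(obs_table.values(c), obs_levels[c]) for c in cat}
    obs_contours = {}
    for i in range(len(cont)):
        for j in range(i + 1, len(cont)):
            a, b = cont[i], cont[j]
            x = _modelling_scale(obs_table, a)
            y = _modelling_scale(obs_table, b)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() >= 100:
                obs_contours[(a, b)] = density_contour(
                    x[ok], y[ok], mass=contour_mass, x_name=a, y_name=b
                )

    re_rows, freq_rows, corr_rows, ov_rows = [], [], [], []
    for rep in range(n_replicates):
        sub = int(rng.integers(0, 2**31 - 1))
        sim = simulate(model, obs_table.n, seed=sub)
        excl_mask = {c: fn(sim) for c, fn in exclusions.items()}

        def sim_col(name):
            v = np.asarray(sim.values(name), dtype=float).copy()
            if name in excl_mask:
                v[np.asarray(excl_mask[name], dtype=bool)] = np.nan
            return v

        for c in cont:
            mm = marginal_metrics(sim_col(c))
            for metric in MARGINAL_METRICS:
                mo = obs_metrics[c][metric]
                re_rows.append({
                    "replicate": rep, "covariate": c, "metric": metric,
                    "m_obs": mo, "m_sim": mm[metric],
                    "re": relative_error(mm[metric], mo) if mo != 0 else np.nan,
                })
        for c in cat:
            fs = _level_freqs(sim.values(c), obs_levels[c])
            for lv in obs_levels[c]:
                freq_rows.append({"replicate": rep, "covariate": c, "level": lv,
                                  "f_obs": obs_freqs[c][lv], "f_sim": fs[lv]})
        # dependence metrics on the modelling scale, exclusions applied
        sim_scaled = {}
        for c in cont:
            v = sim_col(c)
            if obs_table.spec(c).log_scale:
                with np.errstate(divide="ignore", invalid="ignore"):
                    v = np.log(v)
            sim_scaled[c] = v
        for (a, b), oc in obs_contours.items():
            x, y = sim_scaled[a], sim_scaled[b]
            ok = ~(np.isnan(x) | np.isnan(y))
            xo = _modelling_scale(obs_table, a)
            yo = _modelling_scale(obs_table, b)
            oko = ~(np.isnan(xo) | np.isnan(yo))
            r_obs = float(np.corrcoef(xo[oko], yo[oko])[0, 1])
            r_sim = float(np.corrcoef(x[ok], y[ok])[0, 1])
            corr_rows.append({"replicate": rep, "x": a, "y": b, "r_obs": r_obs,
                              "r_sim": r_sim, "error": abs(r_sim - r_obs)})
            if ok.sum() >= 100:
                sc = density_contour(x[ok], y[ok], mass=contour_mass, x_name=a, y_name=b)
                ov_rows.append({"replicate": rep, "x": a, "y": b,
                                "overlap_pct": overlap_metric(oc, sc)})

    report = EvaluationReport(
        n_replicates=n_replicates,
        marginal_re=pd.DataFrame(re_rows, columns=["replicate", "covariate", "metric", "m_obs", "m_sim", "re"]),
        category_freq=pd.DataFrame(freq_rows, columns=["replicate", "covariate", "level", "f_obs", "f_sim"]),
        correlation=pd.DataFrame(corr_rows, columns=["replicate", "x", "y", "r_obs", "r_sim", "error"]),
        overlap=pd.DataFrame(ov_rows, columns=["replicate", "x", "y", "overlap_pct"]),
    )
    report.summarize()
    return report


# ---------------------------------------------------------------------------
# subgroup strategy comparison
# ---------------------------------------------------------------------------


def compare_subgroup_strategies(
    obs_table: CovariateTable,
    group_column: str,
    family_set: list[str] | None = None,
    n_replicates: int = 10,
    seed=None,
    min_group_n: int = 200,
    full_model: VineCopulaModel | None = None,
) -> dict:
    """Filtered-full versus subgroup-copula simulation, per group.

    Fits one model on the whole table (unless supplied) and one per group on
    the group's rows (the group column dropped, being constant there); for
    each group, evaluates both strategies against the group's observed rows.
    Groups below ``min_group_n`` rows are skipped with a warning.
    """
    if obs_table.spec(group_column).kind != CATEGORICAL:
        raise ValueError(f"{group_column!r} must be categorical")
    rng = np.random.default_rng(seed)
    if full_model is None:
        full_model = fit_vine(obs_table, family_set=family_set, pit_seed=int(rng.integers(2**31)))
    results: dict = {}
    levels = full_model.marginals[group_column].levels
    for lv in levels:
        mask = np.array([v == lv for v in obs_table.values(group_column)])
        n_g = int(mask.sum())
        if n_g < min_group_n:
            log.warning("group %r has %d < %d rows; skipped", lv, n_g, min_group_n)
            results[lv] = {"skipped": True, "n": n_g}
            continue
        obs_g = obs_table.subset_rows(mask).drop_covariate(group_column)

        sub_model = fit_vine(obs_g, family_set=family_set, pit_seed=int(rng.integers(2**31)))

        # filtered-full: simulate from the full model, keep the group's rows
        seed_f = int(rng.integers(2**31))
        seed_s = int(rng.integers(2**31))
        rep_full = _evaluate_filtered_full(
            obs_g, full_model, group_column, lv, n_replicates, seed_f
        )
        rep_sub = evaluate_model(obs_g, sub_model, n_replicates=n_replicates, seed=seed_s)
        results[lv] = {
            "n": n_g,
            "filtered_full": rep_full,
            "subgroup": rep_sub,
            "filtered_full_summary": rep_full.summary,
            "subgroup_summary": rep_sub.summary,
        }
    return results


def _evaluate_filtered_full(obs_g, full_model, group_column, level, n_replicates, seed):
    """evaluate_model where each replicate is a filtered full-model draw."""
    rng = np.random.default_rng(seed)
    cont = obs_g.continuous
    obs_metrics = {c: marginal_metrics(obs_g.values(c)) for c in cont}
    obs_contours = {}
    for i in range(len(cont)):
        for j in range(i + 1, len(cont)):
            a, b = cont[i], cont[j]
            x = _modelling_scale(obs_g, a)
            y = _modelling_scale(obs_g, b)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() >= 100:
                obs_contours[(a, b)] = density_contour(x[ok], y[ok], x_name=a, y_name=b)
    re_rows, corr_rows, ov_rows = [], [], []
    for rep in range(n_replicates):
        sub = int(rng.integers(0, 2**31 - 1))
        sim = simulate_subgroup(full_model, obs_g.n, {group_column: level}, seed=sub)
        for c in cont:
            mm = marginal_metrics(sim.values(c))
            for metric in MARGINAL_METRICS:
                mo = obs_metrics[c][metric]
                re_rows.append({"replicate": rep, "covariate": c, "metric": metric,
                                "m_obs": mo, "m_sim": mm[metric],
                                "re": relative_error(mm[metric], mo) if mo != 0 else np.nan})
        for (a, b), oc in obs_contours.items():
            x = _modelling_scale(sim, a)
            y = _modelling_scale(sim, b)
            xo = _modelling_scale(obs_g, a)
            yo = _modelling_scale(obs_g, b)
            oko = ~(np.isnan(xo) | np.isnan(yo))
            r_obs = float(np.corrcoef(xo[oko], yo[oko])[0, 1])
            r_sim = float(np.corrcoef(x, y)[0, 1])
            corr_rows.append({"replicate": rep, "x": a, "y": b, "r_obs": r_obs,
                              "r_sim": r_sim, "error": abs(r_sim - r_obs)})
            sc = density_contour(x, y, x_name=a, y_name=b)
            ov_rows.append({"replicate": rep, "x": a, "y": b,
                            "overlap_pct": overlap_metric(oc, sc)})
    report = EvaluationReport(
        n_replicates=n_replicates,
        marginal_re=pd.DataFrame(re_rows, columns=["replicate", "covariate", "metric", "m_obs", "m_sim", "re"]),
        category_freq=pd.DataFrame(columns=["replicate", "covariate", "level", "f_obs", "f_sim"]),
        correlation=pd.DataFrame(corr_rows, columns=["replicate", "x", "y", "r_obs", "r_sim", "error"]),
        overlap=pd.DataFrame(ov_rows, columns=["replicate", "x", "y", "overlap_pct"]),
    )
    report.summarize()
    return report


# ---------------------------------------------------------------------------
# holdout missing-data validation
# ---------------------------------------------------------------------------


def holdout_missing_validation(
    obs_table: CovariateTable,
    target_covariate: str,
    holdout_bands: list[tuple[float, float]],
    anchor_covariate: str,
    family_set: list[str] | None = None,
    seed=None,
    n_sim: int | None = None,
) -> dict:
    """Mask the target in each anchor band, refit, simulate, and compare the
    simulated in-band target distribution with the held-out observations.

    Returns per-band relative errors of mean/SD plus the (anchor, target)
    contour overlap where enough held-out data exist.
    """
    if obs_table.spec(target_covariate).kind != CONTINUOUS:
        raise ValueError("target covariate must be continuous")
    rng = np.random.default_rng(seed)
    n_sim = n_sim or obs_table.n
    out: dict = {}
    anchor = np.asarray(obs_table.values(anchor_covariate), dtype=float)
    target = np.asarray(obs_table.values(target_covariate), dtype=float)
    for lo, hi in holdout_bands:
        band = (anchor >= lo) & (anchor < hi)
        held = band & ~np.isnan(target)
        if held.sum() == 0:
            log.warning("band [%s, %s): no held-out values; skipped", lo, hi)
            out[(lo, hi)] = {"skipped": True}
            continue
        df = obs_table.df.copy()
        df.loc[band, target_covariate] = np.nan
        masked = CovariateTable(df=df, columns=list(obs_table.columns),
                                weight_column=obs_table.weight_column)
        model = fit_vine(masked, family_set=family_set, pit_seed=int(rng.integers(2**31)))
        sim = simulate(model, n_sim, seed=int(rng.integers(2**31)))
        sim_anchor = np.asarray(sim.values(anchor_covariate), dtype=float)
        sim_target = np.asarray(sim.values(target_covariate), dtype=float)
        in_band = (sim_anchor >= lo) & (sim_anchor < hi)
        held_vals = target[held]
        sim_vals = sim_target[in_band]
        res = {
            "n_held_out": int(held.sum()),
            "n_sim_in_band": int(in_band.sum()),
            "re_mean": relative_error(float(np.mean(sim_vals)), float(np.mean(held_vals))),
            "re_sd": relative_error(float(np.std(sim_vals, ddof=1)), float(np.std(held_vals, ddof=1))),
        }
        if held.sum() >= 100 and in_band.sum() >= 100:
            log_t = obs_table.spec(target_covariate).log_scale
            ho = np.log(held_vals) if log_t else held_vals
            so = np.log(sim_vals) if log_t else sim_vals
            try:
                res["overlap_pct"] = overlap_metric(
                    (anchor[held], ho), (sim_anchor[in_band], so)
                )
            except ValueError:  # pragma: no cover - degenerate band
                pass
        out[(lo, hi)] = res
    return out
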