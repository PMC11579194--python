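"""Virtual population simulation from a fitted vine copula model.

Sampling uses the inverse Rosenblatt transform: independent uniforms are
pushed through a chain of inverse h-functions dictated by the vine structure,
yielding a dependent uniform-scale sample, which is then mapped back to the
natural scale per covariate (inverse PIT; exponentiation for log-scale
covariates; cumulative-probability decoding for categoricals).

The h-inverse chain requires a variable elimination order.  It is derived by
peeling the structure: the top tree's single edge names a variable that is a
conditioned member of exactly one edge per tree; removing that variable and
its edges leaves a vine on the remaining variables, and so on.  This is the
column decomposition underlying the usual R-vine matrix representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .marginals import decode_categorical
from .table import CATEGORICAL, CONTINUOUS, ColumnSpec, CovariateTable
from .vine import StructureError, VineCopulaModel, VineEdge, VineStructure


class InfeasibleFilterError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the requested filters."""


@dataclass
class _Column:
    """One elimination step: variable plus its edges ordered by tree level."""

    variable: str
    entries: list[tuple[int, VineEdge]]  # (tree level, edge), level ascending


def peel_columns(structure: VineStructure) -> list[_Column]:
    """Decompose the vine into elimination columns (last column edge-free)."""
    remaining: list[tuple[int, VineEdge]] = [
        (t, e) for t, tree in enumerate(structure.trees, start=1) for e in tree
    ]
    variables = set(structure.variables)
    columns: list[_Column] = []
    d = len(structure.variables)
    for step in range(d - 1):
        t_max = d - 1 - step
        top = [(t, e) for t, e in remaining if t == t_max]
        if len(top) != 1:
            raise StructureError(f"expected a single edge at tree {t_max}, found {len(top)}")
        x = min(top[0][1].conditioned)
        entries = []
        for t in range(t_max, 0, -1):
            cands = [(tt, e) for tt, e in remaining if tt == t and x in e.conditioned]
            if len(cands) != 1:
                raise StructureError(
                    f"variable {x!r} is conditioned in {len(cands)} edges of tree {t}; "
                    f"structure is not a regular vine"
                )
            entries.append(cands[0])
            remaining.remove(cands[0])
        entries.reverse()  # ascending tree level
        # matrix property: conditioning sets are nested unions of lower partners
        partners = []
        for t, e in entries:
            if e.conditioning != frozenset(partners):
                raise StructureError(f"edge {e.label()} breaks the nested-conditioning property")
            a, b = e.conditioned
            partners.append(b if a == x else a)
        columns.append(_Column(variable=x, entries=entries))
        variables.discard(x)
    columns.append(_Column(variable=variables.pop(), entries=[]))
    return columns


def _rosenblatt_inverse(model: VineCopulaModel, W: np.ndarray) -> dict[str, np.ndarray]:
    """Map iid uniforms W (n x d) to dependent uniforms per variable."""
    columns = peel_columns(model.structure)
    n = W.shape[0]
    cache: dict[tuple, np.ndarray] = {}
    U: dict[str, np.ndarray] = {}
    for ci in range(len(columns) - 1, -1, -1):
        colspec = columns[ci]
        x = colspec.variable
        u = W[:, ci].copy()
        # backward pass: w -> F_x through inverse h-functions, top tree first
        for _, e in reversed(colspec.entries):
            a, b = e.conditioned
            if x == a:
                cond = cache[(b, e.conditioning)]
                u = e.copula.hinv(u, cond, which=2)
            else:
                cond = cache[(a, e.conditioning)]
                u = e.copula.hinv(u, cond, which=1)
        U[x] = u
        cache[(x, frozenset())] = u
        # forward pass: cache both conditional margins of every edge
        for _, e in colspec.entries:
            a, b = e.conditioned
            ua = cache[(a, e.conditioning)]
            ub = cache[(b, e.conditioning)]
            cache[(a, e.conditioning | {b})] = e.copula.hfunc(ua, ub, which=2)
            cache[(b, e.conditioning | {a})] = e.copula.hfunc(ua, ub, which=1)
    return U


def simulate(model: VineCopulaModel, n: int, seed=None, rng: np.random.Generator | None = None) -> CovariateTable:
    """Simulate ``n`` complete covariate rows from the fitted model."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(seed)
    d = len(model.variables)
    W = rng.uniform(size=(n, d))
    if n == 0:
        Uvals = {v: np.empty(0) for v in model.variables}
    else:
        Uvals = _rosenblatt_inverse(model, W)
    data = {}
    for spec in model.columns:
        m = model.marginals[spec.name]
        u = Uvals[spec.name]
        if spec.kind == CONTINUOUS:
            data[spec.name] = m.quantile(u) if n else np.empty(0)
        else:
            order = model.categorical_order.get(spec.name, list(m.levels))
            data[spec.name] = decode_categorical(m.reordered(order), u)
    df = pd.DataFrame(data, columns=[c.name for c in model.columns])
    return CovariateTable(df=df, columns=list(model.columns), meta={"seed": seed, "n": n})


# ---------------------------------------------------------------------------
# subgroup simulation by rejection / filtering
# ---------------------------------------------------------------------------


def _filter_mask(table: CovariateTable, filters: dict) -> np.ndarray:
    mask = np.ones(table.n, dtype=bool)
    for name, crit in filters.items():
        spec = table.spec(name)
        vals = table.values(name)
        if spec.kind == CATEGORICAL:
            allowed = crit if isinstance(crit, (list, tuple, set)) else [crit]
            mask &= np.array([v in allowed for v in vals])
        else:
            lo, hi = crit  # inclusive numeric range; None = open side
            v = np.asarray(vals, dtype=float)
            if lo is not None:
                mask &= v >= lo
            if hi is not None:
                mask &= v <= hi
    return mask


def simulate_subgroup(
    model: VineCopulaModel,
    n: int,
    filters: dict,
    seed=None,
    max_attempts: int = 2_000_000,
    min_acceptance: float = 1e-4,
) -> CovariateTable:
    """Simulate from the full model and keep rows satisfying all filters.

    ``filters`` maps covariate name to either a category (or list of
    categories) or an inclusive ``(low, high)`` range for continuous
    covariates.  The empirical acceptance rate is recorded in
    ``table.meta['acceptance_rate']``.
    """
    for name in filters:
        if name not in model.variables:
            raise KeyError(f"filter references unknown covariate {name!r}")
    rng = np.random.default_rng(seed)
    kept: list[pd.DataFrame] = []
    n_kept = 0
    attempts = 0
    batch = max(4 * n, 1024)
    while n_kept < n:
        if attempts >= max_attempts:
            rate = n_kept / attempts if attempts else 0.0
            if rate < min_acceptance or n_kept == 0:
                raise InfeasibleFilterError(
                    f"acceptance rate {rate:.2e} after {attempts} attempts; "
                    f"filters appear infeasible: {filters}"
                )
            break
        batch = min(batch, max_attempts - attempts)
        t = simulate(model, batch, rng=rng)
        mask = _filter_mask(t, filters)
        kept.append(t.df.loc[mask])
        n_kept += int(mask.sum())
        attempts += batch
        batch *= 2  # geometric growth toward rare subgroups
    df = pd.concat(kept, ignore_index=True) if kept else pd.DataFrame()
    df = df.iloc[:n].reset_index(drop=True)
    if len(df) < n:
        raise InfeasibleFilterError(
            f"only {len(df)}/{n} rows accepted after {attempts} attempts: {filters}"
        )
    rate = n_kept / attempts if attempts else 1.0
    return CovariateTable(
        df=df,
        columns=list(model.columns),
        meta={"seed": seed, "filters": filters, "acceptance_rate": rate, "attempts": attempts},
    )


# ---------------------------------------------------------------------------
# derived covariates
# ---------------------------------------------------------------------------


def derive_bmi(
    table: CovariateTable,
    weight_col: str = "weight",
    height_col: str = "height",
    out_col: str = "bmi",
) -> CovariateTable:
    """Append BMI = weight[kg] / (height[cm]/100)^2."""
    w = np.asarray(table.values(weight_col), dtype=float)
    h = np.asarray(table.values(height_col), dtype=float)
    if np.nanmin(h) <= 0:
        raise ValueError("height must be strictly positive to derive BMI")
    bmi = w / (h / 100.0) ** 2
    df = table.df.copy()
    df[out_col] = bmi
    cols = list(table.columns) + [ColumnSpec(name=out_col, kind=CONTINUOUS, unit="kg/m^2")]
    return CovariateTable(df=df, columns=cols, weight_column=table.weight_column, meta=dict(table.meta))
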