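"""Vine copula structure selection and sequential estimation.

The d-dimensional dependence structure is factorized into d-1 nested trees of
bivariate (conditional) copulas.  Tree 1 pairs the variables themselves; each
later tree pairs edges of the previous tree that share a node (the proximity
condition).  Trees are selected greedily: a maximum spanning tree on the
absolute empirical Kendall's tau of the (conditional) pseudo-observations,
after which each selected edge gets the AIC-best parametric pair copula and
its h-functions propagate the conditioning to the next tree.

Missing data are handled per edge: a pair copula is fitted on the rows that
are complete for everything the edge conditions on, and rows with missing
inputs simply propagate missing conditional pseudo-observations upward.

Categorical covariates enter through a randomized PIT whose level ordering
matters; ``fit_vine_with_categorical`` searches all level orderings (sharing
one jitter realization so candidate likelihoods are comparable) and keeps the
ordering with the lowest AIC.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import marginals as mg
from .bicop import DEFAULT_FAMILY_SET, BivariateCopula, fit_bicop
from .marginals import EstimationError, MarginalModel
from .table import CATEGORICAL, CONTINUOUS, ColumnSpec, CovariateTable

log = logging.getLogger(__name__)

MIN_PAIR_N = 20


class StructureError(RuntimeError):
    """Raised when no valid spanning tree exists on the admissible graph."""


# ---------------------------------------------------------------------------
# structure types
# ---------------------------------------------------------------------------


@dataclass
class VineEdge:
    """One pair copula: conditioned pair (a, b) given conditioning set."""

    conditioned: tuple[str, str]  # lexicographically sorted
    conditioning: frozenset
    copula: BivariateCopula | None = None
    tau_emp: float = 0.0
    n_complete: int = 0

    @property
    def constraint(self) -> frozenset:
        return frozenset(self.conditioned) | self.conditioning

    def label(self) -> str:
        a, b = self.conditioned
        if self.conditioning:
            return f"{a},{b}|{','.join(sorted(self.conditioning))}"
        return f"{a},{b}"

    def to_dict(self) -> dict:
        return {
            "conditioned": list(self.conditioned),
            "conditioning": sorted(self.conditioning),
            "copula": self.copula.to_dict() if self.copula else None,
            "tau_emp": float(self.tau_emp),
            "n_complete": int(self.n_complete),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VineEdge":
        return cls(
            conditioned=tuple(d["conditioned"]),
            conditioning=frozenset(d["conditioning"]),
            copula=BivariateCopula.from_dict(d["copula"]) if d.get("copula") else None,
            tau_emp=float(d.get("tau_emp", 0.0)),
            n_complete=int(d.get("n_complete", 0)),
        )


@dataclass
class VineStructure:
    variables: list[str]
    trees: list[list[VineEdge]]

    def validate(self) -> None:
        """Check edge counts, acyclicity/connectedness and proximity."""
        d = len(self.variables)
        if len(self.trees) != d - 1:
            raise StructureError(f"expected {d - 1} trees, found {len(self.trees)}")
        prev_nodes: list[frozenset] = [frozenset([v]) for v in self.variables]
        for t, tree in enumerate(self.trees, start=1):
            if len(tree) != d - t:
                raise StructureError(f"tree {t} has {len(tree)} edges, expected {d - t}")
            parent = {n: n for n in prev_nodes}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for e in tree:
                if len(e.conditioning) != t - 1:
                    raise StructureError(f"edge {e.label()} in tree {t} has wrong conditioning size")
                # proximity: constraint must be union of two previous nodes sharing all but one var
                ends = [n for n in prev_nodes if n <= e.constraint and len(e.constraint - n) == 1]
                pair = [n for n in ends if len(n) == t]
                if len(pair) != 2:
                    raise StructureError(f"edge {e.label()} violates the proximity condition")
                ra, rb = find(pair[0]), find(pair[1])
                if ra == rb:
                    raise StructureError(f"tree {t} contains a cycle at {e.label()}")
                parent[ra] = rb
            prev_nodes = [e.constraint for e in tree]

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "trees": [[e.to_dict() for e in tree] for tree in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VineStructure":
        return cls(
            variables=list(d["variables"]),
            trees=[[VineEdge.from_dict(e) for e in tree] for tree in d["trees"]],
        )


@dataclass
class VineCopulaModel:
    structure: VineStructure
    marginals: dict[str, MarginalModel]
    columns: list[ColumnSpec]
    categorical_order: dict[str, list] = field(default_factory=dict)
    loglik: float = 0.0
    weighted: bool = False
    n_fit: int = 0
    pit_seed: int = 0
    truncation: int | None = None
    n_candidates: int = 1  # categorical ordering search bookkeeping

    @property
    def n_params(self) -> int:
        return sum(e.copula.n_params for tree in self.structure.trees for e in tree if e.copula)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def variables(self) -> list[str]:
        return self.structure.variables

    def first_tree_edges(self) -> list[VineEdge]:
        return self.structure.trees[0]

    def summary(self) -> str:
        lines = [
            f"vine copula on {len(self.variables)} covariates "
            f"(n={self.n_fit}, loglik={self.loglik:.1f}, aic={self.aic:.1f}, "
            f"params={self.n_params}, weighted={self.weighted})",
            "first tree:",
        ]
        for e in self.first_tree_edges():
            c = e.copula
            lines.append(
                f"  {e.label():<28s} {c.family:>12s} rot{c.rotation:<4d} "
                f"tau={c.tau():+.3f}  (empirical {e.tau_emp:+.3f}, n={e.n_complete})"
            )
        for cov, order in self.categorical_order.items():
            lines.append(f"level order for {cov}: {list(order)}")
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "vinepop-model",
            "version": 1,
            "structure": self.structure.to_dict(),
            "marginals": {k: m.to_dict() for k, m in sorted(self.marginals.items())},
            "columns": [c.to_dict() for c in self.columns],
            "categorical_order": {k: list(v) for k, v in sorted(self.categorical_order.items())},
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "weighted": self.weighted,
            "n_fit": int(self.n_fit),
            "pit_seed": int(self.pit_seed),
            "truncation": self.truncation,
            "n_candidates": int(self.n_candidates),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VineCopulaModel":
        return cls(
            structure=VineStructure.from_dict(d["structure"]),
            marginals={k: MarginalModel.from_dict(m) for k, m in d["marginals"].items()},
            columns=[ColumnSpec.from_dict(c) for c in d["columns"]],
            categorical_order={k: list(v) for k, v in d.get("categorical_order", {}).items()},
            loglik=float(d["loglik"]),
            weighted=bool(d.get("weighted", False)),
            n_fit=int(d.get("n_fit", 0)),
            pit_seed=int(d.get("pit_seed", 0)),
            truncation=d.get("truncation"),
            n_candidates=int(d.get("n_candidates", 1)),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "VineCopulaModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# maximum spanning tree (deterministic Kruskal)
# ---------------------------------------------------------------------------


def _kruskal_max(nodes, weighted_edges):
    """Maximum spanning tree on explicit edges [(w, a, b), ...].

    Deterministic: edges sorted by weight descending then by the string keys
    of their endpoints.  Raises StructureError if the graph is disconnected.
    """
    keys = {n: i for i, n in enumerate(nodes)}
    order = sorted(
        weighted_edges,
        key=lambda e: (-e[0], str(e[1]), str(e[2])),
    )
    parent = list(range(len(nodes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    chosen = []
    for w, a, b in order:
        ra, rb = find(keys[a]), find(keys[b])
        if ra != rb:
            parent[ra] = rb
            chosen.append((a, b))
            if len(chosen) == len(nodes) - 1:
                return chosen
    raise StructureError("admissible graph is disconnected; no spanning tree exists")


def select_tree(nodes, pairwise_weights) -> list[tuple]:
    """Spanning tree maximizing total weight.

    ``pairwise_weights`` is a symmetric (k x k) matrix aligned with ``nodes``
    (entries must be finite and nonnegative) or a dict {(a, b): weight}.
    """
    nodes = list(nodes)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes")
    edges = []
    if isinstance(pairwise_weights, dict):
        for (a, b), w in pairwise_weights.items():
            edges.append((float(w), a, b))
    else:
        W = np.asarray(pairwise_weights, dtype=float)
        if W.shape != (len(nodes), len(nodes)):
            raise ValueError("weight matrix does not match node count")
        if not np.all(np.isfinite(W)):
            raise ValueError("weights must be finite")
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                edges.append((float(W[i, j]), nodes[i], nodes[j]))
    return _kruskal_max(nodes, edges)


# ---------------------------------------------------------------------------
# pseudo-observations
# ---------------------------------------------------------------------------


def _fit_all_marginals(table: CovariateTable, weights, categorical_order):
    models: dict[str, MarginalModel] = {}
    for spec in table.columns:
        vals = table.values(spec.name)
        models[spec.name] = mg.fit_marginal(
            vals,
            weights=weights,
            log_scale=spec.log_scale,
            kind=spec.kind,
            name=spec.name,
            level_order=categorical_order.get(spec.name),
        )
        if spec.kind == CONTINUOUS and models[spec.name].n_used < 10:
            raise EstimationError(f"covariate {spec.name!r} has too few values")
    return models


def _categorical_jitters(table: CovariateTable, pit_seed: int) -> dict[str, np.ndarray]:
    """One uniform jitter per row per categorical column, derived from pit_seed.

    The jitter depends only on (pit_seed, column name), never on the level
    ordering, so ordering-search candidates see identical randomization.
    """
    jitters = {}
    for name in table.categorical:
        ss = np.random.SeedSequence([pit_seed, abs(hash(name)) % (2**31)])
        jitters[name] = np.random.default_rng(ss).uniform(size=table.n)
    return jitters


def _pseudo_observations(table, models, jitters):
    U = np.full((table.n, len(table.covariates)), np.nan)
    for j, name in enumerate(table.covariates):
        m = models[name]
        if m.kind == CONTINUOUS:
            vals = table.values(name)
            ok = ~np.isnan(vals)
            col = np.full(table.n, np.nan)
            col[ok] = m.pit(vals[ok])
            U[:, j] = col
        else:
            U[:, j] = mg.pit_categorical_jittered(m, list(table.values(name)), jitters[name])
    return U


def _pair_tau(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 2:
        return 0.0, n
    t = stats.kendalltau(x[ok], y[ok]).statistic
    return (0.0 if not np.isfinite(t) else float(t)), n


# ---------------------------------------------------------------------------
# sequential vine fitting
# ---------------------------------------------------------------------------


def fit_vine(
    table: CovariateTable,
    family_set: list[str] | None = None,
    weights: np.ndarray | None = None,
    truncation: int | None = None,
    pit_seed: int = 0,
    categorical_order: dict[str, list] | None = None,
) -> VineCopulaModel:
    """Fit marginals, select the tree sequence by MST on |Kendall's tau| of
    (conditional) pseudo-observations, and estimate AIC-best pair copulas.

    ``truncation`` limits copula estimation to the first so-many trees; the
    remaining structure is still selected but carries independence copulas.
    """
    if len(table.covariates) < 2:
        raise ValueError("need at least 2 covariates")
    if family_set is None:
        family_set = DEFAULT_FAMILY_SET
    categorical_order = dict(categorical_order or {})
    if weights is None:
        weights = table.weights

    models = _fit_all_marginals(table, weights, categorical_order)
    for name in table.categorical:
        categorical_order.setdefault(name, list(models[name].levels))
    jitters = _categorical_jitters(table, pit_seed)
    U = _pseudo_observations(table, models, jitters)

    d = len(table.covariates)
    names = list(table.covariates)
    col = {n: U[:, j] for j, n in enumerate(names)}

    # node state: for tree 1 a node is a variable; afterwards a node is a
    # previous edge.  cond_data[node][var] = F(var | other vars of the node).
    nodes: list = list(names)
    cond_data: dict = {n: {n: col[n]} for n in names}
    node_constraint: dict = {n: frozenset([n]) for n in names}
    node_ends: dict = {n: frozenset() for n in names}  # endpoints in previous tree

    trees: list[list[VineEdge]] = []
    total_ll = 0.0
    for t in range(1, d):
        # admissible pairs + weights
        weighted_edges = []
        pair_info = {}
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                na, nb = nodes[i], nodes[j]
                if t > 1 and not (node_ends[na] & node_ends[nb]):
                    continue  # proximity: must join edges sharing a node
                ca, cb = node_constraint[na], node_constraint[nb]
                new_conditioning = ca & cb
                sym = sorted(ca ^ cb)
                if len(sym) != 2:
                    continue
                va = sym[0] if sym[0] in ca else sym[1]
                vb = sym[0] if sym[0] in cb else sym[1]
                xa = cond_data[na][va]
                xb = cond_data[nb][vb]
                tau, n_ok = _pair_tau(xa, xb)
                weighted_edges.append((abs(tau), na, nb))
                pair_info[(na, nb)] = (va, vb, new_conditioning, tau, n_ok)
        chosen = _kruskal_max(nodes, weighted_edges)

        tree_edges = []
        for na, nb in chosen:
            if (na, nb) not in pair_info:
                na, nb = nb, na
            va, vb, conditioning, tau, n_ok = pair_info[(na, nb)]
            a, b = sorted([va, vb])
            xa = cond_data[na][va]
            xb = cond_data[nb][vb]
            xu, xv = (xa, xb) if a == va else (xb, xa)  # copula args ordered (a, b)
            ok = ~(np.isnan(xu) | np.isnan(xv))
            if truncation is not None and t > truncation:
                cop = BivariateCopula("independence", 0, [], loglik=0.0, n_fit=int(ok.sum()))
            else:
                w_ok = None if weights is None else np.asarray(weights, float)[ok]
                cop = fit_bicop(xu[ok], xv[ok], weights=w_ok, family_set=family_set)
            edge = VineEdge(
                conditioned=(a, b),
                conditioning=conditioning,
                copula=cop,
                tau_emp=tau,
                n_complete=int(ok.sum()),
            )
            total_ll += cop.loglik
            # propagate conditional pseudo-observations (NaN rows stay NaN)
            out_a = np.full(table.n, np.nan)
            out_b = np.full(table.n, np.nan)
            both = ~(np.isnan(xu) | np.isnan(xv))
            out_a[both] = cop.hfunc(xu[both], xv[both], which=2)  # F(a | b, S)
            out_b[both] = cop.hfunc(xu[both], xv[both], which=1)  # F(b | a, S)
            cond_data[edge_key(edge)] = {a: out_a, b: out_b}
            node_constraint[edge_key(edge)] = edge.constraint
            node_ends[edge_key(edge)] = frozenset([na, nb])
            tree_edges.append(edge)
        # deterministic order inside each tree
        tree_edges.sort(key=lambda e: e.label())
        trees.append(tree_edges)
        nodes = [edge_key(e) for e in tree_edges]

    structure = VineStructure(variables=names, trees=trees)
    structure.validate()
    return VineCopulaModel(
        structure=structure,
        marginals=models,
        columns=list(table.columns),
        categorical_order=categorical_order,
        loglik=total_ll,
        weighted=weights is not None,
        n_fit=table.n,
        pit_seed=pit_seed,
        truncation=truncation,
    )


def edge_key(e: VineEdge) -> tuple:
    return ("edge", e.conditioned, tuple(sorted(e.conditioning)))


def fit_vine_with_categorical(
    table: CovariateTable,
    categorical_covariate: str,
    family_set: list[str] | None = None,
    weights: np.ndarray | None = None,
    pit_seed: int = 0,
    truncation: int | None = None,
) -> VineCopulaModel:
    """Search all level orderings of one categorical covariate by AIC.

    One vine is fitted per distinct ordering (k! candidates, sharing the PIT
    jitter realization so likelihoods are comparable); the model with the
    lowest AIC is returned, with the chosen ordering recorded.
    """
    spec = table.spec(categorical_covariate)
    if spec.kind != CATEGORICAL:
        raise ValueError(f"{categorical_covariate!r} is not categorical")
    vals = [v for v in table.values(categorical_covariate) if not _is_missing(v)]
    levels = sorted(set(vals), key=str)
    k = len(levels)
    if k > 7:
        raise ValueError(
            f"{categorical_covariate!r} has {k} levels; an exhaustive ordering search "
            f"needs k! fits and is refused for k > 7 - pre-specify an order via "
            f"fit_vine(categorical_order=...) instead"
        )
    best = None
    n_cand = 0
    for order in itertools.permutations(levels):
        m = fit_vine(
            table,
            family_set=family_set,
            weights=weights,
            truncation=truncation,
            pit_seed=pit_seed,
            categorical_order={categorical_covariate: list(order)},
        )
        n_cand += 1
        if best is None or m.aic < best.aic - 1e-12:
            best = m
    best.n_candidates = n_cand
    log.info(
        "ordering search over %d candidates for %r: chose %s (aic=%.1f)",
        n_cand, categorical_covariate, best.categorical_order[categorical_covariate], best.aic,
    )
    return best


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


# ---------------------------------------------------------------------------
# evaluation of a fitted vine on (new) data
# ---------------------------------------------------------------------------


def loglik_vine(model: VineCopulaModel, table: CovariateTable) -> float:
    """Sum of per-edge copula log-densities on propagated pseudo-observations."""
    if set(table.covariates) != set(model.variables):
        raise ValueError(
            f"table covariates {sorted(table.covariates)} do not match model "
            f"variables {sorted(model.variables)}"
        )
    jitters = _categorical_jitters(table, model.pit_seed)
    U = _pseudo_observations(table, model.marginals, jitters)
    col = {n: U[:, j] for j, n in enumerate(table.covariates)}
    cond_data = {frozenset([n]): {n: col[n]} for n in model.variables}
    total = 0.0
    for tree in model.structure.trees:
        for e in tree:
            a, b = e.conditioned
            xa = cond_data[e.constraint - {b}][a]
            xb = cond_data[e.constraint - {a}][b]
            ok = ~(np.isnan(xa) | np.isnan(xb))
            total += float(np.sum(e.copula.logpdf(xa[ok], xb[ok])))
            out_a = np.full(len(xa), np.nan)
            out_b = np.full(len(xa), np.nan)
            out_a[ok] = e.copula.hfunc(xa[ok], xb[ok], which=2)
            out_b[ok] = e.copula.hfunc(xa[ok], xb[ok], which=1)
            cond_data[e.constraint] = {a: out_a, b: out_b}
    return total


def aic_vine(model: VineCopulaModel) -> float:
    return model.aic
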