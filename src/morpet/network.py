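"""Covariance-network group comparison with network-based-statistic correction.

Each group's subjects x regions BP_ND matrix is turned into an inter-regional
Pearson correlation matrix, Fisher z-transformed, and compared edge-wise
between groups (statistic z_A - z_B) by permuting group labels and
recomputing both matrices under every relabelling.  Family-wise error over
the n(n-1)/2 partially dependent edges is controlled with the network-based
statistic (NBS): edges supra-threshold at the primary alpha form a graph, and
the size (edge count) of each connected component is referred to the
permutation null of the maximal component size.

The NBS null reuses the same relabellings as the edge test, so the component
null is consistent with the edge p-values; per-permutation edge "p-values"
are obtained by ranking each permuted statistic within the permutation
ensemble.  Permutation p-values carry +1 smoothing and can never be zero.
When the requested permutation count exceeds the number of distinct
relabellings the test switches to exhaustive enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "EdgeStatSet",
    "NBSComponent",
    "NBSResult",
    "NetworkReport",
    "count_edges",
    "correlation_matrix",
    "fisher_z",
    "edge_permutation_test",
    "nbs_correct",
    "run_network_comparison",
]

log = logging.getLogger(__name__)


def count_edges(n_regions: int) -> int:
    """Number of undirected region pairs, n(n-1)/2."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    return n_regions * (n_regions - 1) // 2


def correlation_matrix(bpnd_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation across subjects for every region pair.

    ``bpnd_matrix`` is subjects x regions.  Requires >= 3 subjects; a
    constant region column is an error naming the region.  The diagonal is 1
    by convention and excluded from all downstream edge analyses.
    """
    X = np.asarray(bpnd_matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("correlation matrix requires at least 3 subjects")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        names = list(bpnd_matrix.columns)
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant region column(s): {bad}")
    r = np.corrcoef(X.T)
    return pd.DataFrame(r, index=bpnd_matrix.columns, columns=bpnd_matrix.columns)


def fisher_z(r):
    """Fisher z-transform arctanh(r), with |r| clamped to 1 - 1e-12."""
    r = np.asarray(r, dtype=float)
    out = np.arctanh(np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12))
    return float(out) if out.ndim == 0 else out


@dataclass
class EdgeStatSet:
    """Edge-wise group-difference statistics and permutation p-values."""

    regions: list[str]
    edge_index: tuple[np.ndarray, np.ndarray]  # upper-triangle (i, j) indices
    observed_stat: np.ndarray                  # z_A - z_B per edge
    p_values: np.ndarray
    n_permutations: int
    seed: int | None
    direction: str                             # "greater" (A > B) or "two-sided"
    exhaustive: bool
    z_a: pd.DataFrame
    z_b: pd.DataFrame
    perm_stats: np.ndarray = field(repr=False, default=None)  # (n_perm, n_edges)

    @property
    def n_edges(self) -> int:
        return self.observed_stat.size

    def edges_frame(self) -> pd.DataFrame:
        i, j = self.edge_index
        names = np.asarray(self.regions)
        return pd.DataFrame({
            "region_i": names[i], "region_j": names[j],
            "z_a": self.z_a.to_numpy()[i, j], "z_b": self.z_b.to_numpy()[i, j],
            "stat": self.observed_stat, "p": self.p_values,
        })


def _z_upper(X: np.ndarray, iu) -> np.ndarray:
    return fisher_z(np.corrcoef(X.T)[iu])


def _directional(stat: np.ndarray, direction: str) -> np.ndarray:
    return np.abs(stat) if direction == "two-sided" else stat


def edge_permutation_test(
    bpnd_a: pd.DataFrame,
    bpnd_b: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int | None = None,
    direction: str = "greater",
) -> EdgeStatSet:
    """Permutation test of the per-edge Fisher-z difference z_A - z_B.

    Group labels are permuted across the pooled subjects and both correlation
    matrices recomputed under every relabelling.  One-sided ("greater",
    A > B, the default) or two-sided p-values with +1 smoothing:
    p = (1 + #{perm >= observed}) / (n_perm + 1).  If the requested count
    exceeds the number of distinct relabellings C(n, n_a), all relabellings
    are enumerated instead (the identity labelling is one of them, so no
    extra smoothing is applied).
    """
    if direction not in ("greater", "two-sided"):
        raise ValueError(f"direction must be 'greater' or 'two-sided', got {direction!r}")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if list(bpnd_a.columns) != list(bpnd_b.columns):
        raise ValueError("both groups must cover the same regions in the same order")
    na, nb = len(bpnd_a), len(bpnd_b)
    if na + nb < 6:
        raise ValueError("permutation test requires combined n >= 6")
    regions = list(bpnd_a.columns)
    R = len(regions)
    iu = np.triu_indices(R, 1)
    # validate (and keep for reporting) the observed matrices
    z_a = fisher_z(correlation_matrix(bpnd_a).to_numpy())
    z_b = fisher_z(correlation_matrix(bpnd_b).to_numpy())
    X = np.vstack([np.asarray(bpnd_a, dtype=float), np.asarray(bpnd_b, dtype=float)])
    observed = z_a[iu] - z_b[iu]

    n_distinct = comb(na + nb, na)
    exhaustive = n_distinct <= n_permutations
    if exhaustive:
        log.info("switching to exhaustive enumeration of %d relabellings", n_distinct)
        splits = [np.array(c) for c in combinations(range(na + nb), na)]
    else:
        rng = np.random.default_rng(seed)
        splits = [rng.permutation(na + nb)[:na] for _ in range(n_permutations)]

    all_idx = np.arange(na + nb)
    perm_stats = np.empty((len(splits), iu[0].size), dtype=np.float32)
    for k, idx_a in enumerate(splits):
        mask = np.zeros(na + nb, dtype=bool)
        mask[idx_a] = True
        perm_stats[k] = _z_upper(X[mask], iu) - _z_upper(X[all_idx[~mask]], iu)

    # compare at float32 so the identity relabelling (exhaustive mode) ties
    # with the observed statistic exactly
    obs_d = _directional(observed.astype(np.float32), direction)
    perm_d = _directional(perm_stats, direction)
    count_ge = (perm_d >= obs_d).sum(axis=0)
    if exhaustive:
        p = count_ge / len(splits)  # identity labelling is included in the count
    else:
        p = (1.0 + count_ge) / (len(splits) + 1.0)

    return EdgeStatSet(
        regions=regions, edge_index=iu, observed_stat=observed, p_values=p,
        n_permutations=len(splits), seed=seed, direction=direction,
        exhaustive=exhaustive,
        z_a=pd.DataFrame(z_a, index=regions, columns=regions),
        z_b=pd.DataFrame(z_b, index=regions, columns=regions),
        perm_stats=perm_stats,
    )


@dataclass
class NBSComponent:
    regions: list[str]
    edges: list[tuple[str, str]]
    n_edges: int
    p_corrected: float


@dataclass
class NBSResult:
    primary_threshold: float
    supra_threshold_edges: list[tuple[str, str]]
    components: list[NBSComponent]          # sorted by size, descending
    max_size_null: np.ndarray = field(repr=False, default=None)
    n_permutations: int = 0


class _UnionFind:
    """Minimal union-find over region indices for component extraction."""

    def __init__(self):
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        p = self.parent.setdefault(x, x)
        while p != self.parent[p]:
            self.parent[p] = self.parent[self.parent[p]]
            p = self.parent[p]
        self.parent[x] = p
        return p

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _max_component_edges(ei: np.ndarray, ej: np.ndarray) -> int:
    if ei.size == 0:
        return 0
    uf = _UnionFind()
    for a, b in zip(ei, ej):
        uf.union(int(a), int(b))
    counts: dict[int, int] = {}
    for a in ei:
        root = uf.find(int(a))
        counts[root] = counts.get(root, 0) + 1
    return max(counts.values())


def _observed_components(ei, ej, regions) -> list[tuple[list[str], list[tuple[str, str]]]]:
    uf = _UnionFind()
    for a, b in zip(ei, ej):
        uf.union(int(a), int(b))
    by_root: dict[int, list[int]] = {}
    for k, (a, b) in enumerate(zip(ei, ej)):
        by_root.setdefault(uf.find(int(a)), []).append(k)
    out = []
    for edge_ids in by_root.values():
        nodes = sorted({int(ei[k]) for k in edge_ids} | {int(ej[k]) for k in edge_ids})
        edges = [(regions[int(ei[k])], regions[int(ej[k])]) for k in edge_ids]
        out.append(([regions[n] for n in nodes], edges))
    return out


def nbs_correct(
    edge_stats: EdgeStatSet,
    primary_threshold: float = 0.05,
    n_permutations: int | None = None,
    seed: int | None = None,
) -> NBSResult:
    """Network-based-statistic component correction.

    Supra-threshold edges (edge permutation p < primary threshold) form a
    graph over regions; each connected component's size, measured as its
    number of supra-threshold edges (extent), is referred to the permutation
    null distribution of the maximal component size.  The null reuses the
    relabellings of ``edge_stats`` (``n_permutations``/``seed`` are accepted
    for interface symmetry but must match when given); per-permutation edge
    p-values come from ranking each permuted statistic within the ensemble.
    An empty supra-threshold set is a valid, empty result.
    """
    if not (0.0 < primary_threshold < 1.0):
        raise ValueError("primary threshold must lie in (0, 1)")
    if edge_stats.perm_stats is None:
        raise ValueError("edge_stats must retain perm_stats for NBS correction")
    if n_permutations is not None and n_permutations != edge_stats.n_permutations:
        raise ValueError("NBS reuses the edge-test relabellings; n_permutations must match")
    if seed is not None and edge_stats.seed is not None and seed != edge_stats.seed:
        raise ValueError("NBS reuses the edge-test relabellings; seed must match")

    P = edge_stats.n_permutations
    regions = edge_stats.regions
    iu_i, iu_j = edge_stats.edge_index
    alpha = primary_threshold

    supra_obs = edge_stats.p_values < alpha
    # per-permutation p-values by descending rank within the ensemble:
    # p_k = #{j: S_j >= S_k} / (P + 1)   (exhaustive: / P), exchangeable with
    # the observed p, so component-level FWER is controlled.
    S = _directional(edge_stats.perm_stats, edge_stats.direction)
    order = np.argsort(np.argsort(S, axis=0, kind="stable"), axis=0)  # 0 = smallest
    count_ge = P - order
    denom = P if edge_stats.exhaustive else P + 1
    supra_perm = (count_ge / denom) < alpha

    null_max = np.fromiter(
        (_max_component_edges(iu_i[supra_perm[k]], iu_j[supra_perm[k]]) for k in range(P)),
        dtype=int, count=P,
    )

    ei, ej = iu_i[supra_obs], iu_j[supra_obs]
    supra_edges = [(regions[int(a)], regions[int(b)]) for a, b in zip(ei, ej)]
    comps = []
    for nodes, edges in _observed_components(ei, ej, regions):
        size = len(edges)
        ge = int(np.sum(null_max >= size))
        p_corr = ge / P if edge_stats.exhaustive else (1 + ge) / (P + 1)
        comps.append(NBSComponent(regions=nodes, edges=edges, n_edges=size,
                                  p_corrected=float(p_corr)))
    comps.sort(key=lambda c: c.n_edges, reverse=True)
    return NBSResult(primary_threshold=alpha, supra_threshold_edges=supra_edges,
                     components=comps, max_size_null=null_max, n_permutations=P)


@dataclass
class NetworkReport:
    """End-to-end covariance-network comparison at one or more thresholds."""

    n_regions: int
    n_edges: int
    edge_stats: EdgeStatSet
    nbs: dict[float, NBSResult]
    n_significant_edges: dict[float, int]

    def significant_components(self, alpha: float, level: float = 0.05) -> list[NBSComponent]:
        return [c for c in self.nbs[alpha].components if c.p_corrected < level]


def run_network_comparison(
    bpnd: pd.DataFrame,
    groups: pd.Series,
    alphas: tuple[float, ...] = (0.05, 0.001),
    n_permutations: int = 10_000,
    seed: int = 0,
    direction: str = "greater",
) -> NetworkReport:
    """Full covariance-network group comparison.

    ``bpnd`` is subjects x regions; ``groups`` maps subject id to
    "patient"/"control".  Patients are group A (so "greater" tests for
    elevated patient covariance).  Runs the edge permutation test once and
    applies NBS correction at every primary threshold in ``alphas``.
    Deterministic given the seed.
    """
    groups = groups.reindex(bpnd.index)
    if groups.isna().any():
        raise ValueError("groups must label every subject in the BP_ND matrix")
    a = bpnd.loc[groups == "patient"]
    b = bpnd.loc[groups == "control"]
    es = edge_permutation_test(a, b, n_permutations=n_permutations, seed=seed,
                               direction=direction)
    nbs = {alpha: nbs_correct(es, primary_threshold=alpha) for alpha in alphas}
    nsig = {alpha: int(np.sum(es.p_values < alpha)) for alpha in alphas}
    return NetworkReport(n_regions=len(es.regions), n_edges=es.n_edges,
                         edge_stats=es, nbs=nbs, n_significant_edges=nsig)
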