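"""Network-based statistic (NBS) permutation inference.

NBS controls the familywise error of edgewise group comparisons at the level
of *connected components*: edges whose group statistic exceeds a fixed
threshold form a graph on the regions, and each connected component's size
(edge count, the "extent" statistic) is compared with the distribution of the
maximum component size under whole-subject group-label permutations.  The
permutation scheme keeps every subject's edge vector intact, preserving the
dependence between edges.

Component p-values use the add-one convention,
``p = (1 + #{null >= observed}) / (K + 1)``, so p is never zero and is
bounded below by ``1/(K+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _cc
from scipy import stats as sps

__all__ = [
    "Component",
    "NBSResult",
    "suprathreshold_components",
    "nbs_permutation_test",
    "f_threshold_from_anova",
]


@dataclass
class Component:
    edges: list[tuple[int, int]]
    nodes: list[int]
    p_value: float | None = None

    @property
    def size(self) -> int:
        return len(self.edges)


@dataclass
class NBSResult:
    stat_threshold: float
    alpha: float
    n_permutations: int
    observed_components: list[Component]
    null_max_sizes: np.ndarray
    seed: int | None
    significant: list[Component] = field(init=False)

    def __post_init__(self) -> None:
        self.significant = [
            c for c in self.observed_components if c.p_value is not None and c.p_value <= self.alpha
        ]

    @property
    def min_p(self) -> float:
        if not self.observed_components:
            return 1.0
        return min(c.p_value for c in self.observed_components)


def suprathreshold_components(stat_matrix: np.ndarray, threshold: float) -> list[Component]:
    """Connected components of the graph of edges with stat >= threshold.

    Components are sorted by size descending, ties broken by smallest member
    region index; isolated nodes are not components.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    A = np.asarray(stat_matrix, dtype=float)
    R = A.shape[0]
    if A.shape != (R, R):
        raise ValueError("stat matrix must be square")
    iu, ju = np.triu_indices(R, k=1)
    with np.errstate(invalid="ignore"):
        keep = np.nan_to_num(A[iu, ju], nan=-np.inf) >= threshold
    ei, ej = iu[keep], ju[keep]
    if ei.size == 0:
        return []
    g = sparse.coo_matrix((np.ones(ei.size), (ei, ej)), shape=(R, R))
    n_comp, labels = _cc(g, directed=False)
    comps: dict[int, Component] = {}
    for a, b in zip(ei, ej):
        lab = labels[a]
        comps.setdefault(lab, Component(edges=[], nodes=[]))
        comps[lab].edges.append((int(a), int(b)))
    out = []
    for c in comps.values():
        c.nodes = sorted({n for e in c.edges for n in e})
        c.edges.sort()
        out.append(c)
    out.sort(key=lambda c: (-c.size, c.nodes[0]))
    return out


def _max_component_size(f_edges: np.ndarray, threshold: float, iu, ju, R: int) -> int:
    keep = f_edges >= threshold
    ei, ej = iu[keep], ju[keep]
    if ei.size == 0:
        return 0
    g = sparse.coo_matrix((np.ones(ei.size), (ei, ej)), shape=(R, R))
    _, labels = _cc(g, directed=False)
    counts = np.bincount(labels[ei], minlength=labels.max() + 1)
    return int(counts.max())


def _group_f(X: np.ndarray, onehot: np.ndarray, sizes: np.ndarray, sst: np.ndarray,
             total: np.ndarray, df1: int, df2: int) -> np.ndarray:
    """F per edge from precomputed totals; ``onehot`` is (k, N)."""
    gsums = onehot @ X  # (k, E)
    ssb = (gsums**2 / sizes[:, None]).sum(axis=0) - total**2 / X.shape[0]
    ssw = np.maximum(sst - ssb, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    return np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), F)


def nbs_permutation_test(
    z_by_group: Mapping[str, np.ndarray],
    stat_threshold: float,
    n_regions: int,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> NBSResult:
    """Max-component-size permutation test over whole-subject label shuffles.

    ``z_by_group`` maps group name to a subjects x edges array (``unique_pairs``
    edge order).  Edges undefined (NaN) for any subject are dropped from the
    graph.  The F statistic is recomputed per permutation for all edges
    jointly; per permutation the maximum suprathreshold component size is
    recorded.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations for usable resolution")
    groups = [np.asarray(g, dtype=float) for g in z_by_group.values()]
    X = np.vstack(groups)
    N, E = X.shape
    k = len(groups)
    sizes = np.array([g.shape[0] for g in groups], dtype=float)
    labels = np.repeat(np.arange(k), [g.shape[0] for g in groups])
    df1, df2 = k - 1, N - k

    valid = np.all(np.isfinite(X), axis=0)
    Xv = np.where(valid, X, 0.0)

    total = Xv.sum(axis=0)
    sst = (Xv**2).sum(axis=0) - total**2 / N

    # unique_pairs edge order is upper-triangular row-major, matching triu_indices
    iu, ju = np.triu_indices(n_regions, k=1)
    if iu.size != E:
        raise ValueError(f"{E} edges do not match {n_regions} regions (expected {iu.size})")

    def onehot_for(lab: np.ndarray) -> np.ndarray:
        M = np.zeros((k, N))
        M[lab, np.arange(N)] = 1.0
        return M

    F_obs = _group_f(Xv, onehot_for(labels), sizes, sst, total, df1, df2)
    F_obs = np.where(valid, F_obs, -np.inf)
    obs_matrix = np.full((n_regions, n_regions), -np.inf)
    obs_matrix[iu, ju] = F_obs
    obs_matrix[ju, iu] = F_obs
    observed = suprathreshold_components(obs_matrix, stat_threshold)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations, dtype=int)
    chunk = 200
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        onehots = np.zeros((b * k, N))
        for t in range(b):
            perm = rng.permutation(labels)
            onehots[t * k : (t + 1) * k][perm, np.arange(N)] = 1.0
        gsums = onehots @ Xv  # (b*k, E)
        for t in range(b):
            gs = gsums[t * k : (t + 1) * k]
            ssb = (gs**2 / sizes[:, None]).sum(axis=0) - total**2 / N
            ssw = np.maximum(sst - ssb, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                Fp = (ssb / df1) / (ssw / df2)
            Fp = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), Fp)
            Fp = np.where(valid, Fp, -np.inf)
            null_max[done + t] = _max_component_size(Fp, stat_threshold, iu, ju, n_regions)
        done += b

    for c in observed:
        c.p_value = float((1 + np.sum(null_max >= c.size)) / (n_permutations + 1))
    return NBSResult(
        stat_threshold=float(stat_threshold),
        alpha=alpha,
        n_permutations=n_permutations,
        observed_components=observed,
        null_max_sizes=null_max,
        seed=seed,
    )


def f_threshold_from_anova(anova, fallback_p: float = 0.001) -> float:
    """Edge-level F threshold mirroring "the minimum significant F".

    Returns the smallest F among FDR-significant edges; if no edge is
    significant, falls back to the parametric F quantile at ``fallback_p``
    for the table's degrees of freedom, so the NBS graph stays sparse under
    the null.
    """
    sig = anova.significant_edges()
    if sig.size:
        return float(np.nanmin(anova.F[sig]))
    return float(sps.f.isf(fallback_p, anova.df1, anova.df2))
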