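"""Connectome-based prediction of a continuous score from IDSCN edges.

The procedure follows the suprathreshold edge-selection style of
connectome-based predictive modelling: inside each outer cross-validation
fold, (1) features are min-max rescaled to [0, 1] using training-fold ranges,
(2) every edge's Pearson correlation with the training target is tested and
edges with p below the selection threshold are kept, (3) the survivors are
restricted to the largest connected component on the region graph, and
(4) a linear model (ridge grid searched by inner cross-validation; the grid
includes lambda = 0, i.e. plain least squares) is fitted on the component's
edges and applied to the held-out fold.

Model quality is the Pearson r between pooled out-of-fold predictions and
the observed scores, summarized across repeats (mean and percentile CI);
significance comes from re-running the whole cross-validation on permuted
targets.  Each edge accumulates a *selection-frequency weight* — the signed
fraction of folds in which it was selected (sign = majority sign of its
training-set correlation) — and thresholding |weight| yields consensus
positive/negative networks with per-region nodal degrees.

Every data-dependent choice (scaling ranges, selection, hyperparameter) is
recomputed from the training fold only; the held-out fold never leaks in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _cc
from scipy import stats as sps

__all__ = [
    "CVConfig",
    "EdgeWeightMap",
    "PredictionResult",
    "fold_edge_selection",
    "nbs_predict_cv",
    "threshold_edge_weights",
]


@dataclass(frozen=True)
class CVConfig:
    outer_folds: int = 10
    repeats: int = 10
    selection_p: float = 0.01
    n_permutations: int = 0  # 0 skips the permutation test; study-scale 10_000
    grid_steps: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2:
            raise ValueError("need at least 2 outer folds")
        if not 0 < self.selection_p < 1:
            raise ValueError("selection_p must lie in (0, 1)")

    @property
    def ridge_grid(self) -> np.ndarray:
        """lambda = 0 (ordinary least squares) plus log-spaced ridge penalties."""
        if self.grid_steps == 1:
            return np.array([0.0])
        return np.concatenate([[0.0], np.logspace(-2, 1, self.grid_steps - 1)])


@dataclass
class EdgeWeightMap:
    weights: np.ndarray  # signed selection frequency per edge, |w| <= 1
    threshold: float
    positive_edges: list[int]
    negative_edges: list[int]
    nodal_degree_positive: np.ndarray
    nodal_degree_negative: np.ndarray


@dataclass
class PredictionResult:
    predicted: np.ndarray  # pooled out-of-fold predictions, last repeat
    observed: np.ndarray
    r_per_repeat: np.ndarray
    r_mean: float
    r_ci: tuple[float, float]
    permutation_p: float | None
    weights: np.ndarray  # signed selection frequencies over all folds x repeats
    empty_folds: int
    seed: int


def _pearson_with_target(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column Pearson r of X with y, and its two-sided p-value."""
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.nan_to_num(np.clip(r, -1, 1))
    # t transform; guard |r| == 1
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * sps.t.sf(np.abs(t), n - 2)
    return r, p


def _largest_component_edges(edge_ids: np.ndarray, iu, ju, n_regions: int) -> np.ndarray:
    if edge_ids.size == 0:
        return edge_ids
    ei, ej = iu[edge_ids], ju[edge_ids]
    g = sparse.coo_matrix((np.ones(ei.size), (ei, ej)), shape=(n_regions, n_regions))
    _, labels = _cc(g, directed=False)
    counts = np.bincount(labels[ei], minlength=labels.max() + 1)
    best = np.argmax(counts)
    return edge_ids[labels[ei] == best]


def fold_edge_selection(
    train_features: np.ndarray,
    train_target: np.ndarray,
    selection_p: float,
    n_regions: int,
) -> np.ndarray:
    """Suprathreshold edge selection on a training fold.

    Edges whose Pearson correlation with the target has p < ``selection_p``
    are restricted to the largest connected component on the region graph;
    that component's edge indices are returned (possibly empty).
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_target, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 training subjects for edge selection")
    _, p = _pearson_with_target(X, y)
    cand = np.flatnonzero(p < selection_p)
    iu, ju = np.triu_indices(n_regions, k=1)
    return _largest_component_edges(cand, iu, ju, n_regions)


def _ridge_fit(Xtr: np.ndarray, ytr: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Closed-form ridge with unpenalized intercept."""
    Xm, ym = Xtr.mean(axis=0), ytr.mean()
    Xc, yc = Xtr - Xm, ytr - ym
    A = Xc.T @ Xc + lam * np.eye(Xtr.shape[1])
    beta = np.linalg.lstsq(A, Xc.T @ yc, rcond=None)[0]
    return beta, float(ym - Xm @ beta)


def _inner_grid_lambda(X: np.ndarray, y: np.ndarray, grid: np.ndarray, rng: np.random.Generator,
                       inner_folds: int = 5) -> float:
    n = len(y)
    folds = np.tile(np.arange(inner_folds), n // inner_folds + 1)[:n]
    folds = folds[rng.permutation(n)]
    mse = np.zeros(len(grid))
    for f in range(inner_folds):
        tr, te = folds != f, folds == f
        if te.sum() == 0 or tr.sum() < 3:
            continue
        for gi, lam in enumerate(grid):
            beta, b0 = _ridge_fit(X[tr], y[tr], lam)
            mse[gi] += ((X[te] @ beta + b0 - y[te]) ** 2).sum()
    return float(grid[int(np.argmin(mse))])


def nbs_predict_cv(
    features: np.ndarray,
    target: np.ndarray,
    cv: CVConfig,
    n_regions: int,
) -> PredictionResult:
    """Repeated k-fold cross-validated prediction with suprathreshold edge
    selection, returning pooled out-of-fold correlations and edge weights."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    n, E = X.shape
    if n < 2 * cv.outer_folds:
        raise ValueError("need at least 2 subjects per outer fold")
    rng = np.random.default_rng(cv.seed)

    r_reps, weights, pred_last, empty = _run_cv(X, y, cv, n_regions, rng)
    r_mean = float(np.mean(r_reps))
    r_ci = tuple(np.percentile(r_reps, [2.5, 97.5]))

    perm_p = None
    if cv.n_permutations:
        perm_rng = np.random.default_rng(rng.integers(0, 2**31))
        count = 0
        for _ in range(cv.n_permutations):
            yp = perm_rng.permutation(y)
            rp, _, _, _ = _run_cv(X, yp, cv, n_regions, perm_rng, repeats=1)
            if np.mean(rp) >= r_mean:
                count += 1
        perm_p = (1 + count) / (cv.n_permutations + 1)

    return PredictionResult(
        predicted=pred_last,
        observed=y,
        r_per_repeat=r_reps,
        r_mean=r_mean,
        r_ci=(float(r_ci[0]), float(r_ci[1])),
        permutation_p=perm_p,
        weights=weights,
        empty_folds=empty,
        seed=cv.seed,
    )


def _run_cv(
    X: np.ndarray,
    y: np.ndarray,
    cv: CVConfig,
    n_regions: int,
    rng: np.random.Generator,
    repeats: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    n, E = X.shape
    repeats = cv.repeats if repeats is None else repeats
    grid = cv.ridge_grid
    sel_count = np.zeros(E)
    sign_votes = np.zeros(E)
    total_folds = 0
    empty = 0
    r_reps = np.empty(repeats)
    pred = np.empty(n)
    for rep in range(repeats):
        folds = np.tile(np.arange(cv.outer_folds), n // cv.outer_folds + 1)[:n]
        folds = folds[rng.permutation(n)]
        for f in range(cv.outer_folds):
            tr, te = folds != f, folds == f
            ytr = y[tr]
            if np.ptp(ytr) == 0:  # constant training target: fold skipped
                pred[te] = ytr.mean()
                empty += 1
                total_folds += 1
                continue
            lo = X[tr].min(axis=0)
            span = np.maximum(X[tr].max(axis=0) - lo, 1e-300)
            Xtr = (X[tr] - lo) / span
            Xte = np.clip((X[te] - lo) / span, -np.inf, np.inf)
            sel = fold_edge_selection(Xtr, ytr, cv.selection_p, n_regions)
            total_folds += 1
            if sel.size == 0:
                pred[te] = ytr.mean()
                empty += 1
                continue
            rtr, _ = _pearson_with_target(Xtr[:, sel], ytr)
            sel_count[sel] += 1
            sign_votes[sel] += np.sign(rtr)
            lam = _inner_grid_lambda(Xtr[:, sel], ytr, grid, rng)
            beta, b0 = _ridge_fit(Xtr[:, sel], ytr, lam)
            pred[te] = Xte[:, sel] @ beta + b0
        if np.ptp(pred) == 0 or np.ptp(y) == 0:
            r_reps[rep] = 0.0
        else:
            r_reps[rep] = np.corrcoef(pred, y)[0, 1]
    freq = sel_count / max(total_folds, 1)
    sign = np.where(sign_votes < 0, -1.0, 1.0)  # ties break positive
    return r_reps, sign * freq, pred.copy(), empty


def threshold_edge_weights(
    weights: np.ndarray,
    threshold: float,
    n_regions: int,
) -> EdgeWeightMap:
    """Keep edges with |weight| > threshold, split by sign, with per-region
    nodal degrees per sign."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    w = np.asarray(weights, dtype=float)
    iu, ju = np.triu_indices(n_regions, k=1)
    pos = np.flatnonzero(w > threshold)
    neg = np.flatnonzero(-w > threshold)
    deg_p = np.zeros(n_regions, dtype=int)
    deg_n = np.zeros(n_regions, dtype=int)
    for e in pos:
        deg_p[iu[e]] += 1
        deg_p[ju[e]] += 1
    for e in neg:
        deg_n[iu[e]] += 1
        deg_n[ju[e]] += 1
    return EdgeWeightMap(
        weights=w,
        threshold=float(threshold),
        positive_edges=pos.tolist(),
        negative_edges=neg.tolist(),
        nodal_degree_positive=deg_p,
        nodal_degree_negative=deg_n,
    )
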