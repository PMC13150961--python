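"""Edgewise group statistics on IDSCN z scores.

Per edge (unique region pair) the three groups are compared with a one-way
fixed-effects ANOVA; the resulting p-values are adjusted across edges with
the Benjamini-Hochberg (BH) step-up procedure, and edges passing the FDR
threshold get pairwise pooled-variance t tests with a Bonferroni factor of 3
(the pairwise family), Cohen's d with normal-approximation confidence
intervals, and eta-squared effect sizes.

Effect-size identities used throughout (and testable directly against any
published F/t table):

    eta^2 = F * df1 / (F * df1 + df2)
    d     = t * sqrt(1/n1 + 1/n2)
    d CI  = d +/- 1.96 * sqrt((n1+n2)/(n1*n2) + d^2 / (2*(n1+n2-2)))

The eta^2 confidence interval has no printed-form identity; it is estimated
by a bias-corrected percentile bootstrap over subjects within groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EdgeAnovaTable",
    "PosthocTable",
    "edgewise_anova",
    "bh_fdr",
    "posthoc_pairwise",
    "eta_squared",
    "eta_squared_ci",
    "cohens_d_from_t",
    "cohens_d_ci",
    "bonferroni_threshold",
    "format_adjusted_p",
    "groups_from_stack",
    "tidy_edge_report",
]


def groups_from_stack(stack, edge_index) -> dict[str, np.ndarray]:
    """Split an IDSCN stack into per-group subject x edge z arrays."""
    flat = edge_index.extract(stack.z)
    out: dict[str, np.ndarray] = {}
    for g in dict.fromkeys(stack.group):
        out[g] = flat[stack.group == g]
    return out


@dataclass
class EdgeAnovaTable:
    F: np.ndarray
    df1: int
    df2: int
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    excluded: np.ndarray  # edges dropped because some subject's z was undefined
    q_threshold: float
    group_names: list[str]
    group_sizes: list[int]

    @property
    def n_edges(self) -> int:
        return self.F.size

    def significant_edges(self) -> np.ndarray:
        return np.flatnonzero(self.significant)


def edgewise_anova(
    z_by_group: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    q_threshold: float = 0.001,
) -> EdgeAnovaTable:
    """Vectorized per-edge one-way ANOVA across groups.

    ``z_by_group`` maps group name to a subjects x edges array of z scores.
    Edges with an undefined (NaN) value for any subject are excluded from
    testing and flagged in ``excluded``; BH adjustment runs over the tested
    edges only.
    """
    if isinstance(z_by_group, Mapping):
        names = list(z_by_group.keys())
        groups = [np.asarray(z_by_group[g], dtype=float) for g in names]
    else:
        groups = [np.asarray(g, dtype=float) for g in z_by_group]
        names = [f"group{i}" for i in range(len(groups))]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    sizes = [g.shape[0] for g in groups]
    if any(n < 2 for n in sizes):
        raise ValueError("every group needs at least 2 subjects")
    E = groups[0].shape[1]
    if any(g.shape[1] != E for g in groups):
        raise ValueError("all groups must cover the same edges")

    X = np.vstack(groups)
    N, k = X.shape[0], len(groups)
    excluded = np.any(~np.isfinite(X), axis=0)

    grand = X.mean(axis=0)
    ssb = np.zeros(E)
    ssw = np.zeros(E)
    for g in groups:
        m = g.mean(axis=0)
        ssb += g.shape[0] * (m - grand) ** 2
        ssw += ((g - m) ** 2).sum(axis=0)
    df1, df2 = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    F = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), F)
    F[excluded] = np.nan
    p = np.full(E, np.nan)
    tested = ~excluded
    p[tested] = sps.f.sf(F[tested], df1, df2)
    q = np.full(E, np.nan)
    q[tested] = bh_fdr(p[tested])
    significant = np.zeros(E, dtype=bool)
    significant[tested] = q[tested] < q_threshold
    return EdgeAnovaTable(
        F=F,
        df1=df1,
        df2=df2,
        p=p,
        q=q,
        significant=significant,
        excluded=excluded,
        q_threshold=q_threshold,
        group_names=names,
        group_sizes=sizes,
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_threshold(alpha: float = 0.05, n_comparisons: int = 3) -> float:
    return alpha / n_comparisons


def cohens_d_from_t(t: float | np.ndarray, n1: int, n2: int) -> float | np.ndarray:
    return t * np.sqrt(1.0 / n1 + 1.0 / n2)


def cohens_d_ci(d: float, n1: int, n2: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for Cohen's d from a pooled two-sample design."""
    zcrit = sps.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2 - 2)))
    return (d - zcrit * se, d + zcrit * se)


def eta_squared(F: float | np.ndarray, df1: int, df2: int) -> float | np.ndarray:
    return (F * df1) / (F * df1 + df2)


def _eta_sq_from_values(groups: list[np.ndarray]) -> float:
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    sst = sum(((g - grand) ** 2).sum() for g in groups)
    return float(ssb / sst) if sst > 0 else 0.0


def eta_squared_ci(
    groups: Sequence[np.ndarray],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Bias-corrected percentile bootstrap CI for eta^2 over the raw values.

    Subjects are resampled with replacement within groups, preserving group
    sizes.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    rng = np.random.default_rng(seed)
    point = _eta_sq_from_values(list(groups))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        res = [g[rng.integers(0, len(g), len(g))] for g in groups]
        boot[b] = _eta_sq_from_values(res)
    # bias correction: map the point estimate's quantile through the normal CDF
    prop = np.clip(np.mean(boot < point), 1.0 / (n_boot + 1), 1 - 1.0 / (n_boot + 1))
    z0 = sps.norm.ppf(prop)
    alpha = (1 - level) / 2
    lo_q = sps.norm.cdf(2 * z0 + sps.norm.ppf(alpha))
    hi_q = sps.norm.cdf(2 * z0 + sps.norm.ppf(1 - alpha))
    lo, hi = np.quantile(boot, [lo_q, hi_q])
    return float(lo), float(hi)


@dataclass
class PosthocTable:
    """Pairwise pooled-variance t tests for the significant edges.

    ``frame`` has one row per (edge, pair): t, df, p_raw, p_adj (Bonferroni
    factor 3, capped at 1), d and its CI.  d/CI are reported only where the
    adjusted p clears ``report_threshold`` (mirroring the convention of
    reporting effect sizes only for significant contrasts).
    """

    frame: pd.DataFrame
    bonferroni_factor: int
    report_threshold: float


def posthoc_pairwise(
    z_by_group: Mapping[str, np.ndarray],
    significant_edges: np.ndarray,
    pairs: Sequence[tuple[str, str]] | None = None,
    bonferroni_factor: int = 3,
    report_threshold: float = 0.02,
) -> PosthocTable:
    """Pooled-variance independent two-sample t per group pair per edge."""
    names = list(z_by_group.keys())
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for e in np.asarray(significant_edges, dtype=int):
        for a, b in pairs:
            xa = np.asarray(z_by_group[a], dtype=float)[:, e]
            xb = np.asarray(z_by_group[b], dtype=float)[:, e]
            n1, n2 = len(xa), len(xb)
            if n1 < 2 or n2 < 2:
                raise ValueError("each group needs at least 2 subjects for a t test")
            df = n1 + n2 - 2
            sp2 = (((xa - xa.mean()) ** 2).sum() + ((xb - xb.mean()) ** 2).sum()) / df
            if sp2 == 0:
                t = 0.0
            else:
                t = (xa.mean() - xb.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            p_raw = 2.0 * sps.t.sf(abs(t), df)
            p_adj = min(1.0, bonferroni_factor * p_raw)
            d = float(cohens_d_from_t(t, n1, n2))
            lo, hi = cohens_d_ci(d, n1, n2)
            reported = p_adj < report_threshold
            rows.append(
                {
                    "edge": int(e),
                    "pair": f"{a}>{b}",
                    "t": float(t),
                    "df": df,
                    "p_raw": float(p_raw),
                    "p_adj": float(p_adj),
                    "d": d if reported else np.nan,
                    "d_lo": lo if reported else np.nan,
                    "d_hi": hi if reported else np.nan,
                }
            )
    return PosthocTable(
        frame=pd.DataFrame(rows),
        bonferroni_factor=bonferroni_factor,
        report_threshold=report_threshold,
    )


def format_adjusted_p(p: float) -> str:
    """Render an adjusted p-value, capping near-1 values as ``">.99"``."""
    if p > 0.99:
        return ">.99"
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0") or ".000"


def tidy_edge_report(
    anova: EdgeAnovaTable,
    posthoc: PosthocTable | None,
    edge_index,
    atlas,
) -> pd.DataFrame:
    """Long-format per-edge statistics table keyed by region display codes."""
    shorts = atlas.short_names
    rows = []
    for e in range(anova.n_edges):
        i, j = edge_index.unflatten(e)
        rows.append(
            {
                "edge": e,
                "region_i": shorts[i],
                "region_j": shorts[j],
                "F": anova.F[e],
                "df1": anova.df1,
                "df2": anova.df2,
                "p": anova.p[e],
                "q": anova.q[e],
                "significant": bool(anova.significant[e]),
                "excluded": bool(anova.excluded[e]),
            }
        )
    df = pd.DataFrame(rows)
    if posthoc is not None and not posthoc.frame.empty:
        wide = posthoc.frame.copy()
        wide["p_adj_report"] = wide["p_adj"].map(format_adjusted_p)
        piv = wide.pivot(index="edge", columns="pair")
        piv.columns = [f"{stat}[{pair}]" for stat, pair in piv.columns]
        df = df.merge(piv, on="edge", how="left")
    return df
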