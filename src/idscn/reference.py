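"""Published edgewise statistics used to validate effect-size identities.

These are the printed group-comparison statistics for the 30 structural
covariance edges reported by a three-group cross-sectional cohort of expert
first-person-shooter (FPS) players (n=39), multiplayer-online-battle-arena
(MOBA) players (n=40), and non-gaming controls (n=37): per edge the one-way
ANOVA F (df = 2, 113) with its eta-squared, and the pairwise pooled t values
with Cohen's d where the contrast cleared the Bonferroni-corrected .02 level.

They serve as a fixed external check that this package's effect-size
identities (eta^2 from F and df; d and its CI from t and group sizes)
reproduce published values: all printed statistics are rounded to 2 decimals,
so identity-based reconstruction agrees to within one unit in the last
printed digit.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GROUP_SIZES",
    "ANOVA_DF",
    "EDGE_ANOVA_ROWS",
    "POSTHOC_ROWS",
    "eta_sq_identity_errors",
    "cohens_d_identity_errors",
]

GROUP_SIZES = {"FPS": 39, "MOBA": 40, "CONTROL": 37}
ANOVA_DF = (2, 113)

# (edge label, printed F, printed eta^2)
EDGE_ANOVA_ROWS: list[tuple[str, float, float]] = [
    ("L ST - L LOrF", 15.86, 0.22),
    ("L ST - L Op", 13.41, 0.19),
    ("L ST - R Op", 12.85, 0.19),
    ("L ST - L RoMF", 16.71, 0.23),
    ("L ST - L SF", 14.69, 0.21),
    ("R ST - R Op", 16.06, 0.22),
    ("R ST - L RoMF", 16.01, 0.22),
    ("R ST - L SF", 17.47, 0.24),
    ("R ST - R SF", 13.53, 0.19),
    ("L TrT - R Op", 15.61, 0.22),
    ("L TrT - L RoMF", 14.54, 0.20),
    ("L TrT - L SF", 13.30, 0.19),
    ("L TrT - L IP", 13.15, 0.19),
    ("L TrT - L SM", 13.47, 0.19),
    ("L TrT - R SP", 12.84, 0.18),
    ("L TrT - R LO", 14.81, 0.21),
    ("L TrT - R IT", 12.73, 0.18),
    ("L ST - R LO", 13.02, 0.19),
    ("L TrT - L IstCg", 13.88, 0.20),
    ("R IT - R PreCu", 13.97, 0.20),
    ("R IT - L PoC", 14.22, 0.20),
    ("L IT - R PoC", 13.05, 0.18),
    ("R LO - L RoMF", 13.16, 0.19),
    ("L LOrF - L Tr", 13.01, 0.18),
    ("L LOrF - R PoC", 15.14, 0.21),
    ("R LO - L IP", 12.54, 0.18),
    ("R LO - L SM", 13.69, 0.20),
    ("L LOrF - R SP", 12.74, 0.18),
    ("L LOrF - L SM", 12.56, 0.18),
    ("L LOrF - L PoC", 12.94, 0.19),
]

# (edge label, contrast, printed t, printed d or None, printed d CI or None)
# df per contrast as printed: FPS>MOBA 76, FPS>control 73, MOBA>control 74.
POSTHOC_ROWS: list[tuple[str, str, float, float | None, tuple[float, float] | None]] = [
    ("L ST - L LOrF", "FPS>MOBA", 3.29, 0.74, (0.28, 1.20)),
    ("L ST - L LOrF", "FPS>CONTROL", 5.60, 1.28, (0.78, 1.79)),
    ("L ST - L LOrF", "MOBA>CONTROL", 2.39, None, None),
    ("L ST - L Op", "FPS>MOBA", 3.57, 0.80, (0.34, 1.27)),
    ("L ST - L Op", "FPS>CONTROL", 5.03, 1.15, (0.66, 1.65)),
    ("L ST - L Op", "MOBA>CONTROL", 1.53, None, None),
    ("L ST - R Op", "FPS>MOBA", 3.77, 0.85, (0.38, 1.32)),
    ("L ST - R Op", "FPS>CONTROL", 4.81, 1.10, (0.61, 1.60)),
    ("L ST - R Op", "MOBA>CONTROL", 1.12, None, None),
    ("L ST - L RoMF", "FPS>MOBA", 3.82, 0.86, (0.39, 1.33)),
    ("L ST - L RoMF", "FPS>CONTROL", 5.66, 1.30, (0.80, 1.80)),
    ("L ST - L RoMF", "MOBA>CONTROL", 1.93, None, None),
    ("L ST - L SF", "FPS>MOBA", 3.81, 0.86, (0.39, 1.32)),
    ("L ST - L SF", "FPS>CONTROL", 5.23, 1.20, (0.70, 1.70)),
    ("L ST - L SF", "MOBA>CONTROL", 1.51, None, None),
    ("R ST - R Op", "FPS>MOBA", 3.69, 0.83, (0.36, 1.30)),
    ("R ST - R Op", "FPS>CONTROL", 5.57, 1.28, (0.78, 1.78)),
    ("R ST - R Op", "MOBA>CONTROL", 1.96, None, None),
    ("R ST - L RoMF", "FPS>MOBA", 3.92, 0.88, (0.41, 1.35)),
    ("R ST - L RoMF", "FPS>CONTROL", 5.49, 1.26, (0.76, 1.76)),
    ("R ST - L RoMF", "MOBA>CONTROL", 1.65, None, None),
    ("R ST - L SF", "FPS>MOBA", 4.24, 0.95, (0.48, 1.43)),
    ("R ST - L SF", "FPS>CONTROL", 5.68, 1.30, (0.80, 1.81)),
    ("R ST - L SF", "MOBA>CONTROL", 1.53, None, None),
    ("R ST - R SF", "FPS>MOBA", 3.77, 0.85, (0.38, 1.32)),
    ("R ST - R SF", "FPS>CONTROL", 4.98, 1.14, (0.65, 1.64)),
    ("R ST - R SF", "MOBA>CONTROL", 1.29, None, None),
    ("L TrT - R Op", "FPS>MOBA", 3.55, 0.80, (0.33, 1.26)),
    ("L TrT - R Op", "FPS>CONTROL", 5.51, 1.26, (0.76, 1.76)),
    ("L TrT - R Op", "MOBA>CONTROL", 2.04, None, None),
    ("L TrT - L RoMF", "FPS>MOBA", 3.87, 0.87, (0.40, 1.34)),
    ("L TrT - L RoMF", "FPS>CONTROL", 5.18, 1.19, (0.70, 1.68)),
    ("L TrT - L RoMF", "MOBA>CONTROL", 1.40, None, None),
    ("L TrT - L SF", "FPS>MOBA", 3.70, 0.83, (0.36, 1.30)),
    ("L TrT - L SF", "FPS>CONTROL", 4.96, 1.14, (0.65, 1.63)),
    ("L TrT - L SF", "MOBA>CONTROL", 1.34, None, None),
    ("L TrT - L IP", "FPS>MOBA", 3.88, 0.87, (0.40, 1.34)),
    ("L TrT - L IP", "FPS>CONTROL", 4.84, 1.11, (0.62, 1.60)),
    ("L TrT - L IP", "MOBA>CONTROL", 1.04, None, None),
    ("L TrT - L SM", "FPS>MOBA", 3.03, 0.68, (0.22, 1.14)),
    ("L TrT - L SM", "FPS>CONTROL", 5.16, 1.18, (0.69, 1.68)),
    ("L TrT - L SM", "MOBA>CONTROL", 2.20, None, None),
    ("L TrT - R SP", "FPS>MOBA", 3.10, 0.70, (0.24, 1.16)),
    ("L TrT - R SP", "FPS>CONTROL", 5.02, 1.15, (0.66, 1.64)),
    ("L TrT - R SP", "MOBA>CONTROL", 1.99, None, None),
    ("L TrT - R LO", "FPS>MOBA", 3.73, 0.84, (0.37, 1.31)),
    ("L TrT - R LO", "FPS>CONTROL", 5.29, 1.21, (0.72, 1.71)),
    ("L TrT - R LO", "MOBA>CONTROL", 1.64, None, None),
    ("L TrT - R IT", "FPS>MOBA", 4.02, 0.90, (0.43, 1.37)),
    ("L TrT - R IT", "FPS>CONTROL", 4.65, 1.07, (0.58, 1.56)),
    ("L TrT - R IT", "MOBA>CONTROL", 0.71, None, None),
    ("L ST - R LO", "FPS>MOBA", 3.10, 0.70, (0.24, 1.16)),
    ("L ST - R LO", "FPS>CONTROL", 5.06, 1.16, (0.67, 1.66)),
    ("L ST - R LO", "MOBA>CONTROL", 2.03, None, None),
    ("L TrT - L IstCg", "FPS>MOBA", 4.30, 0.97, (0.49, 1.44)),
    ("L TrT - L IstCg", "FPS>CONTROL", 4.78, 1.10, (0.61, 1.59)),
    ("L TrT - L IstCg", "MOBA>CONTROL", 0.57, None, None),
    ("R IT - R PreCu", "FPS>MOBA", 4.62, 1.04, (0.56, 1.52)),
    ("R IT - R PreCu", "FPS>CONTROL", 4.52, 1.04, (0.55, 1.52)),
    ("R IT - R PreCu", "MOBA>CONTROL", -0.02, None, None),
    ("R IT - L PoC", "FPS>MOBA", 4.41, 0.99, (0.52, 1.47)),
    ("R IT - L PoC", "FPS>CONTROL", 4.79, 1.10, (0.61, 1.59)),
    ("R IT - L PoC", "MOBA>CONTROL", 0.47, None, None),
    ("L IT - R PoC", "FPS>MOBA", 3.38, 0.76, (0.30, 1.22)),
    ("L IT - R PoC", "FPS>CONTROL", 5.00, 1.15, (0.65, 1.64)),
    ("L IT - R PoC", "MOBA>CONTROL", 1.70, None, None),
    ("R LO - L RoMF", "FPS>MOBA", 3.27, 0.74, (0.27, 1.20)),
    ("R LO - L RoMF", "FPS>CONTROL", 5.05, 1.16, (0.66, 1.65)),
    ("R LO - L RoMF", "MOBA>CONTROL", 1.86, None, None),
    ("L LOrF - L Tr", "FPS>MOBA", 3.53, 0.79, (0.33, 1.26)),
    ("L LOrF - L Tr", "FPS>CONTROL", 4.95, 1.14, (0.64, 1.63)),
    ("L LOrF - L Tr", "MOBA>CONTROL", 1.49, None, None),
    ("L LOrF - R PoC", "FPS>MOBA", 3.30, 0.74, (0.30, 1.20)),
    ("L LOrF - R PoC", "FPS>CONTROL", 5.46, 1.25, (0.75, 1.75)),
    ("L LOrF - R PoC", "MOBA>CONTROL", 2.24, None, None),
    ("R LO - L IP", "FPS>MOBA", 2.06, None, None),
    ("R LO - L IP", "FPS>CONTROL", 4.98, 1.14, (0.65, 1.64)),
    ("R LO - L IP", "MOBA>CONTROL", 2.98, 0.68, (0.21, 1.15)),
    ("R LO - L SM", "FPS>MOBA", 1.90, None, None),
    ("R LO - L SM", "FPS>CONTROL", 5.18, 1.19, (0.69, 1.68)),
    ("R LO - L SM", "MOBA>CONTROL", 3.33, 0.76, (0.29, 1.23)),
    ("L LOrF - R SP", "FPS>MOBA", 1.94, None, None),
    ("L LOrF - R SP", "FPS>CONTROL", 5.01, 1.15, (0.66, 1.64)),
    ("L LOrF - R SP", "MOBA>CONTROL", 3.12, 0.71, (0.24, 1.18)),
    ("L LOrF - L SM", "FPS>MOBA", 2.66, None, None),
    ("L LOrF - L SM", "FPS>CONTROL", 5.01, 1.15, (0.66, 1.64)),
    ("L LOrF - L SM", "MOBA>CONTROL", 2.41, None, None),
    ("L LOrF - L PoC", "FPS>MOBA", 2.52, None, None),
    ("L LOrF - L PoC", "FPS>CONTROL", 5.09, 1.17, (0.67, 1.66)),
    ("L LOrF - L PoC", "MOBA>CONTROL", 2.63, None, None),
]

_PAIR_SIZES = {
    "FPS>MOBA": (GROUP_SIZES["FPS"], GROUP_SIZES["MOBA"]),
    "FPS>CONTROL": (GROUP_SIZES["FPS"], GROUP_SIZES["CONTROL"]),
    "MOBA>CONTROL": (GROUP_SIZES["MOBA"], GROUP_SIZES["CONTROL"]),
}


def eta_sq_identity_errors() -> np.ndarray:
    """|eta^2 identity from printed F - printed eta^2| for every edge row."""
    from .stats import eta_squared

    df1, df2 = ANOVA_DF
    return np.array(
        [abs(float(eta_squared(F, df1, df2)) - eta) for _, F, eta in EDGE_ANOVA_ROWS]
    )


def cohens_d_identity_errors() -> tuple[np.ndarray, np.ndarray]:
    """(|d identity - printed d|, |d CI identity - printed CI| per bound)
    over every contrast with a printed effect size."""
    from .stats import cohens_d_ci, cohens_d_from_t

    d_err, ci_err = [], []
    for _, pair, t, d_printed, ci_printed in POSTHOC_ROWS:
        if d_printed is None:
            continue
        n1, n2 = _PAIR_SIZES[pair]
        d = float(cohens_d_from_t(t, n1, n2))
        d_err.append(abs(d - d_printed))
        lo, hi = cohens_d_ci(d, n1, n2)
        ci_err.extend([abs(lo - ci_printed[0]), abs(hi - ci_printed[1])])
    return np.array(d_err), np.array(ci_err)
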