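"""Population statistics for contrast-gain-control studies.

Paired nonparametric comparisons (Wilcoxon signed-rank) between contrast
conditions, SD-based outlier flagging, the laminar two-factor ANOVA (layer
and penetration as additive fixed effects) with Tukey-Kramer-corrected
pairwise layer comparisons, and the gain-threshold correlation.

Outlier conventions follow the study design: per-parameter changes lying
more than 1.96 SD from the mean are flagged (but retained) in tuning
comparisons, while the laminar ANOVA and the gain-threshold correlation
exclude values more than 3 SD from the mean beforehand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import MultiComparison

OUTLIER_K_FLAG = 1.96
OUTLIER_K_EXCLUDE = 3.0
LAYERS = ("2/3", "4", "5", "6")

__all__ = [
    "paired_signed_rank",
    "detect_outliers",
    "laminar_anova",
    "gain_threshold_correlation",
    "LaminarAnovaResult",
    "population_report",
]


def paired_signed_rank(x_low: np.ndarray, x_high: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Exact null distribution for n <= 25 pairs, normal approximation with
    continuity correction otherwise.  If every difference is zero the test
    is degenerate and (0, 1) is returned with a warning.
    """
    x_low = np.asarray(x_low, float)
    x_high = np.asarray(x_high, float)
    if x_low.shape != x_high.shape:
        raise ValueError("paired vectors must have equal length")
    if len(x_low) < 6:
        raise ValueError("need at least 6 pairs for a meaningful test")
    if not (np.all(np.isfinite(x_low)) and np.all(np.isfinite(x_high))):
        raise ValueError("inputs must be finite")
    diffs = x_high - x_low
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; test degenerate",
                      RuntimeWarning)
        return 0.0, 1.0
    method = "exact" if len(diffs) <= 25 and not np.any(diffs == 0) else "approx"
    res = sps.wilcoxon(x_high, x_low, alternative="two-sided", method=method,
                       correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def detect_outliers(values: np.ndarray, k: float = OUTLIER_K_FLAG) -> np.ndarray:
    """Flag entries with |value - mean| > k * SD (population SD).

    A zero-variance sample has no outliers.  Flags are computed per call;
    apply to each parameter independently.
    """
    values = np.asarray(values, float)
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    sd = np.std(values)
    if sd == 0:
        return np.zeros(len(values), bool)
    return np.abs(values - values.mean()) > k * sd


@dataclass(frozen=True)
class LaminarAnovaResult:
    anova_table: pd.DataFrame
    layer_p: float
    penetration_p: float
    pairwise: pd.DataFrame  # Tukey-Kramer-corrected layer contrasts
    layer_means: pd.Series
    n_excluded: int


def laminar_anova(
    table: pd.DataFrame,
    response: str = "gain_change_pct",
    anova_type: int = 2,
    exclude_k: float | None = OUTLIER_K_EXCLUDE,
) -> LaminarAnovaResult:
    """Two-factor fixed-effects ANOVA of gain control by layer and penetration.

    The model is additive (no interaction): response ~ C(layer) +
    C(penetration).  Units whose response lies more than ``exclude_k`` SD
    from the mean are removed first.  Layers with fewer than one unit are
    dropped with a warning.  Pairwise layer contrasts use the Tukey-Kramer
    (honestly-significant-difference for unequal n) correction.

    ``anova_type`` selects the sums-of-squares convention (2 by default;
    the design is typically unbalanced).
    """
    df = table.dropna(subset=[response, "layer", "penetration_id"]).copy()
    df = df[df["layer"].isin(LAYERS)]
    n_excluded = 0
    if exclude_k is not None and len(df) >= 3:
        flags = detect_outliers(df[response].to_numpy(), k=exclude_k)
        n_excluded = int(flags.sum())
        df = df[~flags]
    counts = df.groupby("layer")[response].count()
    sparse = [l for l in LAYERS if 0 < counts.get(l, 0) < 2]
    if sparse:
        warnings.warn(f"layers dropped for insufficient data: {sparse}",
                      RuntimeWarning)
        df = df[~df["layer"].isin(sparse)]
    if df["layer"].nunique() < 2:
        raise ValueError("need at least two layers with >= 2 units each")

    # a single penetration carries no blocking information: drop the factor
    formula = f"{response} ~ C(layer)"
    if df["penetration_id"].nunique() > 1:
        formula += " + C(penetration_id)"
    model = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=anova_type)
    layer_row = [i for i in anova.index if "layer" in i][0]
    pen_rows = [i for i in anova.index if "penetration" in i]
    pen_p = float(anova.loc[pen_rows[0], "PR(>F)"]) if pen_rows else float("nan")

    mc = MultiComparison(df[response], df["layer"])
    tukey = mc.tukeyhsd()
    pairwise = pd.DataFrame(tukey.summary().data[1:],
                            columns=tukey.summary().data[0])
    return LaminarAnovaResult(
        anova_table=anova,
        layer_p=float(anova.loc[layer_row, "PR(>F)"]),
        penetration_p=pen_p,
        pairwise=pairwise,
        layer_means=df.groupby("layer")[response].mean(),
        n_excluded=n_excluded,
    )


def gain_threshold_correlation(
    table: pd.DataFrame,
    gain_col: str = "gain_change_pct",
    threshold_col: str = "threshold_change_pct",
    exclude_k: float | None = OUTLIER_K_EXCLUDE,
) -> tuple[float, float]:
    """Pearson correlation between gain and threshold changes.

    Units more than ``exclude_k`` SD from the mean on either variable are
    removed first.
    """
    df = table.dropna(subset=[gain_col, threshold_col])
    g = df[gain_col].to_numpy(float)
    t = df[threshold_col].to_numpy(float)
    if exclude_k is not None and len(g) >= 3:
        keep = ~(detect_outliers(g, exclude_k) | detect_outliers(t, exclude_k))
        g, t = g[keep], t[keep]
    if len(g) < 3:
        raise ValueError("need at least 3 units after outlier exclusion")
    r, p = sps.pearsonr(g, t)
    return float(r), float(p)


def population_report(table: pd.DataFrame) -> str:
    """Plain-text population summary: medians, paired tests, ANOVA, contrasts."""
    lines = [f"Units: {len(table)}"]
    if "gain_change_pct" in table:
        med = table["gain_change_pct"].median()
        frac = (table["gain_change_pct"] < 0).mean()
        lines.append(f"Median gain change: {med:.1f}% "
                     f"({100 * frac:.1f}% of units reduced gain)")
    if "threshold_change_pct" in table:
        lines.append("Median threshold change: "
                     f"{table['threshold_change_pct'].median():.2f}%")
    if {"gain_low", "gain_high"} <= set(table.columns):
        try:
            stat, p = paired_signed_rank(table["gain_low"], table["gain_high"])
            lines.append(f"Signed-rank gain low vs high: W={stat:.1f}, p={p:.3g}")
        except ValueError:
            pass
    try:
        r, p = gain_threshold_correlation(table)
        lines.append(f"Gain-threshold correlation: R={r:.2f}, p={p:.2g}")
    except (ValueError, KeyError):
        pass
    if {"layer", "penetration_id"} <= set(table.columns):
        try:
            res = laminar_anova(table)
            lines.append(f"Laminar ANOVA: layer p={res.layer_p:.3g}, "
                         f"penetration p={res.penetration_p:.3g} "
                         f"({res.n_excluded} outliers excluded)")
            lines.append("Layer means (%): " + ", ".join(
                f"L{l}: {m:.1f}" for l, m in res.layer_means.items()))
            lines.append(res.pairwise.to_string(index=False))
        except ValueError:
            lines.append("Laminar ANOVA skipped (insufficient data)")
    return "\n".join(lines) + "\n"
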