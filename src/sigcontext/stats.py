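"""Comparison statistics for context-resolved signature exposures.

Conventions (fixed, classical, and applied throughout): zero paired
differences are dropped before signed-ranking; tied absolute differences get
average ranks; reported p-values are two-sided unless stated otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "PairedExposures",
    "EffectSizeResult",
    "signed_rank_effect",
    "rank_sum_test",
    "fisher_combine",
    "bh_fdr",
    "spearman_trend",
    "pca_project",
    "tertile_grouping",
    "exposure_sv_correlation",
    "boxplot_summary",
]


@dataclass
class PairedExposures:
    """Per-sample (late, early) weight pairs for one signature and context pair."""

    sample_ids: list[str]
    w_late: np.ndarray
    w_early: np.ndarray

    def __post_init__(self):
        self.w_late = np.asarray(self.w_late, dtype=float)
        self.w_early = np.asarray(self.w_early, dtype=float)
        if len(self.w_late) != len(self.w_early) or len(self.w_late) != len(self.sample_ids):
            raise ValueError("late/early weights and sample ids must align")


@dataclass
class EffectSizeResult:
    """Signed-rank statistic W, total rank sum R, and rank-biserial effect W/R."""

    W: float
    R: float
    effect: float
    n: int


def signed_rank_effect(pairs: PairedExposures) -> EffectSizeResult:
    """Rank-biserial effect size from the Wilcoxon signed-rank statistic.

    Differences d_i = w_late - w_early; zero differences are dropped; |d_i|
    are ranked with average ranks for ties; W = sum sgn(d_i) * R_i; the
    effect is W / R where R is the total rank sum. Effect +1 means the
    late weight exceeds the early weight in every pair.
    """
    d = pairs.w_late - pairs.w_early
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("degenerate pairs: all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    W = float(np.sum(np.sign(d) * ranks))
    R = float(ranks.sum())
    return EffectSizeResult(W=W, R=R, effect=W / R, n=len(d))


def rank_sum_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
    exact_threshold: int = 10,
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both groups have at most ``exact_threshold``
    observations and there are no ties; normal approximation with tie
    correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (len(a) <= exact_threshold and len(b) <= exact_threshold) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


def fisher_combine(pvalues: Sequence[float]) -> float:
    """Fisher's method: X = -2 sum ln p ~ chi-square with 2k df under the null."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    X = -2.0 * np.log(p).sum()
    return float(sps.chi2.sf(X, df=2 * p.size))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def spearman_trend(
    levels: Sequence[float],
    weights: Sequence[float],
) -> tuple[float, float]:
    """Spearman correlation between ordinal context level and exposure weight.

    Observations are pooled (sample, level) pairs. Returns (rho, p); rho is
    NaN with p NaN when either variable is constant.
    """
    lv = np.asarray(levels, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(np.unique(lv)) < 2:
        raise ValueError("need at least 2 distinct levels")
    if len(np.unique(w)) < 2:
        logger.warning("spearman_trend: constant weights, correlation undefined")
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = sps.spearmanr(lv, w)
    return float(rho), float(p)


def pca_project(matrix: np.ndarray, n_components: int = 2):
    """Column-centered PCA of a (rows = signatures) x (features) matrix.

    No variance scaling. The sign of each component is fixed so the loading
    of largest magnitude is positive. Returns (coordinates (n, k),
    explained_variance (k,), total_variance).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(s))
    n = X.shape[0]
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    coords = U[:, :k] * s[:k]
    explained = (s**2) / (n - 1)
    total = float(explained.sum())
    return coords, explained[:k], total


def tertile_grouping(values: Sequence[float]) -> np.ndarray:
    """Split samples into expression tertiles: low (0-33%), middle (33-67%), high.

    Cuts are the empirical 1/3 and 2/3 quantiles; a value exactly at a
    boundary goes to the lower group. All-equal input collapses to "low"
    with a warning.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 samples for tertiles")
    q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
    if q1 == q2 and np.all(v == v[0]):
        logger.warning("tertile_grouping: all values equal; everything labelled 'low'")
        return np.array(["low"] * len(v))
    labels = np.full(len(v), "middle", dtype=object)
    labels[v <= q1] = "low"
    labels[v > q2] = "high"
    return labels.astype(str)


def exposure_sv_correlation(
    weights: Sequence[float],
    sv_counts: Sequence[float],
) -> tuple[float, float]:
    """Spearman correlation between per-sample signature weight and SV count."""
    w = np.asarray(weights, dtype=float)
    s = np.asarray(sv_counts, dtype=float)
    if len(w) != len(s):
        raise ValueError("weights and SV counts must pair up")
    if len(w) < 3:
        raise ValueError("need at least 3 samples")
    if len(np.unique(s)) < 2 or len(np.unique(w)) < 2:
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = sps.spearmanr(w, s)
    return float(rho), float(p)


def boxplot_summary(values: Sequence[float]) -> dict[str, float]:
    """Five-number boxplot summary with Tukey whiskers.

    Whiskers extend at most 1.5 x IQR beyond the quartiles, clipped to the
    most extreme observed value inside that fence.
    """
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    hi_fence, lo_fence = q3 + 1.5 * iqr, q1 - 1.5 * iqr
    upper = float(v[v <= hi_fence].max()) if (v <= hi_fence).any() else float(q3)
    lower = float(v[v >= lo_fence].min()) if (v >= lo_fence).any() else float(q1)
    return {
        "lower_whisker": lower,
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "upper_whisker": upper,
    }


def compare_contexts(
    exposures: pd.DataFrame,
    signature: str,
    context_a: str,
    context_b: str,
    paired: bool = True,
) -> dict[str, float]:
    """Compare one signature's weights between two contexts across samples.

    ``exposures`` is the long-format (sample, context, signature, weight)
    table. Paired mode uses samples present in both contexts and reports the
    Wilcoxon signed-rank p with the rank-biserial W/R effect size; unpaired
    mode uses the rank-sum test.
    """
    sel = exposures[exposures["signature"] == signature]
    wa = sel[sel["context"] == context_a].set_index("sample")["weight"]
    wb = sel[sel["context"] == context_b].set_index("sample")["weight"]
    if paired:
        common = wa.index.intersection(wb.index)
        if len(common) == 0:
            raise ValueError("no samples shared between contexts")
        pairs = PairedExposures(list(common), wa[common].to_numpy(), wb[common].to_numpy())
        eff = signed_rank_effect(pairs)
        d = pairs.w_late - pairs.w_early
        d = d[d != 0]
        p = float(sps.wilcoxon(d, alternative="two-sided").pvalue) if len(d) else 1.0
        return {"statistic": eff.W, "p": p, "effect_size": eff.effect, "n": eff.n}
    p = rank_sum_test(wa.to_numpy(), wb.to_numpy())
    return {"statistic": float("nan"), "p": p, "effect_size": float("nan"),
            "n": len(wa) + len(wb)}
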