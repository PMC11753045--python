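"""Differential methylation: positions (DMPs), de novo regions (DMRs) and
pre-defined promoter regions.

Three analysis modes mirror the three ways two groups of methylomes are
compared:

``call_dmps``
    Per-CpG Mann-Whitney U tests with Bonferroni control, plus an absolute
    methylation-difference filter (|delta| >= 0.1 by default).
``segment_dmrs``
    De novo regions found by recursive binary segmentation of the per-site
    group-mean-difference signal, filtered to >= 10 CpGs and |delta| >=
    0.1, then tested by BOTH a Mann-Whitney U test on per-sample region
    means and a two-sample 2-D Kolmogorov-Smirnov test on (position,
    methylation) point clouds; significance requires both
    Benjamini-Hochberg-adjusted p values below alpha.
``region_dmr_test``
    Pre-defined regions (e.g. 1.5-kb promoter windows): Mann-Whitney U on
    per-sample region means with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import kolmogorov
from statsmodels.stats.multitest import multipletests

from .io import MethylationMatrix

logger = logging.getLogger(__name__)

#: largest combined sample size for which the exact MWU null is enumerated
EXACT_MWU_MAX_N = 12

DMR_COLUMNS = [
    "chrom", "start", "end", "n_cpgs", "mean_a", "mean_b", "delta",
    "p_mwu", "p_ks2d", "p_adj", "direction",
]


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mwu_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration for combined n <= 12 without ties; otherwise the
    tie-corrected normal approximation with continuity correction.  Returns
    (U statistic of group a, two-sided p).  If every value is identical
    across both groups the test is vacuous and p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        u = len(a) * len(b) / 2.0
        return u, 1.0
    if len(pooled) <= EXACT_MWU_MAX_N and not _has_ties(pooled):
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _quadrant_fractions(x, y, x0, y0):
    """Fractions of (x, y) in the four closed/open quadrants around (x0, y0).

    Quadrants split at the origin with (<=, >) in each axis; every point
    falls in exactly one quadrant.
    """
    le_x = x <= x0
    le_y = y <= y0
    n = len(x)
    return np.array(
        [
            np.sum(le_x & le_y),
            np.sum(le_x & ~le_y),
            np.sum(~le_x & le_y),
            np.sum(~le_x & ~le_y),
        ],
        dtype=float,
    ) / n


def ks2d_statistic(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Two-sample 2-D KS statistic (Fasano-Franceschini construction).

    D is the maximum over ALL data points of both samples, and over the
    four quadrant orientations anchored at that point, of the absolute
    difference between the two samples' quadrant fractions.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    pooled = np.vstack([a, b])
    xa, ya = a[:, 0], a[:, 1]
    xb, yb = b[:, 0], b[:, 1]
    d = 0.0
    for x0, y0 in pooled:
        fa = _quadrant_fractions(xa, ya, x0, y0)
        fb = _quadrant_fractions(xb, yb, x0, y0)
        d = max(d, float(np.max(np.abs(fa - fb))))
    return d


def _pearson_safe(x, y) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def ks2d_test(points_a, points_b) -> tuple[float, float]:
    """Two-sample 2-D KS test with the Fasano-Franceschini / Peacock
    large-sample p approximation.

    The p-value uses the Kolmogorov tail at
    ``sqrt(n_eff) * D / (1 + sqrt(1 - r^2) * (0.25 - 0.75 / sqrt(n_eff)))``
    with ``n_eff = n_a n_b / (n_a + n_b)`` and r the average within-sample
    Pearson correlation of the two coordinates (the correlation
    correction).  Approximate for small n; adequate as a region filter.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs >= 3 points")
    pooled = np.vstack([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    d = ks2d_statistic(a, b)
    n_eff = len(a) * len(b) / (len(a) + len(b))
    r = 0.5 * (_pearson_safe(a[:, 0], a[:, 1]) + _pearson_safe(b[:, 0], b[:, 1]))
    r2 = min(r * r, 1.0)
    denom = 1.0 + np.sqrt(1.0 - r2) * (0.25 - 0.75 / np.sqrt(n_eff))
    lam = np.sqrt(n_eff) * d / denom
    return d, float(min(max(kolmogorov(lam), 0.0), 1.0))


def _vectorized_mwu(values: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Row-wise two-sided MWU p-values for a sites x samples matrix.

    Uses the same method-selection rule as :func:`mwu_test` applied row-wise
    (exact for small tie-free rows, tie-corrected normal otherwise); rows
    where all values coincide get p = 1.
    """
    A = values[:, ia]
    B = values[:, ib]
    n_tot = A.shape[1] + B.shape[1]
    p = np.ones(values.shape[0])
    finite = ~(np.isnan(A).any(axis=1) | np.isnan(B).any(axis=1))
    const = np.zeros(values.shape[0], dtype=bool)
    pooled = np.concatenate([A, B], axis=1)
    const[finite] = np.all(pooled[finite] == pooled[finite, :1], axis=1)
    todo = finite & ~const
    if todo.any():
        if n_tot <= EXACT_MWU_MAX_N:
            for i in np.flatnonzero(todo):
                _, p[i] = mwu_test(A[i], B[i])
        else:
            res = stats.mannwhitneyu(
                A[todo], B[todo], alternative="two-sided", method="asymptotic", axis=1
            )
            p[todo] = np.minimum(res.pvalue, 1.0)
    # rows with missing values: pairwise-complete fallback
    for i in np.flatnonzero(~finite):
        a = A[i][~np.isnan(A[i])]
        b = B[i][~np.isnan(B[i])]
        if len(a) >= 2 and len(b) >= 2:
            _, p[i] = mwu_test(a, b)
        else:
            p[i] = np.nan
    return p


def bonferroni(p: np.ndarray) -> np.ndarray:
    return np.minimum(np.asarray(p, dtype=float) * len(p), 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_dmps(
    matrix: MethylationMatrix,
    group_a: str,
    group_b: str,
    min_delta: float = 0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differentially methylated positions between two groups.

    Per site: MWU on per-sample beta values, Bonferroni over all tested
    sites; a DMP requires adjusted p < alpha AND |delta| >= min_delta
    (delta = mean_a - mean_b).  Sites missing in > 50% of either group are
    excluded (count logged).  Returns the full tested table with a ``dmp``
    flag; direction is ``hyper`` when group a exceeds group b.
    """
    ia = [matrix.samples.index(s) for s in matrix.samples_of(group_a)]
    ib = [matrix.samples.index(s) for s in matrix.samples_of(group_b)]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs >= 2 samples")
    V = matrix.values.to_numpy(dtype=float)
    miss_a = np.isnan(V[:, ia]).mean(axis=1) > 0.5
    miss_b = np.isnan(V[:, ib]).mean(axis=1) > 0.5
    keep = ~(miss_a | miss_b)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("call_dmps: excluded %d sites missing in >50%% of a group", n_dropped)
    V = V[keep]
    feats = matrix.features.loc[keep].reset_index(drop=True)
    with np.errstate(invalid="ignore"):
        mean_a = np.nanmean(V[:, ia], axis=1)
        mean_b = np.nanmean(V[:, ib], axis=1)
    delta = mean_a - mean_b
    p_raw = _vectorized_mwu(V, np.asarray(ia), np.asarray(ib))
    p_bonf = bonferroni(p_raw)
    out = feats[["chrom", "pos"]].copy()
    out["mean_a"] = mean_a
    out["mean_b"] = mean_b
    out["delta"] = delta
    out["p_raw"] = p_raw
    out["p_bonferroni"] = p_bonf
    out["direction"] = np.where(delta >= 0, "hyper", "hypo")
    out["dmp"] = (p_bonf < alpha) & (np.abs(delta) >= min_delta)
    return out


@dataclass
class SegmentationParams:
    min_cpgs: int = 10
    min_delta: float = 0.1
    alpha: float = 0.05
    max_gap_bp: int = 300


def _best_subinterval(s: np.ndarray, lo: int, hi: int, min_len: int):
    """Maximise |S[j]-S[i]| / sqrt(j-i) over lo <= i < j <= hi with
    j - i >= min_len; ``s`` is the prefix-sum array (len n+1)."""
    best = (-1.0, lo, hi)
    for j in range(lo + min_len, hi + 1):
        i = np.arange(lo, j - min_len + 1)
        scores = np.abs(s[j] - s[i]) / np.sqrt(j - i)
        k = int(np.argmax(scores))
        if scores[k] > best[0]:
            best = (float(scores[k]), int(i[k]), j)
    return best


def _segment_candidates(d: np.ndarray, min_cpgs: int) -> list[tuple[int, int]]:
    """Recursive binary segmentation of the difference signal ``d``.

    At each level the sub-interval maximising |mean| * sqrt(length) is
    chosen as a candidate and the flanks are recursed; recursion stops when
    the best sub-interval is the whole interval or fewer than ``min_cpgs``
    sites remain.  Candidates are pairwise disjoint by construction.
    """
    s = np.concatenate([[0.0], np.cumsum(d)])
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < min_cpgs:
            return
        _, i, j = _best_subinterval(s, lo, hi, min_cpgs)
        out.append((i, j))
        if (i, j) == (lo, hi):
            return
        recurse(lo, i)
        recurse(j, hi)

    recurse(0, len(d))
    return out


def segment_dmrs(
    matrix: MethylationMatrix,
    group_a: str,
    group_b: str,
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """De novo DMRs by recursive binary segmentation + dual testing.

    The per-site signal is the difference of group mean methylation.  Sites
    are split into runs at inter-CpG gaps > ``max_gap_bp`` and segmented
    per run; candidates are filtered to >= ``min_cpgs`` CpGs and |delta| >=
    ``min_delta`` (delta from per-sample region means), then tested by MWU
    on per-sample region means and by the 2-D KS test on pooled (position,
    beta) points.  Both BH-adjusted p values must fall below alpha.
    Output regions are disjoint.
    """
    params = params or SegmentationParams()
    sa = matrix.samples_of(group_a)
    sb = matrix.samples_of(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs >= 2 samples")
    candidates = []  # (chrom, site_positions, A_block, B_block)
    for chrom in pd.unique(matrix.features["chrom"]):
        sel = matrix.features["chrom"] == chrom
        feats = matrix.features.loc[sel]
        order = np.argsort(feats["pos"].to_numpy(), kind="mergesort")
        pos = feats["pos"].to_numpy()[order]
        A = matrix.values.loc[sel, sa].to_numpy(dtype=float)[order]
        B = matrix.values.loc[sel, sb].to_numpy(dtype=float)[order]
        with np.errstate(invalid="ignore"):
            d = np.nanmean(A, axis=1) - np.nanmean(B, axis=1)
        ok = ~np.isnan(d)
        pos, A, B, d = pos[ok], A[ok], B[ok], d[ok]
        if len(pos) == 0:
            continue
        run_breaks = np.flatnonzero(np.diff(pos) > params.max_gap_bp)
        starts = np.concatenate([[0], run_breaks + 1])
        ends = np.concatenate([run_breaks + 1, [len(pos)]])
        for r0, r1 in zip(starts, ends):
            if r1 - r0 < params.min_cpgs:
                continue
            for i, j in _segment_candidates(d[r0:r1], params.min_cpgs):
                lo, hi = r0 + i, r0 + j
                candidates.append((chrom, pos[lo:hi], A[lo:hi], B[lo:hi]))
    rows = []
    for chrom, pos, A, B in candidates:
        region_means_a = np.nanmean(A, axis=0)
        region_means_b = np.nanmean(B, axis=0)
        mean_a = float(np.mean(region_means_a))
        mean_b = float(np.mean(region_means_b))
        delta = mean_a - mean_b
        if len(pos) < params.min_cpgs or abs(delta) < params.min_delta:
            continue
        _, p_mwu = mwu_test(region_means_a, region_means_b)
        pts_a = np.column_stack([np.tile(pos, A.shape[1]), A.T.ravel()])
        pts_b = np.column_stack([np.tile(pos, B.shape[1]), B.T.ravel()])
        pts_a = pts_a[~np.isnan(pts_a[:, 1])]
        pts_b = pts_b[~np.isnan(pts_b[:, 1])]
        _, p_ks = ks2d_test(pts_a, pts_b)
        rows.append(
            (chrom, int(pos[0]), int(pos[-1]) + 2, len(pos), mean_a, mean_b,
             delta, p_mwu, p_ks, np.nan, "hyper" if delta >= 0 else "hypo")
        )
    df = pd.DataFrame(rows, columns=DMR_COLUMNS)
    if df.empty:
        return df
    p_mwu_adj = bh_adjust(df["p_mwu"].to_numpy())
    p_ks_adj = bh_adjust(df["p_ks2d"].to_numpy())
    df["p_adj"] = np.maximum(p_mwu_adj, p_ks_adj)
    df = df[df["p_adj"] < params.alpha].reset_index(drop=True)
    return df


def region_dmr_test(
    matrix: MethylationMatrix,
    group_a: str,
    group_b: str,
    min_delta: float = 0.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pre-defined-region differential methylation (promoter mode).

    Per region: MWU on per-sample region means, BH adjustment across
    regions.  Regions entirely missing in either group are excluded and
    logged.  Returns the tested table with ``significant`` flags and
    hyper/hypo direction (group a relative to group b).
    """
    sa = matrix.samples_of(group_a)
    sb = matrix.samples_of(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs >= 2 samples")
    A = matrix.values[sa].to_numpy(dtype=float)
    B = matrix.values[sb].to_numpy(dtype=float)
    ok = (~np.isnan(A)).sum(axis=1) >= 2
    ok &= (~np.isnan(B)).sum(axis=1) >= 2
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("region_dmr_test: excluded %d regions without >=2 values per group", n_dropped)
    feats = matrix.features.loc[ok].copy()
    A, B = A[ok], B[ok]
    with np.errstate(invalid="ignore"):
        mean_a = np.nanmean(A, axis=1)
        mean_b = np.nanmean(B, axis=1)
    delta = mean_a - mean_b
    ia = np.arange(A.shape[1])
    ib = np.arange(B.shape[1]) + A.shape[1]
    p_raw = _vectorized_mwu(np.concatenate([A, B], axis=1), ia, ib)
    p_adj = bh_adjust(p_raw)
    out = feats.reset_index()
    out["mean_a"] = mean_a
    out["mean_b"] = mean_b
    out["delta"] = delta
    out["p_raw"] = p_raw
    out["p_adj"] = p_adj
    out["direction"] = np.where(delta >= 0, "hyper", "hypo")
    out["significant"] = (p_adj < alpha) & (np.abs(delta) >= min_delta)
    return out


def top_variable(matrix: MethylationMatrix, fraction: float = 0.01) -> MethylationMatrix:
    """The top ceil(fraction * n) features by across-sample variance.

    Ties are broken by feature order (stable sort), constant features rank
    last.
    """
    if matrix.values.empty:
        raise ValueError("empty matrix")
    var = matrix.values.var(axis=1, ddof=1).to_numpy()
    var = np.where(np.isnan(var), -np.inf, var)
    k = int(np.ceil(fraction * len(var)))
    order = np.argsort(-var, kind="stable")[:k]
    idx = matrix.values.index[np.sort(order)]
    return matrix.subset_features(idx)
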