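"""Cross-platform WGBS vs methylation-array comparison.

The race-associated promoter-DMR (pDMR) procedure harmonizes a WGBS cohort
with an array cohort measured on a sparse probe subset:

1. subset the WGBS CpGs to exact probe positions;
2. stack both cohorts into one sites x samples matrix and quantile
   normalize jointly (a monotone batch distortion of either platform is
   removed exactly in distribution);
3. report a contrast-score symmetry diagnostic (per-feature group-mean
   differences should be centered on 0 under the null);
4. average normalized values over 1.5-kb promoter windows;
5. keep promoters with |cohort difference| > 0.1;
6. keep promoters whose minority-cohort mean lies outside the reference
   cohort's [Q1, Q3] (the IQR-fence bound is recorded alongside);
7. Wilcoxon rank-sum test per surviving promoter, BH-FDR < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import promoter_windows
from .diffmeth import _vectorized_mwu, bh_adjust
from .io import map_to_regions

logger = logging.getLogger(__name__)


def subset_to_probes(records: pd.DataFrame, probes: pd.DataFrame) -> pd.DataFrame:
    """Keep only CpG records at exact (chrom, pos) probe positions.

    ``probes`` needs columns ``chrom, pos``.  Raises if the intersection is
    empty (the cross-platform pipeline cannot proceed); the retention count
    is logged.
    """
    merged = records.merge(probes[["chrom", "pos"]].drop_duplicates(), on=["chrom", "pos"], how="inner")
    if merged.empty:
        raise ValueError("no CpG records at probe positions; cannot harmonize platforms")
    logger.info("subset_to_probes: retained %d/%d sites", len(merged), len(records))
    return merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _tie_averaged_map(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map one complete sample vector onto the reference distribution.

    Each value is replaced by the reference value at its rank; tied values
    all receive the mean of the tied ranks' reference values.
    """
    order = np.argsort(values, kind="mergesort")
    out = np.empty_like(reference)
    out[order] = reference
    # average reference values within tie groups
    sv = values[order]
    tie_starts = np.flatnonzero(np.concatenate([[True], sv[1:] != sv[:-1]]))
    tie_ends = np.concatenate([tie_starts[1:], [len(sv)]])
    mapped_sorted = reference.copy()
    for s, e in zip(tie_starts, tie_ends):
        if e - s > 1:
            mapped_sorted[s:e] = reference[s:e].mean()
    out[order] = mapped_sorted
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a features x samples matrix (missing allowed).

    The reference distribution is the mean of the per-sample sorted vectors
    computed on complete features (rows without missing values).  Each
    sample's non-missing values are replaced by the reference value at
    their rank; ties receive the mean of the tied ranks' reference values.
    When a sample has a different number of non-missing values than the
    reference length, the reference is linearly interpolated at the
    sample's rank quantiles.  Within-sample rank order is preserved
    exactly (ties excepted).
    """
    V = matrix.to_numpy(dtype=float)
    complete = ~np.isnan(V).any(axis=1)
    if complete.sum() < 2:
        raise ValueError("need >= 2 complete features to build the reference")
    ref = np.sort(V[complete], axis=0).mean(axis=1)
    out = np.full_like(V, np.nan)
    m = len(ref)
    for j in range(V.shape[1]):
        col = V[:, j]
        ok = ~np.isnan(col)
        vals = col[ok]
        k = len(vals)
        if k < 2:
            raise ValueError(f"sample {matrix.columns[j]!r} has < 2 non-missing values")
        if k == m:
            target = ref
        else:
            target = np.interp(np.linspace(0.0, 1.0, k), np.linspace(0.0, 1.0, m), ref)
        out[ok, j] = _tie_averaged_map(vals, target)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class ContrastDiagnostic:
    """Symmetry diagnostic of per-feature group-mean differences."""

    scores: np.ndarray
    frac_positive: float
    skewness: float
    symmetric: bool


def contrast_symmetry(
    matrix: pd.DataFrame,
    groups: pd.Series,
    frac_band: tuple[float, float] = (0.45, 0.55),
    max_abs_skew: float = 0.5,
) -> ContrastDiagnostic:
    """Per-feature contrast scores (mean group a - mean group b) and their
    symmetry around zero.

    The flag is set iff the fraction of positive scores lies in
    ``frac_band`` and |sample skewness| < ``max_abs_skew``; after a
    successful batch correction under the null the distribution should be
    nearly symmetric around 0.
    """
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("contrast_symmetry needs exactly two groups")
    sa = groups.index[groups == labels[0]]
    sb = groups.index[groups == labels[1]]
    scores = matrix[sa].mean(axis=1).to_numpy() - matrix[sb].mean(axis=1).to_numpy()
    scores = scores[~np.isnan(scores)]
    frac_pos = float(np.mean(scores > 0))
    skew = float(stats.skew(scores)) if len(scores) > 2 else 0.0
    symmetric = (frac_band[0] <= frac_pos <= frac_band[1]) and abs(skew) < max_abs_skew
    return ContrastDiagnostic(scores, frac_pos, skew, symmetric)


@dataclass
class IqrFilterResult:
    promoter: object
    q1: float
    q3: float
    iqr: float
    test_mean: float
    passes: bool
    side: str  # low | high | none
    within_fence: bool


def iqr_fence_filter(reference_values, test_mean: float, promoter=None) -> IqrFilterResult:
    """Quartile filter of a test mean against a reference distribution.

    Q1/Q3 are linear-interpolation (type-7) quantiles of the reference
    values.  ``passes`` iff the test mean is strictly below Q1 or strictly
    above Q3; ``within_fence`` additionally records whether it stays inside
    the 1.5 x IQR outlier fences (reported, not enforced).
    """
    ref = np.asarray(reference_values, dtype=float)
    ref = ref[~np.isnan(ref)]
    if len(ref) < 4:
        raise ValueError("need >= 4 reference values")
    q1, q3 = np.quantile(ref, [0.25, 0.75])  # numpy default = type-7 linear
    iqr = q3 - q1
    if test_mean < q1:
        side, passes = "low", True
        within = test_mean >= q1 - 1.5 * iqr
    elif test_mean > q3:
        side, passes = "high", True
        within = test_mean <= q3 + 1.5 * iqr
    else:
        side, passes, within = "none", False, True
    return IqrFilterResult(promoter, float(q1), float(q3), float(iqr), float(test_mean), passes, side, within)


def race_pdmr_pipeline(
    wgbs_samples: dict,
    array_matrix: pd.DataFrame,
    probes: pd.DataFrame,
    promoters: pd.DataFrame,
    min_delta: float = 0.1,
    alpha: float = 0.05,
    test_all_then_filter: bool = False,
) -> tuple[pd.DataFrame, dict, ContrastDiagnostic]:
    """The full cross-platform promoter-DMR chain.

    Parameters
    ----------
    wgbs_samples
        Mapping sample id -> methylome frame (the test cohort, e.g. the
        WGBS minority cohort).
    array_matrix
        Probe x sample beta-value DataFrame for the reference cohort,
        indexed by (chrom, pos) MultiIndex or with ``chrom``/``pos``
        columns in a ``features`` companion — here: MultiIndex.
    probes
        Probe manifest with ``chrom, pos`` columns.
    promoters
        Gene table (``gene, chrom, tss, strand``) or ready-made promoter
        windows (with ``start``/``end``); 1.5-kb windows are built when
        absent.
    min_delta
        Cohort |difference| threshold (strict >).
    alpha
        BH-FDR threshold for the Wilcoxon step.

    Returns (pdmr_table, audit_counts, contrast_diagnostic).  By default
    the Wilcoxon test runs only on promoters surviving the delta and IQR
    filters and FDR is computed over that tested set;
    ``test_all_then_filter`` switches to testing every promoter first.
    """
    audit: dict[str, int] = {}
    # 1. subset WGBS records to probe positions, build site x sample matrix
    wgbs_at_probes = {sid: subset_to_probes(rec, probes) for sid, rec in wgbs_samples.items()}
    frames = {
        sid: rec.set_index(["chrom", "pos"])["ratio"] for sid, rec in wgbs_at_probes.items()
    }
    wgbs_mat = pd.DataFrame(frames)
    if not isinstance(array_matrix.index, pd.MultiIndex):
        raise ValueError("array_matrix must be indexed by (chrom, pos)")
    # 2. joint quantile normalization over both platforms
    joint = wgbs_mat.join(array_matrix, how="inner")
    audit["sites_joint"] = len(joint)
    normed = quantile_normalize(joint)
    wgbs_ids = list(wgbs_mat.columns)
    array_ids = list(array_matrix.columns)
    groups = pd.Series(
        ["wgbs"] * len(wgbs_ids) + ["array"] * len(array_ids), index=wgbs_ids + array_ids
    )
    # 3. symmetry diagnostic (reported, not gating)
    diag = contrast_symmetry(normed, groups)
    # 4. promoter averaging (1.5-kb TSS windows built unless intervals given)
    if "tss" in promoters.columns or "start" not in promoters.columns:
        windows = promoter_windows(promoters)
    else:
        windows = promoters.copy()
    if "name" not in windows.columns:
        windows = windows.assign(name=windows.index.astype(str))
    site_records = {
        sid: pd.DataFrame(
            {
                "chrom": normed.index.get_level_values(0),
                "pos": normed.index.get_level_values(1),
                "ratio": normed[sid].to_numpy(),
            }
        )
        for sid in normed.columns
    }
    prom_mat = map_to_regions(site_records, windows, groups=groups)
    audit["promoters_total"] = len(prom_mat.values)
    A = prom_mat.values[wgbs_ids].to_numpy(dtype=float)
    B = prom_mat.values[array_ids].to_numpy(dtype=float)
    complete = (~np.isnan(A)).all(axis=1) & (~np.isnan(B)).all(axis=1)
    audit["promoters_complete"] = int(complete.sum())
    feats = prom_mat.features.loc[complete].copy()
    A, B = A[complete], B[complete]
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    delta = mean_a - mean_b
    # 5. |delta| filter (strict >)
    pass_delta = np.abs(delta) > min_delta
    audit["pass_delta"] = int(pass_delta.sum())
    # 6. IQR quartile filter: array cohort as reference, WGBS cohort mean as test
    pass_iqr = np.zeros(len(feats), dtype=bool)
    side = np.full(len(feats), "none", dtype=object)
    for i in np.flatnonzero(pass_delta):
        res = iqr_fence_filter(B[i], mean_a[i])
        pass_iqr[i] = res.passes
        side[i] = res.side
    audit["pass_iqr"] = int(pass_iqr.sum())
    tested = pass_delta & pass_iqr if not test_all_then_filter else np.ones(len(feats), dtype=bool)
    # 7. Wilcoxon rank-sum per tested promoter, BH-FDR
    p_raw = np.full(len(feats), np.nan)
    if tested.any():
        joint_vals = np.concatenate([A[tested], B[tested]], axis=1)
        p_raw[tested] = _vectorized_mwu(
            joint_vals, np.arange(A.shape[1]), np.arange(B.shape[1]) + A.shape[1]
        )
    p_adj = np.full(len(feats), np.nan)
    if tested.any():
        p_adj[tested] = bh_adjust(p_raw[tested])
    out = feats.reset_index(drop=True)
    out["mean_wgbs"] = mean_a
    out["mean_array"] = mean_b
    out["delta"] = delta
    out["side"] = side
    out["p_raw"] = p_raw
    out["p_adj"] = p_adj
    out["significant"] = tested & pass_delta & pass_iqr & (p_adj < alpha)
    audit["significant"] = int(out["significant"].sum())
    logger.info("race_pdmr_pipeline audit: %s", audit)
    return out, audit, diag


def meth_expr_association(
    meth_matrix: pd.DataFrame, expr_matrix: pd.DataFrame
) -> tuple[pd.Series, float, int]:
    """Per-gene Spearman correlation between promoter methylation and
    expression, plus the fraction of genes with a negative association.

    Both matrices are genes x samples on a shared gene universe and sample
    set.  Genes with a constant methylation or expression vector have an
    undefined correlation and are excluded (their count is returned).
    """
    genes = meth_matrix.index.intersection(expr_matrix.index)
    samples = meth_matrix.columns.intersection(expr_matrix.columns)
    if len(genes) == 0 or len(samples) < 3:
        raise ValueError("need a shared gene universe and >= 3 shared samples")
    rho = {}
    n_excluded = 0
    for g in genes:
        x = meth_matrix.loc[g, samples].to_numpy(dtype=float)
        y = expr_matrix.loc[g, samples].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
            n_excluded += 1
            continue
        rho[g] = stats.spearmanr(x[ok], y[ok]).statistic
    rho = pd.Series(rho, name="spearman_rho")
    frac_negative = float((rho < 0).mean()) if len(rho) else float("nan")
    return rho, frac_negative, n_excluded
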