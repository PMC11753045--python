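"""Methylation-canyon discovery.

Undermethylated regions (UMRs) are called per sample with a two-state
hidden Markov model over the ordered CpG sequence of each chromosome.  The
emission of (methylated count | coverage) at a CpG is Beta-Binomial with a
state-specific mean methylation mu_s and a shared precision kappa
(alpha = mu*kappa, beta = (1-mu)*kappa), so the model works on the raw
sequencing counts rather than on ratios and naturally downweights
low-coverage sites.  Decoding is Viterbi in log space by default; a
posterior-threshold decoder (forward-backward, P(UMR) >= threshold) is
available.

Downstream of per-sample UMRs:

* adjacent UMRs within 500 bp are merged when the merged span (including
  the gap CpGs) keeps a mean methylation <= 0.1;
* merged UMRs of length >= 3.5 kb with mean methylation < 0.1 are
  designated canyons;
* per-group consensus canyons are union-merged across samples and retained
  when supported by at least half of the group's samples;
* unique/shared canyon sets between two groups are defined by >= 1 bp
  overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln, logsumexp

logger = logging.getLogger(__name__)

UMR_COLUMNS = ["chrom", "start", "end", "n_cpgs", "mean_meth", "sample"]

#: a CpG-run interval covers the CG dinucleotide of its last CpG
CPG_END_PAD = 2


@dataclass
class HmmParams:
    """Parameters of the two-state beta-binomial HMM.

    mu_umr / mu_bg
        State mean methylation of the undermethylated and background state.
    kappa
        Beta-binomial precision (alpha + beta) shared by both states.
    p_stay_umr / p_stay_bg
        Self-transition probabilities; p_stay_umr = 0.99 gives an expected
        UMR dwell length of ~100 CpGs.
    min_cpgs
        Minimum CpGs for an emitted UMR.
    posterior_threshold
        If not None, decode by thresholding the posterior P(UMR) instead of
        Viterbi.
    """

    mu_umr: float = 0.03
    mu_bg: float = 0.70
    kappa: float = 20.0
    p_stay_umr: float = 0.99
    p_stay_bg: float = 0.999
    min_cpgs: int = 10
    max_mean: float = 0.1
    posterior_threshold: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.mu_umr < self.mu_bg < 1.0):
            raise ValueError("need 0 < mu_umr < mu_bg < 1")
        for p in (self.p_stay_umr, self.p_stay_bg):
            if not (0.0 < p < 1.0):
                raise ValueError("self-transition probabilities must be in (0,1)")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def _bb_loglik(k: np.ndarray, n: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    """Beta-binomial log pmf, vectorised (binomial coefficient included so
    both states share it; it cancels in decoding but keeps values proper)."""
    a = mu * kappa
    b = (1.0 - mu) * kappa
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + betaln(k + a, n - k + b) - betaln(a, b)
    )


def _log_transition(params: HmmParams) -> np.ndarray:
    # state 0 = background, 1 = UMR
    return np.log(
        [
            [params.p_stay_bg, 1.0 - params.p_stay_bg],
            [1.0 - params.p_stay_umr, params.p_stay_umr],
        ]
    )


def _log_start(params: HmmParams) -> np.ndarray:
    # stationary distribution of the 2-state chain
    leave_bg = 1.0 - params.p_stay_bg
    leave_umr = 1.0 - params.p_stay_umr
    pi_umr = leave_bg / (leave_bg + leave_umr)
    return np.log([1.0 - pi_umr, pi_umr])


def viterbi_path(emission_ll: np.ndarray, log_trans: np.ndarray, log_start: np.ndarray) -> np.ndarray:
    """Most probable state path for a T x S emission log-likelihood matrix.

    Ties are broken toward the lower state index (background), which makes
    the decode deterministic.
    """
    T, S = emission_ll.shape
    back = np.zeros((T, S), dtype=np.int8)
    score = log_start + emission_ll[0]
    for t in range(1, T):
        # cand[i, j] = score[i] + trans[i, j]
        cand = score[:, None] + log_trans
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(S)] + emission_ll[t]
    path = np.empty(T, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def posterior_umr(emission_ll: np.ndarray, log_trans: np.ndarray, log_start: np.ndarray) -> np.ndarray:
    """Forward-backward posterior probability of the UMR state per site."""
    T, S = emission_ll.shape
    fwd = np.zeros((T, S))
    fwd[0] = log_start + emission_ll[0]
    for t in range(1, T):
        fwd[t] = emission_ll[t] + logsumexp(fwd[t - 1][:, None] + log_trans, axis=0)
    bwd = np.zeros((T, S))
    for t in range(T - 2, -1, -1):
        bwd[t] = logsumexp(log_trans + (emission_ll[t + 1] + bwd[t + 1])[None, :], axis=1)
    post = fwd + bwd
    post -= logsumexp(post, axis=1, keepdims=True)
    return np.exp(post[:, 1])


def _runs_of(mask: np.ndarray):
    """Yield (i0, i1) half-open index runs where mask is True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        yield int(idx[s]), int(idx[e]) + 1


def call_umrs(records: pd.DataFrame, params: HmmParams | None = None, sample: str = "sample") -> pd.DataFrame:
    """Call per-sample UMRs from sorted, coverage-filtered CpG records.

    Returns a frame with columns ``chrom, start, end, n_cpgs, mean_meth,
    sample``; intervals span the first to the last CpG of the decoded run
    (half-open, end = last position + 2).  Runs shorter than
    ``params.min_cpgs`` or with mean methylation >= ``params.max_mean`` are
    discarded.
    """
    params = params or HmmParams()
    log_trans = _log_transition(params)
    log_start = _log_start(params)
    out = []
    for chrom, sub in records.groupby("chrom", sort=False):
        sub = sub[sub["coverage"] > 0]
        if len(sub) < params.min_cpgs:
            logger.warning("%s: only %d covered CpGs (< min_cpgs=%d); no UMRs called",
                           chrom, len(sub), params.min_cpgs)
            continue
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError("records must be sorted by position within chromosome")
        k = sub["meth_count"].to_numpy(dtype=float)
        n = sub["coverage"].to_numpy(dtype=float)
        ratio = sub["ratio"].to_numpy(dtype=float)
        ll = np.column_stack(
            [
                _bb_loglik(k, n, params.mu_bg, params.kappa),
                _bb_loglik(k, n, params.mu_umr, params.kappa),
            ]
        )
        if params.posterior_threshold is not None:
            in_umr = posterior_umr(ll, log_trans, log_start) >= params.posterior_threshold
        else:
            in_umr = viterbi_path(ll, log_trans, log_start) == 1
        for i0, i1 in _runs_of(in_umr):
            if i1 - i0 < params.min_cpgs:
                continue
            mean_meth = float(np.mean(ratio[i0:i1]))
            if mean_meth >= params.max_mean:
                continue
            out.append((chrom, int(pos[i0]), int(pos[i1 - 1]) + CPG_END_PAD, i1 - i0, mean_meth, sample))
    return pd.DataFrame(out, columns=UMR_COLUMNS)


def _span_stats(records_by_chrom: dict, chrom: str, start: int, end: int) -> tuple[int, float]:
    pos, ratio, csum, cnt = records_by_chrom[chrom]
    lo = int(np.searchsorted(pos, start, side="left"))
    hi = int(np.searchsorted(pos, end, side="left"))
    n = int(cnt[hi] - cnt[lo])
    mean = (csum[hi] - csum[lo]) / n if n else float("nan")
    return n, mean


def _index_records(records: pd.DataFrame) -> dict:
    by_chrom = {}
    for chrom, sub in records.groupby("chrom", sort=False):
        sub = sub[sub["coverage"] > 0]
        pos = sub["pos"].to_numpy()
        ratio = sub["ratio"].to_numpy(dtype=float)
        by_chrom[chrom] = (
            pos,
            ratio,
            np.concatenate([[0.0], np.cumsum(ratio)]),
            np.concatenate([[0], np.cumsum(np.ones(len(pos), dtype=np.int64))]),
        )
    return by_chrom


def merge_umrs(
    umrs: pd.DataFrame,
    records: pd.DataFrame,
    max_gap: int = 500,
    max_mean: float = 0.1,
) -> pd.DataFrame:
    """Merge adjacent same-sample UMRs within ``max_gap`` bp when the merged
    span keeps mean methylation <= ``max_mean``.

    The merged mean is recomputed over ALL covered CpGs in the union span,
    including those in the gap.  The pass is left-to-right and chains merge
    transitively through accepted merges; the operation is idempotent.
    """
    if umrs.empty:
        return umrs.copy()
    if umrs["sample"].nunique() > 1:
        raise ValueError("merge_umrs expects UMRs from a single sample")
    sample = umrs["sample"].iloc[0]
    idx = _index_records(records)
    out = []
    for chrom, sub in umrs.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for row in sub.itertuples(index=False):
            if cur is None:
                cur = [row.start, row.end, row.n_cpgs, row.mean_meth]
                continue
            gap = row.start - cur[1]
            merged = False
            if gap <= max_gap:
                n, mean = _span_stats(idx, chrom, cur[0], row.end)
                if mean <= max_mean:
                    cur = [cur[0], row.end, n, mean]
                    merged = True
            if not merged:
                out.append((chrom, cur[0], cur[1], cur[2], cur[3], sample))
                cur = [row.start, row.end, row.n_cpgs, row.mean_meth]
        if cur is not None:
            out.append((chrom, cur[0], cur[1], cur[2], cur[3], sample))
    res = pd.DataFrame(out, columns=UMR_COLUMNS)
    return res.sort_values(["chrom", "start"]).reset_index(drop=True)


def designate_canyons(
    umrs: pd.DataFrame, min_length_bp: int = 3500, max_mean: float = 0.1
) -> pd.DataFrame:
    """Keep merged UMRs of length >= 3.5 kb with mean methylation < 0.1."""
    if umrs.empty:
        return umrs.copy()
    length = umrs["end"] - umrs["start"]
    keep = (length >= min_length_bp) & (umrs["mean_meth"] < max_mean)
    return umrs[keep].reset_index(drop=True)


def _union_merge(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union-merge strictly overlapping intervals (abutting ones stay apart)."""
    out = []
    for chrom, sub in intervals.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for row in sub.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = row.start, row.end
            elif row.start < cur_e:
                cur_e = max(cur_e, row.end)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = row.start, row.end
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)


def _overlap_any(chrom, start, end, other: pd.DataFrame) -> bool:
    sub = other[other["chrom"] == chrom]
    return bool(((sub["start"] < end) & (start < sub["end"])).any())


def group_consensus(canyons_by_sample: dict, min_frac: float = 0.5) -> pd.DataFrame:
    """Build within-group consensus canyons.

    All canyon intervals of the group's samples are union-merged; a merged
    interval is retained iff the number of samples contributing at least
    one overlapping canyon is >= ceil(min_frac * n_samples).  Returns
    ``chrom, start, end, support, n_samples``.
    """
    if not canyons_by_sample:
        raise ValueError("empty group")
    n_samples = len(canyons_by_sample)
    pooled = [df for df in canyons_by_sample.values() if not df.empty]
    if not pooled:
        return pd.DataFrame(columns=["chrom", "start", "end", "support", "n_samples"])
    merged = _union_merge(pd.concat(pooled, ignore_index=True)[["chrom", "start", "end"]])
    need = ceil(min_frac * n_samples)
    support = []
    for row in merged.itertuples(index=False):
        s = sum(
            _overlap_any(row.chrom, row.start, row.end, df)
            for df in canyons_by_sample.values()
        )
        support.append(s)
    merged["support"] = support
    merged["n_samples"] = n_samples
    keep = merged["support"] >= need
    return merged[keep].reset_index(drop=True)


def unique_canyons(consensus_a: pd.DataFrame, consensus_b: pd.DataFrame):
    """Partition two consensus sets into (a_only, b_only, shared).

    An interval is shared iff it overlaps >= 1 bp with any interval of the
    other set; ``shared`` stacks the shared intervals of both sets with a
    ``set`` column.
    """
    a_shared_mask = np.array(
        [_overlap_any(r.chrom, r.start, r.end, consensus_b) for r in consensus_a.itertuples(index=False)],
        dtype=bool,
    ) if len(consensus_a) else np.zeros(0, dtype=bool)
    b_shared_mask = np.array(
        [_overlap_any(r.chrom, r.start, r.end, consensus_a) for r in consensus_b.itertuples(index=False)],
        dtype=bool,
    ) if len(consensus_b) else np.zeros(0, dtype=bool)
    a_only = consensus_a[~a_shared_mask].reset_index(drop=True)
    b_only = consensus_b[~b_shared_mask].reset_index(drop=True)
    shared_parts = []
    if a_shared_mask.any():
        shared_parts.append(consensus_a[a_shared_mask].assign(set="a"))
    if b_shared_mask.any():
        shared_parts.append(consensus_b[b_shared_mask].assign(set="b"))
    shared = (
        pd.concat(shared_parts, ignore_index=True)
        if shared_parts
        else pd.DataFrame(columns=list(consensus_a.columns) + ["set"])
    )
    return a_only, b_only, shared


def annotate_canyons_to_genes(canyons: pd.DataFrame, genes: pd.DataFrame) -> list[list[str]]:
    """For each canyon, every gene whose interval overlaps it by >= 1 bp.

    ``genes`` needs columns ``gene, chrom, start, end``.  Returns one gene
    list per canyon (possibly empty), in canyon order.
    """
    out = []
    for row in canyons.itertuples(index=False):
        sub = genes[genes["chrom"] == row.chrom]
        hit = sub[(sub["start"] < row.end) & (row.start < sub["end"])]
        out.append(list(hit["gene"]))
    return out


def unique_umps(
    promoter_means_a: pd.Series, promoter_means_b: pd.Series, threshold: float = 0.1
):
    """Unique undermethylated promoters between two groups.

    A promoter is ``a_only`` iff its group-a mean is < threshold while the
    group-b mean is >= threshold (strict <); symmetric for ``b_only``.
    Both series must share the same promoter universe.
    """
    if not promoter_means_a.index.equals(promoter_means_b.index):
        raise ValueError("promoter universes differ")
    a = promoter_means_a
    b = promoter_means_b
    a_only = list(a.index[(a < threshold) & (b >= threshold)])
    b_only = list(a.index[(b < threshold) & (a >= threshold)])
    return a_only, b_only
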