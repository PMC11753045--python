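import itertools

import numpy as np
import pandas as pd
import pytest

from methcanyon.canyons import (
    HmmParams,
    _bb_loglik,
    _log_start,
    _log_transition,
    call_umrs,
    designate_canyons,
    group_consensus,
    merge_umrs,
    unique_canyons,
    annotate_canyons_to_genes,
    unique_umps,
    viterbi_path,
)
from methcanyon.io import records_from_arrays


def _records(ratios, coverage=20, spacing=100, chrom="chr1"):
    pos = np.arange(len(ratios)) * spacing + 1000
    cov = np.full(len(ratios), coverage)
    meth = np.rint(np.asarray(ratios) * coverage).astype(int)
    return records_from_arrays(chrom, pos, cov, meth)


class TestCallUmrs:
    def test_unambiguous_zero_block_decoded_as_single_umr(self):
        ratios = [0.8] * 50 + [0.0] * 50 + [0.8] * 50
        rec = _records(ratios)
        umrs = call_umrs(rec, HmmParams())
        assert len(umrs) == 1
        u = umrs.iloc[0]
        assert u["start"] == 1000 + 50 * 100
        assert u["end"] == 1000 + 99 * 100 + 2
        assert u["n_cpgs"] == 50
        assert u["mean_meth"] == 0.0

    def test_fully_methylated_chromosome_has_no_umrs(self):
        umrs = call_umrs(_records([0.8] * 120), HmmParams())
        assert umrs.empty

    def test_short_chromosome_warns_and_returns_nothing(self, caplog):
        umrs = call_umrs(_records([0.0] * 5), HmmParams(min_cpgs=10))
        assert umrs.empty

    def test_no_state_separation_yields_no_umrs_on_null_data(self):
        # with mu_umr ~ mu_bg the decode cannot carve out low-methylation runs
        # from background-level data
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cov = rng.integers(10, 30, 200)
            meth = rng.binomial(cov, 0.7)
            rec = records_from_arrays("chr1", np.arange(200) * 100, cov, meth)
            params = HmmParams(mu_umr=0.7 - 1e-9, mu_bg=0.7)
            if len(call_umrs(rec, params)):
                hits += 1
        assert hits == 0


class TestViterbiOracle:
    def _brute_force(self, ll, log_trans, log_start):
        n = ll.shape[0]
        best, best_path = -np.inf, None
        for path in itertools.product([0, 1], repeat=n):
            score = log_start[path[0]] + ll[0, path[0]]
            for t in range(1, n):
                score += log_trans[path[t - 1], path[t]] + ll[t, path[t]]
            if score > best:
                best, best_path = score, path
        return np.array(best_path)

    @pytest.mark.parametrize("seed", range(20))
    def test_viterbi_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        params = HmmParams()
        n = 12
        cov = rng.integers(1, 30, n).astype(float)
        meth = rng.binomial(cov.astype(int), rng.uniform(0, 1, n)).astype(float)
        ll = np.column_stack(
            [
                _bb_loglik(meth, cov, params.mu_bg, params.kappa),
                _bb_loglik(meth, cov, params.mu_umr, params.kappa),
            ]
        )
        lt, ls = _log_transition(params), _log_start(params)
        np.testing.assert_array_equal(viterbi_path(ll, lt, ls), self._brute_force(ll, lt, ls))


class TestMergeUmrs:
    def _umr_frame(self, rows, sample="s"):
        return pd.DataFrame(
            [(c, s, e, n, m, sample) for c, s, e, n, m in rows],
            columns=["chrom", "start", "end", "n_cpgs", "mean_meth", "sample"],
        )

    def test_gap_400_with_low_gap_cpgs_merges(self):
        # UMRs [0,2000) at 0.05 and [2400,4000) at 0.08; gap CpGs at 0.09
        pos = np.concatenate([np.arange(0, 2000, 100), np.arange(2000, 2400, 100), np.arange(2400, 4000, 100)])
        ratios = np.concatenate([np.full(20, 0.05), np.full(4, 0.09), np.full(16, 0.08)])
        cov = np.full(len(pos), 100)
        rec = records_from_arrays("chr1", pos, cov, np.rint(ratios * 100).astype(int))
        umrs = self._umr_frame([("chr1", 0, 2000, 20, 0.05), ("chr1", 2400, 4000, 16, 0.08)])
        merged = merge_umrs(umrs, rec)
        assert len(merged) == 1
        assert (merged["start"].iloc[0], merged["end"].iloc[0]) == (0, 4000)
        # merged mean recomputed over every CpG in the union span
        expected = ratios[pos < 4000].mean()
        assert merged["mean_meth"].iloc[0] == pytest.approx(expected, abs=1e-2)

    def test_gap_501_not_merged(self):
        rec = _records([0.0] * 60, spacing=50)
        umrs = self._umr_frame([("chr1", 1000, 1500, 10, 0.0), ("chr1", 2001, 2600, 10, 0.0)])
        merged = merge_umrs(umrs, rec, max_gap=500)
        assert len(merged) == 2

    def test_high_gap_methylation_blocks_merge(self):
        pos = np.arange(0, 4000, 100)
        ratios = np.where((pos >= 2000) & (pos < 2400), 0.9, 0.02)
        rec = records_from_arrays("chr1", pos, np.full(len(pos), 100), np.rint(ratios * 100).astype(int))
        umrs = self._umr_frame([("chr1", 0, 2000, 20, 0.02), ("chr1", 2400, 4000, 16, 0.02)])
        merged = merge_umrs(umrs, rec)
        assert len(merged) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        pos = np.sort(rng.choice(50_000, 500, replace=False))
        cov = np.full(500, 50)
        rec = records_from_arrays("chr1", pos, cov, rng.binomial(50, 0.05, 500))
        starts = np.sort(rng.choice(45_000, 8, replace=False))
        umrs = self._umr_frame(
            [("chr1", int(s), int(s + 1000), 5, 0.05) for s in starts]
        )
        once = merge_umrs(umrs, rec)
        twice = merge_umrs(once, rec)
        pd.testing.assert_frame_equal(once, twice)

    def test_mixed_samples_rejected(self):
        umrs = pd.concat(
            [self._umr_frame([("chr1", 0, 100, 5, 0.0)], "a"),
             self._umr_frame([("chr1", 200, 300, 5, 0.0)], "b")],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="single sample"):
            merge_umrs(umrs, _records([0.0] * 10))


class TestDesignateCanyons:
    @pytest.mark.parametrize(
        "length,mean,is_canyon",
        [(3_600, 0.05, True), (3_400, 0.01, False), (5_000, 0.12, False), (3_500, 0.09, True)],
    )
    def test_length_and_mean_rules(self, length, mean, is_canyon):
        umrs = pd.DataFrame(
            [("chr1", 0, length, 40, mean, "s")],
            columns=["chrom", "start", "end", "n_cpgs", "mean_meth", "sample"],
        )
        out = designate_canyons(umrs)
        assert (len(out) == 1) is is_canyon


def _canyon(chrom, start, end, sample="s"):
    return pd.DataFrame(
        [(chrom, start, end, 40, 0.02, sample)],
        columns=["chrom", "start", "end", "n_cpgs", "mean_meth", "sample"],
    )


class TestGroupConsensus:
    def _by_sample(self, present_in, total, interval=(1000, 6000)):
        out = {}
        for i in range(total):
            sid = f"s{i}"
            out[sid] = (
                _canyon("chr1", *interval, sid) if i < present_in else _canyon("chr1", 50_000, 55_000, sid)
            )
        return out

    def test_five_of_nine_retained(self):
        cons = group_consensus(self._by_sample(5, 9))
        near = cons[(cons["start"] < 10_000)]
        assert len(near) == 1 and near["support"].iloc[0] == 5

    def test_four_of_nine_removed(self):
        cons = group_consensus(self._by_sample(4, 9))
        assert (cons["start"] >= 10_000).all()

    def test_single_sample_group_keeps_everything(self):
        cons = group_consensus({"s0": _canyon("chr1", 0, 5000)})
        assert len(cons) == 1 and cons["support"].iloc[0] == 1

    def test_support_never_exceeds_group_size(self):
        cons = group_consensus(self._by_sample(9, 9))
        assert (cons["support"] <= cons["n_samples"]).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_consensus({})


class TestUniqueCanyons:
    def _iv(self, triples):
        return pd.DataFrame(triples, columns=["chrom", "start", "end"])

    def test_disjoint_sets(self):
        a = self._iv([("chr1", 0, 10), ("chr1", 100, 110), ("chr1", 200, 210)])
        b = self._iv([("chr1", 50, 60), ("chr1", 300, 310)])
        a_only, b_only, shared = unique_canyons(a, b)
        assert (len(a_only), len(b_only), len(shared)) == (3, 2, 0)

    def test_identical_sets_all_shared(self):
        a = self._iv([("chr1", 0, 10), ("chr2", 5, 15)])
        a_only, b_only, shared = unique_canyons(a, a.copy())
        assert a_only.empty and b_only.empty and len(shared) == 4

    def test_matches_all_pairs_overlap_oracle(self):
        rng = np.random.default_rng(9)
        def rand_set(n):
            s = rng.integers(0, 10_000, n)
            return self._iv([("chr1", int(x), int(x + rng.integers(10, 500))) for x in s])
        for _ in range(20):
            a, b = rand_set(15), rand_set(12)
            a_only, b_only, shared = unique_canyons(a, b)
            exp_a_shared = sum(
                any(ra.start < rb.end and rb.start < ra.end for rb in b.itertuples())
                for ra in a.itertuples()
            )
            assert len(a_only) == len(a) - exp_a_shared


def test_annotate_canyons_to_genes_matches_all_pairs_overlap():
    rng = np.random.default_rng(11)
    genes = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(30)],
            "chrom": "chr1",
            "start": rng.integers(0, 90_000, 30),
        }
    )
    genes["end"] = genes["start"] + rng.integers(1000, 10_000, 30)
    canyons = pd.DataFrame(
        {"chrom": "chr1", "start": rng.integers(0, 90_000, 10)}
    )
    canyons["end"] = canyons["start"] + 5_000
    lists = annotate_canyons_to_genes(canyons, genes)
    for row, got in zip(canyons.itertuples(index=False), lists):
        expected = [
            g.gene for g in genes.itertuples(index=False)
            if g.start < row.end and row.start < g.end
        ]
        assert got == expected


def test_intergenic_canyon_gets_empty_gene_list():
    genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "start": [0], "end": [100]})
    canyons = pd.DataFrame({"chrom": ["chr1"], "start": [5_000], "end": [9_000]})
    assert annotate_canyons_to_genes(canyons, genes) == [[]]


class TestUniqueUmps:
    def _series(self, d):
        return pd.Series(d)

    @pytest.mark.parametrize(
        "a,b,expect_a,expect_b",
        [
            (0.05, 0.40, True, False),
            (0.05, 0.09, False, False),  # undermethylated in both
            (0.10, 0.50, False, False),  # strict <: 0.10 fails
            (0.50, 0.05, False, True),
        ],
    )
    def test_threshold_logic(self, a, b, expect_a, expect_b):
        a_only, b_only = unique_umps(self._series({"p": a}), self._series({"p": b}))
        assert (("p" in a_only), ("p" in b_only)) == (expect_a, expect_b)

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            unique_umps(self._series({"p": 0.1}), self._series({"q": 0.1}))
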