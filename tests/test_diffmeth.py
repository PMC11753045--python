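import itertools

import numpy as np
import pandas as pd
import pytest

from methcanyon.diffmeth import (
    bh_adjust,
    bonferroni,
    call_dmps,
    ks2d_statistic,
    ks2d_test,
    mwu_test,
    region_dmr_test,
    segment_dmrs,
    top_variable,
)
from methcanyon.io import MethylationMatrix

from conftest import beta_matrix, site_matrix


def exact_mwu_p(a, b):
    """Enumeration oracle: U null distribution over all rank assignments."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)

    def u_stat(idx_a):
        av = pooled[list(idx_a)]
        bv = pooled[[i for i in range(n) if i not in idx_a]]
        return sum((x > y) + 0.5 * (x == y) for x in av for y in bv)

    u_obs = u_stat(tuple(range(na)))
    us = [u_stat(c) for c in itertools.combinations(range(n), na)]
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestMwu:
    def test_fully_separated_small_groups(self):
        u, p = mwu_test([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 rank assignments

    def test_identical_groups_give_p_one(self):
        _, p = mwu_test([0.5, 0.5, 0.5], [0.5, 0.5])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_p_matches_enumeration_for_4v4(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(8, dtype=float))  # tie-free
        a, b = vals[:4], vals[4:]
        _, p = mwu_test(a, b)
        assert p == pytest.approx(exact_mwu_p(a, b), abs=1e-12)

    @pytest.mark.parametrize("na,nb", [(2, 4), (5, 6), (6, 6)])
    def test_exact_p_matches_enumeration_various_sizes(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        vals = rng.permutation(np.arange(na + nb, dtype=float))
        a, b = vals[:na], vals[na:]
        _, p = mwu_test(a, b)
        assert p == pytest.approx(exact_mwu_p(a, b), abs=1e-12)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            mwu_test([1.0], [2.0, 3.0])


def oracle_ks2d(a, b):
    """Quadratic quadrant-CDF oracle: plain loops over origins/quadrants."""
    best = 0.0
    for x0, y0 in np.vstack([a, b]):
        for qx, qy in itertools.product([True, False], repeat=2):
            fa = np.mean([((x <= x0) == qx) and ((y <= y0) == qy) for x, y in a])
            fb = np.mean([((x <= x0) == qx) and ((y <= y0) == qy) for x, y in b])
            best = max(best, abs(fa - fb))
    return best


class TestKs2d:
    def test_identical_point_sets_give_zero(self):
        pts = np.random.default_rng(0).random((10, 2))
        d, p = ks2d_test(pts, pts.copy())
        assert d == 0.0
        assert p == 1.0

    def test_fully_separated_quadrants_give_one(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.0, 0.4, (100, 2))
        b = rng.uniform(0.6, 1.0, (100, 2))
        d, p = ks2d_test(a, b)
        assert d == 1.0
        assert p < 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_statistic_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((20, 2))
        b = rng.random((20, 2))
        assert ks2d_statistic(a, b) == pytest.approx(oracle_ks2d(a, b), abs=1e-12)

    def test_degenerate_identical_points(self):
        a = np.ones((5, 2))
        d, p = ks2d_test(a, a.copy())
        assert (d, p) == (0.0, 1.0)


class TestCallDmps:
    def _matrix(self, rng, mu_a, mu_b, na=9, nb=7, kappa=200.0):
        pos = np.arange(len(mu_a)) * 100
        A = beta_matrix(rng, mu_a, na, kappa)
        B = beta_matrix(rng, mu_b, nb, kappa)
        return site_matrix(pos, A, B)

    def test_small_delta_never_called_despite_tiny_p(self):
        rng = np.random.default_rng(0)
        mu_a = np.full(20, 0.55)
        mu_b = np.full(20, 0.50)
        mat = self._matrix(rng, mu_a, mu_b, kappa=100_000.0)  # tiny noise
        out = call_dmps(mat, "A", "B")
        assert not out["dmp"].any()
        assert (np.abs(out["delta"]) < 0.1).all()

    def test_planted_large_effect_called_in_most_seeds(self):
        called = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mu_a = np.full(20, 0.4)
            mu_a[7] = 0.8  # planted site, delta 0.4
            mu_b = np.full(20, 0.4)
            out = call_dmps(self._matrix(rng, mu_a, mu_b), "A", "B")
            hits = out.loc[out["dmp"], "pos"]
            if list(hits) == [700]:
                called += 1
        assert called >= 9

    def test_group_swap_flips_delta_and_keeps_calls(self):
        rng = np.random.default_rng(3)
        mu_a = np.full(15, 0.3); mu_a[4] = 0.75
        mu_b = np.full(15, 0.3)
        mat = self._matrix(rng, mu_a, mu_b)
        fwd = call_dmps(mat, "A", "B")
        rev = call_dmps(mat, "B", "A")
        np.testing.assert_allclose(fwd["delta"], -rev["delta"], atol=1e-12)
        assert list(fwd["dmp"]) == list(rev["dmp"])

    def test_single_sample_group_rejected(self):
        rng = np.random.default_rng(1)
        mat = self._matrix(rng, np.full(5, 0.5), np.full(5, 0.5), na=1, nb=3)
        with pytest.raises(ValueError):
            call_dmps(mat, "A", "B")


class TestSegmentDmrs:
    def _planted_block(self, seed, n_sites=300, block=(100, 150), delta=0.3, na=8, nb=8):
        rng = np.random.default_rng(seed)
        pos = np.arange(n_sites) * 100  # regular spacing keeps one run
        mu_b = np.full(n_sites, 0.6)
        mu_a = mu_b.copy()
        mu_a[block[0]:block[1]] -= delta
        A = beta_matrix(rng, mu_a, na)
        B = beta_matrix(rng, mu_b, nb)
        return site_matrix(pos, A, B), pos[block[0]], pos[block[1] - 1] + 2

    def test_planted_block_recovered_as_single_dmr(self):
        good = 0
        for seed in range(10):
            mat, b0, b1 = self._planted_block(seed)
            res = segment_dmrs(mat, "A", "B")
            if len(res) != 1:
                continue
            r = res.iloc[0]
            overlap = min(r["end"], b1) - max(r["start"], b0)
            if overlap >= 0.8 * (b1 - b0) and r["direction"] == "hypo":
                good += 1
        assert good >= 9

    def test_flat_null_median_zero_dmrs(self):
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            pos = np.arange(200) * 100
            A = beta_matrix(rng, np.full(200, 0.6), 8)
            B = beta_matrix(rng, np.full(200, 0.6), 8)
            counts.append(len(segment_dmrs(site_matrix(pos, A, B), "A", "B")))
        assert np.median(counts) == 0

    def test_small_block_below_cpg_floor_not_called(self):
        mat, _, _ = self._planted_block(0, block=(100, 108), delta=0.5)
        res = segment_dmrs(mat, "A", "B")
        # no region of fewer than 10 CpGs may surface
        assert (res["n_cpgs"] >= 10).all()
        assert not (
            (res["start"] >= 9_900) & (res["end"] <= 10_900) & (res["n_cpgs"] < 10)
        ).any()

    def test_output_regions_disjoint_and_filtered(self):
        mat, _, _ = self._planted_block(5, n_sites=400, block=(50, 120))
        res = segment_dmrs(mat, "A", "B")
        assert (res["n_cpgs"] >= 10).all()
        assert (res["delta"].abs() >= 0.1).all()
        by_chrom = res.sort_values(["chrom", "start"])
        assert (by_chrom["start"].iloc[1:].to_numpy() >= by_chrom["end"].iloc[:-1].to_numpy()).all()


class TestRegionDmrTest:
    def _promoter_matrix(self, rng, mu_a, mu_b, na=9, nb=7):
        genes = [f"g{i}" for i in range(len(mu_a))]
        A = beta_matrix(rng, mu_a, na)
        B = beta_matrix(rng, mu_b, nb)
        cols = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
        values = pd.DataFrame(np.hstack([A, B]), index=genes, columns=cols)
        features = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(len(genes)) * 10_000,
             "end": np.arange(len(genes)) * 10_000 + 1_500}, index=genes)
        groups = pd.Series({c: ("A" if c.startswith("a") else "B") for c in cols})
        return MethylationMatrix(values, features, groups)

    def test_identical_group_values_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.random(10)
        values = pd.DataFrame({f"s{i}": vals for i in range(8)})
        features = pd.DataFrame({"chrom": "chr1", "start": range(10), "end": range(1, 11)})
        groups = pd.Series({f"s{i}": ("A" if i < 4 else "B") for i in range(8)})
        out = region_dmr_test(MethylationMatrix(values, features, groups), "A", "B")
        assert (out["p_raw"] == 1.0).all()
        assert not out["significant"].any()

    def test_hyper_hypo_ratio_recovered(self):
        # 60 hyper + 30 hypo planted among 1,000 promoters
        rng = np.random.default_rng(1)
        mu_b = rng.uniform(0.35, 0.6, 1000)
        mu_a = mu_b.copy()
        mu_a[:60] += 0.3
        mu_a[60:90] -= 0.3
        out = region_dmr_test(self._promoter_matrix(rng, mu_a, mu_b), "A", "B")
        sig = out[out["significant"]]
        ratio = (sig["direction"] == "hyper").sum() / max((sig["direction"] == "hypo").sum(), 1)
        assert 2.0 * 0.85 <= ratio <= 2.0 * 1.15

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(2)
        mat = self._promoter_matrix(rng, rng.uniform(0.2, 0.8, 50), rng.uniform(0.2, 0.8, 50))
        shuffled_cols = list(rng.permutation(mat.values.columns))
        mat2 = MethylationMatrix(mat.values[shuffled_cols], mat.features, mat.groups)
        a = region_dmr_test(mat, "A", "B")
        b = region_dmr_test(mat2, "A", "B")
        np.testing.assert_allclose(a["p_raw"], b["p_raw"], atol=1e-12)
        np.testing.assert_allclose(a["delta"], b["delta"], atol=1e-12)


class TestTopVariable:
    def _matrix(self, values):
        features = pd.DataFrame(
            {"chrom": "chr1", "start": range(len(values)), "end": range(1, len(values) + 1)}
        )
        groups = pd.Series({c: "g" for c in values.columns})
        return MethylationMatrix(values, features, groups)

    def test_ceil_arithmetic(self):
        rng = np.random.default_rng(0)
        mat = self._matrix(pd.DataFrame(rng.random((200, 5))))
        assert len(top_variable(mat, 0.01).values) == 2

    def test_constant_features_rank_last(self):
        values = pd.DataFrame(np.vstack([np.zeros((3, 4)), np.random.default_rng(1).random((5, 4))]))
        top = top_variable(self._matrix(values), fraction=5 / 8)
        assert set(top.values.index) == {3, 4, 5, 6, 7}

    def test_matches_brute_force_variance_sort(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.random((50, 6)))
        top = top_variable(self._matrix(values), 0.2)
        var = values.var(axis=1)
        expected = set(var.sort_values(ascending=False, kind="stable").index[:10])
        assert set(top.values.index) == expected


def test_adjustments_are_monotone_and_ordered():
    rng = np.random.default_rng(0)
    p = rng.random(100)
    bonf, bh = bonferroni(p), bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(bonf[order]) >= -1e-12).all()
    assert (np.diff(bh[order]) >= -1e-12).all()
    assert (bh <= bonf + 1e-12).all()
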