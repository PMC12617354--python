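"""Pairwise r², distance binning, pair accounting, and downsampling."""

import numpy as np
import pytest

from ldne import (
    EmptyProfileError,
    LDParams,
    build_ld_profile,
    downsample_panel,
    make_fixture_panel,
    pairwise_r2,
    read_ld_profile,
    write_ld_profile,
)
from ldne.panel import MISSING

from _oracles import ld_profile_oracle, r2_oracle
from conftest import random_panel


class TestPairwiseR2:
    def test_identical_vectors(self):
        a = [0, 1, 2, 0, 1, 2]
        assert pairwise_r2(a, a) == pytest.approx(1.0)

    def test_sign_cancels_under_squaring(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        assert pairwise_r2(a, 2 - a) == pytest.approx(1.0)

    def test_known_value(self):
        # cov 0.5, variances 2/3 each -> r = 0.75, r2 = 0.5625
        assert pairwise_r2([0, 0, 1, 1, 2, 2], [0, 1, 0, 1, 2, 2]) == \
            pytest.approx(0.5625, abs=1e-12)

    def test_pairwise_complete_deletion(self):
        a = [0, 0, 1, 1, 2, 2, MISSING]
        b = [0, 1, 0, 1, 2, 2, 2]
        assert pairwise_r2(a, b) == pytest.approx(0.5625, abs=1e-12)

    @pytest.mark.parametrize("a, b, msg", [
        ([0, 1], [1, 0], "fewer than 3"),
        ([1, 1, 1, 1], [0, 1, 2, 0], "monomorphic"),
        ([0, MISSING, 1, MISSING], [MISSING, 0, 1, 2], "fewer than 3"),
    ])
    def test_undefined_cases_raise(self, a, b, msg):
        with pytest.raises(ValueError, match=msg):
            pairwise_r2(a, b)

    def test_matches_brute_force_oracle_on_random_vectors(self):
        """1000 random small dosage vectors agree with corrcoef² to 1e-12."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            n = int(rng.integers(4, 30))
            a = rng.integers(0, 3, size=n)
            b = rng.integers(0, 3, size=n)
            a[rng.random(n) < 0.1] = MISSING
            b[rng.random(n) < 0.1] = MISSING
            try:
                r2 = pairwise_r2(a, b)
            except ValueError:
                continue
            assert r2 == pytest.approx(r2_oracle(a, b), abs=1e-12)
            checked += 1


class TestBuildProfile:
    def test_toy_pair_accounting(self, toy_panel):
        """3 SNPs at bp 1, 100001, 200001 -> exactly 3 eligible pairs."""
        bins = build_ld_profile(toy_panel, LDParams(min_pairs_per_bin=1))
        assert sum(b.n_pairs for b in bins) == 3

    def test_boundary_conventions(self):
        # pairs at exactly mindist included; below mindist excluded
        panel = make_fixture_panel("ld_toy_3snp")
        params = LDParams(mindist_bp=100_000, maxdist_bp=200_001,
                          num_bins=4, min_pairs_per_bin=1)
        bins = build_ld_profile(panel, params)
        # distances present: 100000 (1-2), 100000 (2-3), 200000 (1-3)
        assert sum(b.n_pairs for b in bins) == 3
        assert bins[0].n_pairs == 2 and bins[0].lo_bp == 100_000
        params2 = LDParams(mindist_bp=100_001, maxdist_bp=200_000,
                           num_bins=4, min_pairs_per_bin=1)
        with pytest.raises(EmptyProfileError):
            build_ld_profile(panel, params2)  # all pairs now out of range

    def test_no_eligible_pairs_raises(self, toy_panel):
        with pytest.raises(EmptyProfileError):
            build_ld_profile(toy_panel, LDParams(mindist_bp=10_000_000,
                                                 maxdist_bp=20_000_000))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_all_pairs_oracle(self, seed):
        """Profile equals independent per-pair enumeration on small panels."""
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, n=15, m=int(rng.integers(4, 20)),
                             missing_rate=0.15, n_chrom=2)
        params = LDParams(mindist_bp=0, maxdist_bp=200_000, num_bins=10,
                          min_pairs_per_bin=1)
        o_sum_d, o_sum_r2, o_n = ld_profile_oracle(panel, params)
        if o_n.sum() == 0:
            with pytest.raises(EmptyProfileError):
                build_ld_profile(panel, params)
            return
        bins = build_ld_profile(panel, params)
        assert [b.n_pairs for b in bins] == o_n.tolist()
        for k, b in enumerate(bins):
            if b.n_pairs:
                assert b.mean_dist_bp == pytest.approx(o_sum_d[k] / o_n[k])
                assert b.mean_r2 == pytest.approx(o_sum_r2[k] / o_n[k],
                                                  abs=1e-9)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(11)
        panel = random_panel(rng, n=20, m=12, missing_rate=0.1)
        params = LDParams(mindist_bp=0, maxdist_bp=200_000, num_bins=5,
                          min_pairs_per_bin=1)
        bins = build_ld_profile(panel, params)
        perm = rng.permutation(panel.n_samples)
        bins_p = build_ld_profile(panel.subset_samples(perm), params)
        for b, bp_ in zip(bins, bins_p):
            assert b.n_pairs == bp_.n_pairs
            if b.n_pairs:
                assert b.mean_r2 == pytest.approx(bp_.mean_r2, abs=1e-12)

    def test_mean_r2_in_unit_interval_and_bin_means_inside_bounds(self):
        rng = np.random.default_rng(21)
        panel = random_panel(rng, n=25, m=18, missing_rate=0.05)
        bins = build_ld_profile(panel, LDParams(mindist_bp=0,
                                                maxdist_bp=200_000,
                                                num_bins=8,
                                                min_pairs_per_bin=1))
        for b in bins:
            if b.n_pairs:
                assert 0.0 <= b.mean_r2 <= 1.0
                assert b.lo_bp <= b.mean_dist_bp < b.hi_bp

    def test_low_confidence_flagging(self, toy_panel):
        bins = build_ld_profile(toy_panel, LDParams(min_pairs_per_bin=100))
        assert all(b.low_confidence for b in bins if b.n_pairs < 100)

    def test_subsampling_cap_is_seeded(self):
        rng = np.random.default_rng(33)
        panel = random_panel(rng, n=15, m=40, missing_rate=0.0, n_chrom=1)
        params = LDParams(mindist_bp=0, maxdist_bp=400_000, num_bins=8,
                          max_snps_per_chrom=20, min_pairs_per_bin=1, seed=9)
        b1 = build_ld_profile(panel, params)
        b2 = build_ld_profile(panel, params)
        assert [b.n_pairs for b in b1] == [b.n_pairs for b in b2]
        assert sum(b.n_pairs for b in b1) <= 20 * 19 // 2


class TestDownsample:
    def test_identity_on_full_id_list(self, toy_panel):
        sub = downsample_panel(
            toy_panel, target_variant_ids=[v.vid for v in toy_panel.variants])
        assert sub.equals(toy_panel)

    def test_seeded_reproducibility_and_order(self):
        rng = np.random.default_rng(1)
        panel = random_panel(rng, n=10, m=30)
        a = downsample_panel(panel, target_count=10, seed=7)
        b = downsample_panel(panel, target_count=10, seed=7)
        assert a.equals(b)
        bps = [v.bp for v in a.variants]
        assert bps == sorted(bps)
        assert np.array_equal(
            a.genotypes,
            panel.genotypes[:, [panel.variants.index(v) for v in a.variants]])

    def test_overdraw_rejected(self, toy_panel):
        with pytest.raises(ValueError, match="requested"):
            downsample_panel(toy_panel, target_count=10)
        with pytest.raises(KeyError):
            downsample_panel(toy_panel, target_variant_ids=["nope"])


def test_profile_tsv_round_trip(tmp_path, toy_panel):
    bins = build_ld_profile(toy_panel, LDParams(min_pairs_per_bin=1))
    path = tmp_path / "profile.tsv"
    write_ld_profile(bins, path)
    back = read_ld_profile(path)
    assert len(back) == len(bins)
    assert [b.n_pairs for b in back] == [b.n_pairs for b in bins]
    assert [b.mean_r2 for b in back if b.n_pairs] == pytest.approx(
        [b.mean_r2 for b in bins if b.n_pairs])
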