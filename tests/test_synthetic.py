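"""Generator contracts: distributional structure, determinism, thinning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import allelesim as al
from allelesim.counts import make_counts


class TestCoinFlipPopulation:
    def test_degenerate_probability_gives_pure_bl6(self):
        cfg = al.GeneratorConfig(n_cells=200, p_bl6=1.0, rng_seed=0)
        c = al.gen_coin_flip_population(cfg)
        assert (c["n_jf1"] == 0).all()

    def test_pooled_fraction_converges(self):
        cfg = al.GeneratorConfig(n_cells=10_000, p_bl6=0.5, lam=3.0, rng_seed=1)
        c = al.gen_coin_flip_population(cfg)
        frac = c["n_bl6"].sum() / (c["n_bl6"].sum() + c["n_jf1"].sum())
        assert abs(frac - 0.5) < 0.02

    def test_same_seed_reproduces_table(self):
        cfg = al.GeneratorConfig(n_cells=100, p_bl6=0.3, rng_seed=7)
        pd.testing.assert_frame_equal(
            al.gen_coin_flip_population(cfg), al.gen_coin_flip_population(cfg)
        )

    def test_invalid_total_model_rejected(self):
        with pytest.raises(ValueError, match="total_count_model"):
            al.GeneratorConfig(n_cells=10, total_count_model="exponential")

    def test_empirical_totals_resampled_from_pool(self):
        cfg = al.GeneratorConfig(
            n_cells=500,
            total_count_model="empirical",
            count_vector=np.array([2, 4]),
            rng_seed=3,
        )
        c = al.gen_coin_flip_population(cfg)
        assert set(c["total"]) <= {2, 4}


class TestAllOrNonePopulation:
    def test_no_noise_is_strictly_monoallelic(self):
        cfg = al.GeneratorConfig(n_cells=500, rng_seed=2)
        c = al.gen_all_or_none_population(cfg)
        assert ((c["n_bl6"] == 0) | (c["n_jf1"] == 0)).all()

    def test_counts_anticorrelated_without_noise(self):
        cfg = al.GeneratorConfig(n_cells=10_000, p_bl6=0.5, lam=3.0, rng_seed=3)
        c = al.gen_all_or_none_population(cfg)
        nz = (c["n_bl6"] + c["n_jf1"]) > 0
        r = np.corrcoef(c.loc[nz, "n_bl6"], c.loc[nz, "n_jf1"])[0, 1]
        assert r <= 0

    def test_full_fdr_swaps_identities(self):
        clean = al.gen_all_or_none_population(
            al.GeneratorConfig(n_cells=300, rng_seed=4)
        )
        swapped = al.gen_all_or_none_population(
            al.GeneratorConfig(n_cells=300, fdr_bl6=1.0, fdr_jf1=1.0, rng_seed=4)
        )
        np.testing.assert_array_equal(clean["n_bl6"], swapped["n_jf1"])
        np.testing.assert_array_equal(clean["n_jf1"], swapped["n_bl6"])


class TestBurstingPopulation:
    def test_sample_moments_match_negbin(self):
        p = al.NegBinParams(p=0.5, r=2.0)  # mean 2, variance 4
        c = al.gen_bursting_population(100_000, p, p, rng_seed=5)
        assert c["n_bl6"].mean() == pytest.approx(2.0, rel=0.02)
        assert c["n_bl6"].var(ddof=1) == pytest.approx(4.0, rel=0.05)

    def test_large_r_approaches_poisson(self):
        # mean fixed at 2, r large -> variance/mean -> 1
        p = al.NegBinParams(p=100.0 / 102.0, r=100.0)
        c = al.gen_bursting_population(50_000, p, p, rng_seed=6)
        ratio = c["n_bl6"].var(ddof=1) / c["n_bl6"].mean()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_alleles_uncorrelated(self):
        p = al.NegBinParams(p=1 / 3, r=1.5)
        c = al.gen_bursting_population(10_000, p, p, rng_seed=7)
        assert abs(np.corrcoef(c["n_bl6"], c["n_jf1"])[0, 1]) < 0.05

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            al.NegBinParams(p=1.5, r=1.0)
        with pytest.raises(ValueError):
            al.NegBinParams(p=0.5, r=-1.0)


class TestThinningOperators:
    def test_false_detection_identity_at_zero(self, coin_flip_counts):
        out = al.apply_false_detection(coin_flip_counts, 0.0, 0.0, rng_seed=0)
        pd.testing.assert_frame_equal(out, coin_flip_counts)

    def test_false_detection_expectation(self):
        c = make_counts([10] * 4000, [0] * 4000)
        out = al.apply_false_detection(c, 0.5, 0.0, rng_seed=8)
        assert out["n_bl6"].mean() == pytest.approx(5.0, rel=0.05)
        np.testing.assert_array_equal(out["n_bl6"] + out["n_jf1"], 10)

    def test_full_rates_swap_counts(self, coin_flip_counts):
        out = al.apply_false_detection(coin_flip_counts, 1.0, 1.0, rng_seed=9)
        np.testing.assert_array_equal(out["n_bl6"], coin_flip_counts["n_jf1"])

    def test_downsampling_identity_and_bound(self, coin_flip_counts):
        same = al.apply_detection_downsampling(coin_flip_counts, 1.0, rng_seed=0)
        pd.testing.assert_frame_equal(same, coin_flip_counts)
        thin = al.apply_detection_downsampling(coin_flip_counts, 0.5, rng_seed=1)
        assert (thin["n_bl6"] <= coin_flip_counts["n_bl6"]).all()
        assert (thin["n_jf1"] <= coin_flip_counts["n_jf1"]).all()

    def test_downsampled_negbin_mean(self):
        p = al.NegBinParams(p=0.5, r=2.0)  # mean 2
        c = al.gen_bursting_population(100_000, p, p, rng_seed=10)
        thin = al.apply_detection_downsampling(c.drop(columns="total"), 0.5, rng_seed=11)
        assert thin["n_bl6"].mean() == pytest.approx(1.0, rel=0.03)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        fdr_b=st.floats(0, 1),
        fdr_j=st.floats(0, 1),
        seed=st.integers(0, 2**20),
    )
    def test_flips_preserve_per_cell_totals(self, fdr_b, fdr_j, seed):
        rng = np.random.default_rng(seed)
        c = make_counts(rng.poisson(3, 50), rng.poisson(3, 50))
        out = al.apply_false_detection(c, fdr_b, fdr_j, rng_seed=seed)
        np.testing.assert_array_equal(
            out["n_bl6"] + out["n_jf1"], c["n_bl6"] + c["n_jf1"]
        )


class TestTissueLayout:
    def test_quota_exact_for_divisible_case(self):
        lay = al.gen_tissue_layout(1000, p_bl6=0.5, seed_size=2, rng_seed=12)
        assert int(np.sum(lay.identities == "BL6")) == 500

    def test_ratio_within_one_cluster_of_request(self):
        lay = al.gen_tissue_layout(1001, p_bl6=0.4, seed_size=4, rng_seed=13)
        assert abs(lay.bl6_fraction - 0.4) <= 4 / 1001 + 1e-12

    def test_clusters_have_requested_size(self):
        lay = al.gen_tissue_layout(1000, p_bl6=0.5, seed_size=4, rng_seed=14)
        sizes = np.bincount(lay.cluster_ids)
        assert (sizes == 4).all()

    def test_clusters_are_spatially_compact(self):
        # mean within-cluster pairwise distance must be far below the
        # random-pairs expectation for a uniform layout
        lay = al.gen_tissue_layout(1000, p_bl6=0.5, seed_size=4, rng_seed=15)
        d_within = []
        for cid in range(lay.cluster_ids.max() + 1):
            pts = lay.positions[lay.cluster_ids == cid]
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    d_within.append(np.hypot(*(pts[i] - pts[j])))
        assert np.mean(d_within) < 0.2 * np.mean(lay.extent)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            al.gen_tissue_layout(3, seed_size=4)


class TestSpotField:
    def test_exact_coincidence_without_noise(self):
        spec = al.SpotFieldSpec(
            n_guide=50, chromatic_shift=(0.0, 0.0), localization_jitter_sd=0.0,
            coloc_prob_bl6=1.0, coloc_prob_jf1=0.0, spurious_density=0.0, rng_seed=16,
        )
        guide, bl6, jf1, truth = al.gen_spot_field(spec)
        np.testing.assert_allclose(
            bl6[["x", "y"]].to_numpy(), guide[["x", "y"]].to_numpy()
        )
        assert len(jf1) == 0

    def test_constant_offset_without_jitter(self):
        spec = al.SpotFieldSpec(
            n_guide=100, chromatic_shift=(0.4, -0.3), localization_jitter_sd=0.0,
            coloc_prob_bl6=1.0, coloc_prob_jf1=0.0, spurious_density=0.0, rng_seed=17,
        )
        guide, bl6, _, _ = al.gen_spot_field(spec)
        disp = bl6[["x", "y"]].to_numpy() - guide[["x", "y"]].to_numpy()
        np.testing.assert_allclose(disp, np.tile([0.4, -0.3], (100, 1)), atol=1e-9)

    def test_truth_fraction_matches_probabilities(self):
        spec = al.SpotFieldSpec(
            n_guide=10_000, coloc_prob_bl6=0.3, coloc_prob_jf1=0.3, rng_seed=18
        )
        *_, truth = al.gen_spot_field(spec)
        assert (truth["true_assignment"] != "none").mean() == pytest.approx(
            0.6, abs=0.02
        )

    def test_inconsistent_probabilities_rejected(self):
        with pytest.raises(ValueError):
            al.SpotFieldSpec(coloc_prob_bl6=0.7, coloc_prob_jf1=0.5)


class TestFociImage:
    def test_empty_scene(self):
        img, truth = al.gen_foci_image(n_foci=0, extent=(64, 64), rng_seed=19)
        assert img.shape == (64, 64)
        assert len(truth) == 0

    def test_noiseless_maximum_at_center(self):
        img, truth = al.gen_foci_image(
            n_foci=1, extent=(64, 64), noise_sd=0.0, rng_seed=20
        )
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert abs(ix - truth["x"].iloc[0]) <= 0.5
        assert abs(iy - truth["y"].iloc[0]) <= 0.5

    def test_minimum_separation_enforced(self):
        _, truth = al.gen_foci_image(
            n_foci=50, extent=(512, 512), psf_sd=2.0, rng_seed=21
        )
        pts = truth[["x", "y"]].to_numpy()
        d = np.sqrt(((pts[None] - pts[:, None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 8.0

    def test_impossible_packing_rejected(self):
        with pytest.raises(ValueError, match="separation|extent"):
            al.gen_foci_image(n_foci=500, extent=(32, 32), psf_sd=2.0, rng_seed=22)
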