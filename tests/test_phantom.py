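"""Phantom generator: rendering, ground truth, bronchodilator simulation,
and cohort sampling."""

import numpy as np
import pytest
from scipy import stats

import qctlung as q
from conftest import compact_spec


class TestBuildPhantom:
    def test_noise_free_mixing_formula(self):
        spec = compact_spec(evlw_weight=0.0, noise_sd=0.0,
                            lung_air_fraction=0.9, seed=1)
        vol, truth = q.build_phantom(spec)
        par = vol.values[truth.lung_mask.mask]
        assert np.all(par == pytest.approx(-1000 * 0.9 + 30 * 0.1))

    def test_single_generation_tree(self):
        spec = compact_spec(airway_generations=1, seed=1)
        _, truth = q.build_phantom(spec)
        assert len(truth.tree.segments) == 1
        assert truth.tree.root.generation == 1

    def test_truth_tree_generation_count_matches_spec(self):
        spec = compact_spec(seed=1)
        _, truth = q.build_phantom(spec)
        assert truth.tree.max_generation == spec.airway_generations
        assert len(truth.tree.segments) == 2**spec.airway_generations - 1

    def test_masks_partition_grid(self, hf_phantom):
        _, _, truth = hf_phantom
        total = (truth.lung_mask.mask.astype(int)
                 + truth.airway_lumen_mask.mask
                 + truth.airway_wall_mask.mask
                 + truth.body_mask.mask)
        assert total.max() == 1  # pairwise disjoint
        # the remainder is background: together they cover the grid
        assert truth.evlw_voxel_mask.mask.sum() > 0
        assert (truth.evlw_voxel_mask.mask <= truth.lung_mask.mask).all()

    def test_same_seed_bit_identical(self):
        spec = compact_spec(seed=42)
        a, _ = q.build_phantom(spec)
        b, _ = q.build_phantom(spec)
        assert np.array_equal(a.values, b.values)

    def test_tree_exceeding_grid_names_generation(self):
        spec = compact_spec(root_length=60.0, seed=0)
        with pytest.raises(ValueError, match="generation"):
            q.build_phantom(spec)

    def test_unresolvable_airway_spacing(self):
        with pytest.raises(ValueError, match="unresolvable"):
            compact_spec(voxel_spacing=(9.0, 9.0, 9.0), root_radius=8.0)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            compact_spec(evlw_weight=1.5)
        with pytest.raises(ValueError):
            compact_spec(lung_air_fraction=-0.1)
        with pytest.raises(ValueError):
            compact_spec(radius_ratio=0.0)


class TestMixtureShape:
    def test_tail_raises_skew_from_symmetric_baseline(self):
        """Adding any bright tail to the symmetric air/tissue mixture gives
        positive skewness; within the congested range skewness then FALLS
        with rising EVLW weight (the HF-versus-control direction)."""
        rng_skews = []
        for seed in range(10):
            skews = []
            for w in (0.0, 0.15):
                spec = q.PhantomSpec(evlw_weight=w, seed=seed)
                hu, _, _ = q.sample_parenchyma_hu(
                    spec, 100_000, np.random.default_rng(seed + 1000))
                skews.append(q.distribution_moments(hu)[1])
            rng_skews.append(skews)
        assert all(s15 > s0 for s0, s15 in rng_skews)

    def test_skew_decreases_with_weight_in_congested_range(self):
        for seed in range(10):
            skews = []
            for w in (0.05, 0.15, 0.25):
                spec = q.PhantomSpec(evlw_weight=w, seed=seed)
                hu, _, _ = q.sample_parenchyma_hu(
                    spec, 100_000, np.random.default_rng(seed + 2000))
                skews.append(q.distribution_moments(hu)[1])
            assert skews[0] > skews[1] > skews[2]

    def test_congestion_and_mean_monotone_in_weight(self):
        """Spearman rho = 1 across the EVLW-weight grid for both the
        congestion index and the mean HU, on every seed."""
        grid = np.arange(0.0, 0.31, 0.05)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pct, mean = [], []
            for w in grid:
                spec = q.PhantomSpec(evlw_weight=float(w), seed=seed)
                hu, _, _ = q.sample_parenchyma_hu(spec, 200_000, rng)
                pct.append(q.congestion_index(hu))
                mean.append(hu.mean())
            assert stats.spearmanr(grid, pct).statistic == pytest.approx(1.0)
            assert stats.spearmanr(grid, mean).statistic == pytest.approx(1.0)


class TestBronchodilator:
    def test_identity(self, hf_phantom):
        _, vol, truth = hf_phantom
        post, post_truth = q.apply_bronchodilator(vol, truth, 0.0, 0.0, seed=9)
        assert np.array_equal(post.values, vol.values)
        assert np.array_equal(post_truth.evlw_voxel_mask.mask,
                              truth.evlw_voxel_mask.mask)

    def test_full_clearance_matches_clean_phantom(self):
        spec = compact_spec(evlw_weight=0.2, seed=21)
        vol, truth = q.build_phantom(spec)
        post, post_truth = q.apply_bronchodilator(vol, truth, 1.0, 0.0, seed=22)
        assert post_truth.evlw_voxel_mask.n_voxels == 0
        clean_spec = compact_spec(evlw_weight=0.0, seed=21)
        clean, clean_truth = q.build_phantom(clean_spec)
        ci_post = q.congestion_index(post.values[post_truth.lung_mask.mask])
        ci_clean = q.congestion_index(clean.values[clean_truth.lung_mask.mask])
        assert ci_post == pytest.approx(ci_clean, abs=0.05)

    def test_clearance_sign_pattern(self):
        """90% clearance: congestion falls, skewness and kurtosis rise —
        the post-bronchodilator direction on every seed."""
        for seed in range(10):
            spec = q.PhantomSpec(evlw_weight=0.25, seed=seed)
            rng = np.random.default_rng(seed + 3000)
            pre, _, _ = q.sample_parenchyma_hu(spec, 150_000, rng)
            post_spec = q.PhantomSpec(evlw_weight=0.025, seed=seed)
            post, _, _ = q.sample_parenchyma_hu(post_spec, 150_000, rng)
            assert q.congestion_index(post) < q.congestion_index(pre)
            _, g1_pre, g2_pre = q.distribution_moments(pre)
            _, g1_post, g2_post = q.distribution_moments(post)
            assert g1_post > g1_pre and g2_post > g2_pre

    def test_wall_thinning_updates_truth(self):
        spec = compact_spec(evlw_weight=0.1, seed=5)
        vol, truth = q.build_phantom(spec)
        post, post_truth = q.apply_bronchodilator(vol, truth, 0.0, 0.25, seed=6)
        assert post_truth.airway_wall_mask.n_voxels < truth.airway_wall_mask.n_voxels
        assert np.array_equal(post_truth.airway_lumen_mask.mask,
                              truth.airway_lumen_mask.mask)
        for a, b in zip(truth.tree.segments, post_truth.tree.segments):
            assert b.wall_mm == pytest.approx(0.75 * a.wall_mm)

    def test_invalid_fractions_rejected(self, hf_phantom):
        _, vol, truth = hf_phantom
        with pytest.raises(ValueError):
            q.apply_bronchodilator(vol, truth, 1.5, 0.0)
        with pytest.raises(ValueError):
            q.apply_bronchodilator(vol, truth, 0.0, -0.1)


class TestCohortSampling:
    def test_degenerate_copula_gives_exact_correlation(self):
        cs = q.CohortSpec(seed=1, target_correlations=[(2, "fev1_pct", 1.0)],
                          gen_gen_rho=0.0, spiro_spiro_rho=0.0)
        subs = [s for s in q.sample_cohort(cs) if s.record.group == "control"]
        a = np.array([s.true_gen_areas[1] for s in subs])
        f = np.array([s.record.spirometry["fev1_pct"] for s in subs])
        assert np.corrcoef(a, f)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_infeasible_matrix_raises(self):
        # a lone strong cross-correlation with the remaining cross entries
        # pinned at zero conflicts with the within-block correlations
        with pytest.raises(ValueError, match="positive semi-definite"):
            q.sample_cohort(q.CohortSpec(
                seed=1, target_correlations=[(2, "fev1_pct", 0.9)]))

    def test_default_targets_feasible_and_deterministic(self):
        a = q.sample_cohort(q.CohortSpec(seed=7))
        b = q.sample_cohort(q.CohortSpec(seed=7))
        assert len(a) == 60
        for s, t in zip(a, b):
            assert np.array_equal(s.true_gen_areas, t.true_gen_areas)
            assert s.record.spirometry == t.record.spirometry

    def test_copula_recovers_target_correlation_in_expectation(self):
        rs = []
        for rep in range(60):
            cs = q.CohortSpec(seed=rep, target_correlations=[(2, "fev1_pct", 0.6)],
                              gen_gen_rho=0.0, spiro_spiro_rho=0.0)
            subs = [s for s in q.sample_cohort(cs) if s.record.group == "hf"]
            a = np.array([s.true_gen_areas[1] for s in subs])
            f = np.array([s.record.spirometry["fev1_pct"] for s in subs])
            rs.append(np.corrcoef(a, f)[0, 1])
        assert np.mean(rs) == pytest.approx(0.6, abs=0.06)

    def test_invalid_cohort_specs(self):
        with pytest.raises(ValueError):
            q.CohortSpec(target_correlations=[(2, "fev1_pct", 1.2)])
        with pytest.raises(ValueError):
            q.CohortSpec(target_correlations=[(9, "fev1_pct", 0.3)])
        with pytest.raises(ValueError):
            q.GroupParams(n=1)
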