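import numpy as np
import pytest

from adcfmri import (
    StimulationParadigm,
    boxcar_glm,
    build_stimulus_timecourse,
    cluster_correct,
    fir_design,
    fir_glm,
    group_cluster_correct,
    group_level_map,
)


@pytest.fixture(scope="module")
def par():
    return StimulationParadigm()


def planted_series(par, tr, amp, sigma, shape3d=(10, 10, 1), seed=0, planted=None):
    """White-noise series with a boxcar response added in ``planted`` voxels."""
    rng = np.random.default_rng(seed)
    box = build_stimulus_timecourse(par, tr)
    n_t = len(box)
    data = 100.0 + rng.normal(0, sigma, size=(*shape3d, n_t))
    if planted is None:
        planted = np.zeros(shape3d, dtype=bool)
        planted[3:7, 3:7, :] = True
    data[planted] += amp * box
    return data, planted


class TestBoxcarGLM:
    def test_planted_response_detected_and_null_calibrated(self, par):
        data, planted = planted_series(par, 2.0, amp=5.0, sigma=1.0, seed=1)
        res = boxcar_glm(data, par, 2.0)
        assert res.kind == "boxcar" and res.dof == 250
        assert np.all(res.z_map[planted] > 10)
        null_z = res.z_map[~planted]
        rate = np.mean(np.abs(null_z) > 2.3)
        assert 0.005 <= rate <= 0.04

    def test_matches_statsmodels_single_voxel(self, par):
        import statsmodels.api as sm

        data, _ = planted_series(par, 2.0, amp=2.0, sigma=1.0, shape3d=(2, 2, 1), seed=2,
                                 planted=np.ones((2, 2, 1), dtype=bool))
        res = boxcar_glm(data, par, 2.0)
        box = build_stimulus_timecourse(par, 2.0)
        fit = sm.OLS(data[0, 0, 0], sm.add_constant(box)).fit()
        assert res.beta[0, 0, 0, 1] == pytest.approx(fit.params[1], rel=1e-10)
        # t and our z agree through the quantile map; compare t directly
        se = np.sqrt(res.sigma2[0, 0, 0] / np.sum((box - box.mean()) ** 2))
        assert res.beta[0, 0, 0, 1] / se == pytest.approx(fit.tvalues[1], rel=1e-10)

    def test_constant_regressor_raises(self):
        par0 = StimulationParadigm(initial_rest_s=24, n_epochs=0)
        data = np.random.default_rng(0).normal(size=(2, 2, 1, 24))
        with pytest.raises(ValueError, match="rank"):
            boxcar_glm(data, par0, 1.0)


class TestFIRDesign:
    def test_paper_parameters_give_four_regressors_of_two_samples(self, par):
        design = fir_design(par, 2.0, n_impulses=4, window_s=16.0)
        assert list(design.columns) == ["intercept", "fir_0", "fir_1", "fir_2", "fir_3"]
        # each regressor sums to n_epochs * stim samples * bin samples
        sums = design[[c for c in design.columns if c != "intercept"]].sum()
        assert (sums == 12 * 8 * 2).all()

    def test_single_bin_design_is_shifted_boxcar(self, par):
        design = fir_design(par, 2.0, n_impulses=1, window_s=2.0)
        box = build_stimulus_timecourse(par, 2.0)
        np.testing.assert_array_equal(design["fir_0"].to_numpy(), box)

    def test_non_divisible_window_rejected(self, par):
        with pytest.raises(ValueError, match="bin"):
            fir_design(par, 2.0, n_impulses=3, window_s=16.0)


class TestFIRGLM:
    @pytest.mark.parametrize("amp", [4.0, -4.0])
    def test_detects_either_polarity(self, par, amp):
        data, planted = planted_series(par, 2.0, amp=amp, sigma=1.0, seed=3)
        res = fir_glm(data, par, 2.0)
        assert res.kind == "fir"
        assert np.all(res.z_map[planted] > 5)
        assert np.all(res.z_map[~np.isnan(res.z_map)] >= 0)

    def test_null_rate_calibrated(self, par):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(16, 16, 4, 252))
        res = fir_glm(data, par, 2.0)
        rate = np.mean(res.z_map > 2.3)
        assert 0.005 <= rate <= 0.03

    def test_recovers_single_fir_regressor(self, par):
        design = fir_design(par, 2.0)
        rng = np.random.default_rng(5)
        data = 10.0 + 0.01 * rng.normal(size=(2, 2, 1, 252))
        data += 5.0 * design["fir_2"].to_numpy()
        res = fir_glm(data, par, 2.0)
        betas = res.beta[0, 0, 0, 1:]
        assert np.argmax(np.abs(betas)) == 2


class TestClusterCorrect:
    def test_zero_map_yields_no_clusters(self, par):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(8, 8, 2, 252))
        res = boxcar_glm(data, par, 2.0)
        res.z_map[:] = 0.0
        cm = cluster_correct(res, data, n_perm=100, seed=0)
        assert cm.n_clusters == 0 and not cm.mask.any()

    def test_planted_blob_survives(self, par):
        planted = np.zeros((32, 32, 4), dtype=bool)
        planted[10:14, 10:14, 1:3] = True  # 32-voxel blob
        data, _ = planted_series(par, 2.0, amp=3.0, sigma=1.0, shape3d=(32, 32, 4),
                                 seed=7, planted=planted)
        res = boxcar_glm(data, par, 2.0)
        cm = cluster_correct(res, data, n_perm=199, seed=7)
        assert cm.n_clusters >= 1
        assert (cm.mask & planted).sum() >= 0.9 * planted.sum()
        assert (cm.table["sign"] == 1).any()

    def test_monotone_in_threshold(self, par):
        planted = np.zeros((16, 16, 2), dtype=bool)
        planted[4:10, 4:10, :] = True
        data, _ = planted_series(par, 2.0, amp=1.5, sigma=1.0, shape3d=(16, 16, 2),
                                 seed=8, planted=planted)
        res = boxcar_glm(data, par, 2.0)
        counts = []
        for thr in (1.5, 2.3, 3.1):
            cm = cluster_correct(res, data, z_threshold=thr, n_perm=100, seed=1)
            counts.append(int(cm.mask.sum()))
        assert counts[0] >= counts[1] >= counts[2]

    def test_reproducible_and_stable_in_n_perm(self, par):
        planted = np.zeros((16, 16, 2), dtype=bool)
        planted[4:10, 4:10, :] = True
        data, _ = planted_series(par, 2.0, amp=2.0, sigma=1.0, shape3d=(16, 16, 2),
                                 seed=9, planted=planted)
        res = boxcar_glm(data, par, 2.0)
        cm1 = cluster_correct(res, data, n_perm=500, seed=3)
        cm2 = cluster_correct(res, data, n_perm=500, seed=3)
        np.testing.assert_array_equal(cm1.labels, cm2.labels)
        assert cm1.table.equals(cm2.table)
        cm3 = cluster_correct(res, data, n_perm=1000, seed=3)
        merged = cm1.table.merge(cm3.table, on=["extent", "sign"], suffixes=("_a", "_b"))
        assert (merged["p_a"] - merged["p_b"]).abs().max() < 0.01


class TestGroupLevel:
    def test_degenerate_identical_maps_capped(self):
        maps = [np.full((4, 4, 2), 1.3)] * 6
        z = group_level_map(maps)
        assert np.isfinite(z).all()
        assert (z > 0).all() and z.max() <= 40

    def test_null_maps_give_standard_normal_group_z(self):
        rng = np.random.default_rng(10)
        maps = [rng.normal(size=(20, 20, 4)) for _ in range(6)]
        z = group_level_map(maps)
        assert abs(np.mean(z)) < 0.08
        assert abs(np.std(z) - 1.0) < 0.08

    def test_geometry_mismatch_and_single_subject_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            group_level_map([np.zeros((4, 4, 2)), np.zeros((5, 4, 2))])
        with pytest.raises(ValueError, match="2 subjects"):
            group_level_map([np.zeros((4, 4, 2))])

    def test_planted_group_effect_survives_sign_flip_correction(self):
        rng = np.random.default_rng(11)
        planted = np.zeros((16, 16, 2), dtype=bool)
        planted[4:9, 4:9, :] = True
        maps = []
        for _ in range(6):
            m = rng.normal(size=(16, 16, 2))
            m[planted] += 3.0
            maps.append(m)
        cm = group_cluster_correct(maps, z_threshold=1.5, n_perm=500, seed=0)
        assert cm.n_clusters >= 1
        covered = (cm.mask & planted).sum() / planted.sum()
        assert covered >= 0.9
        assert not (cm.mask & ~planted).sum() > 0.05 * (~planted).sum()
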