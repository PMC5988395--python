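"""Module ICA, spatial maps, MRC clustering, and cluster-extent FWE."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from sklearn.metrics import adjusted_rand_score

from tbinet import funcnet, stats

from conftest import make_cohort_table


class TestModuleIca:
    def test_planted_supergaussian_sources_recovered(self, rng):
        t, v = 300, 40
        sources = rng.laplace(size=(t, 3))
        mixing = rng.standard_normal((3, v))
        x = sources @ mixing + 0.05 * rng.standard_normal((t, v))
        comp = funcnet.module_ica_components(x, n_pca=3, n_ica=3, seed=0)
        corr = np.abs(np.corrcoef(sources.T, comp.components.T)[:3, 3:])
        assert np.all(corr.max(axis=1) >= 0.95)

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal((100, 30))
        a = funcnet.module_ica_components(x, n_pca=5, n_ica=5, seed=7)
        b = funcnet.module_ica_components(x, n_pca=5, n_ica=5, seed=7)
        assert np.array_equal(a.components, b.components)

    def test_unit_sample_variance(self, rng):
        x = rng.standard_normal((120, 25))
        comp = funcnet.module_ica_components(x, n_pca=4, n_ica=4, seed=1)
        assert np.allclose(comp.components.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_rank_deficient_data_errors(self, rng):
        base = rng.standard_normal((60, 2))
        x = base @ rng.standard_normal((2, 30))  # rank 2
        with pytest.raises(ValueError, match="rank"):
            funcnet.module_ica_components(x, n_pca=5, n_ica=5, seed=0)


class TestComponentSpatialMap:
    def _components(self, rng, t=200, c=3):
        src = rng.laplace(size=(t, c))
        return funcnet.ComponentSet(
            components=(src - src.mean(0)) / src.std(0, ddof=1)
        )

    def test_regression_consistency(self, rng):
        comp = self._components(rng)
        c1 = comp.components[:, 0]
        brain = np.column_stack(
            [2.0 * c1 + rng.standard_normal(200), rng.standard_normal(200)]
        )
        sm = funcnet.component_spatial_map(brain, comp)
        assert sm.maps[0, 0] == pytest.approx(2.0, abs=0.25)
        assert abs(sm.maps[0, 1]) < 0.25

    def test_orthogonal_voxel_maps_near_zero(self, rng):
        comp = self._components(rng)
        brain = rng.standard_normal((200, 4))
        sm = funcnet.component_spatial_map(brain, comp)
        assert np.all(np.abs(sm.maps) < 0.5)

    def test_component_rescaling_inverts_map(self, rng):
        comp = self._components(rng)
        c1 = comp.components[:, 0]
        brain = (3.0 * c1 + 0.1 * rng.standard_normal(200))[:, None]
        sm1 = funcnet.component_spatial_map(brain, comp)
        scaled = funcnet.ComponentSet(
            components=comp.components * np.array([4.0, 1.0, 1.0])
        )
        sm2 = funcnet.component_spatial_map(brain, scaled)
        assert sm2.maps[0, 0] == pytest.approx(sm1.maps[0, 0] / 4.0, rel=1e-6)

    def test_collinear_components_error(self, rng):
        c = rng.standard_normal((50, 1))
        comp = funcnet.ComponentSet(components=np.column_stack([c, 2 * c]))
        with pytest.raises(ValueError, match="collinear"):
            funcnet.component_spatial_map(rng.standard_normal((50, 3)), comp)


class TestClusterSpatialMaps:
    def _family_maps(self, rng, n_per=40, v=500, k=5, noise=0.3):
        centers = rng.standard_normal((k, v)) * 2
        maps, labels = [], []
        for f in range(k):
            maps.append(centers[f] + noise * rng.standard_normal((n_per, v)))
            labels.extend([f] * n_per)
        return np.vstack(maps), np.array(labels)

    def test_planted_families_perfectly_recovered(self, rng):
        maps, truth = self._family_maps(rng)
        out = funcnet.cluster_spatial_maps(maps, k=5, seed=0)
        assert adjusted_rand_score(truth, out.labels) == 1.0

    def test_affine_rescaling_invariance(self, rng):
        maps, _ = self._family_maps(rng, n_per=10, v=100)
        out1 = funcnet.cluster_spatial_maps(maps, k=5, seed=3)
        scales = rng.uniform(0.5, 4.0, (maps.shape[0], 1))
        offsets = rng.standard_normal((maps.shape[0], 1)) * 10
        out2 = funcnet.cluster_spatial_maps(maps * scales + offsets, k=5, seed=3)
        assert adjusted_rand_score(out1.labels, out2.labels) == 1.0

    def test_centroids_unit_norm(self, rng):
        maps, _ = self._family_maps(rng, n_per=8, v=64)
        out = funcnet.cluster_spatial_maps(maps, k=5, seed=0)
        assert np.allclose(np.linalg.norm(out.centroids, axis=1), 1.0)

    def test_constant_map_error_names_index(self, rng):
        maps = rng.standard_normal((10, 50))
        maps[3] = 7.0
        with pytest.raises(ValueError, match="index 3"):
            funcnet.cluster_spatial_maps(maps, k=2, seed=0)

    def test_identical_maps_degenerate_input(self, rng):
        one = rng.standard_normal(50)
        maps = np.tile(one, (12, 1))
        out = funcnet.cluster_spatial_maps(maps, k=3, seed=0)
        assert len(out.labels) == 12  # all labeled despite degeneracy


class TestMrcGroupContrast:
    def test_contrast_antisymmetry(self, rng):
        cohort = make_cohort_table(8, 6, seed=3)
        maps = {s: rng.standard_normal((2, 50)) for s in cohort.index}
        t_maps, _, _ = funcnet.mrc_group_contrast(maps, cohort)
        assert np.allclose(t_maps["control_gt_tbi"], -t_maps["tbi_gt_control"])

    def test_planted_tbi_blob_sign(self, rng):
        cohort = make_cohort_table(12, 10, seed=4)
        blob = np.arange(5)
        maps = {}
        for s in cohort.index:
            m = rng.standard_normal((1, 60))
            if cohort.loc[s, "group"] == "tbi":
                m[:, blob] += 3.0
            maps[s] = m
        t_maps, _, _ = funcnet.mrc_group_contrast(maps, cohort)
        assert np.all(t_maps["control_gt_tbi"][blob] < -2)
        assert np.all(t_maps["tbi_gt_control"][blob] > 2)

    def test_missing_group_errors(self, rng):
        cohort = make_cohort_table(4, 3, seed=0)
        maps = {
            s: rng.standard_normal((1, 20))
            for s in cohort.index
            if cohort.loc[s, "group"] == "control"
        }
        with pytest.raises(ValueError, match="tbi"):
            funcnet.mrc_group_contrast(maps, cohort)


class TestClusterExtent:
    def test_matches_independent_voxel_oracle_at_zero_smoothness(self):
        null = funcnet.cluster_extent_threshold(
            (10, 10, 10), fwhm=0, voxel_p=0.01, alpha=0.05, n_iter=2000, seed=3
        )
        # brute-force oracle: iid Bernoulli exceedance masks, no smoothing
        # machinery at all
        rng = np.random.default_rng(99)
        st = ndimage.generate_binary_structure(3, 1)
        maxes = []
        for _ in range(2000):
            mask = rng.random((10, 10, 10)) < 0.01
            lab, k = ndimage.label(mask, structure=st)
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, k + 1))
            maxes.append(0 if k == 0 else int(sizes.max()))
        maxes = np.asarray(maxes)
        s = 1
        while np.mean(maxes >= s) > 0.05:
            s += 1
        assert abs(null.min_cluster_size - s) <= 1

    def test_alpha_one_gives_threshold_one(self):
        null = funcnet.cluster_extent_threshold(
            (8, 8, 8), fwhm=0, voxel_p=0.05, alpha=1.0, n_iter=50, seed=0
        )
        assert null.min_cluster_size == 1

    def test_threshold_nondecreasing_in_fwhm(self):
        sizes = [
            funcnet.cluster_extent_threshold(
                (12, 12, 12), fwhm=f, voxel_p=0.01, alpha=0.05, n_iter=400, seed=0
            ).min_cluster_size
            for f in (0, 2, 4)
        ]
        assert sizes[0] <= sizes[1] <= sizes[2]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            funcnet.cluster_extent_threshold((8, 8, 8), fwhm=-1, voxel_p=0.01)
        with pytest.raises(ValueError):
            funcnet.cluster_extent_threshold((8, 8, 8), fwhm=0, voxel_p=0.01, alpha=1.5)
        with pytest.raises(ValueError):
            funcnet.cluster_extent_threshold((8, 8, 8), fwhm=0, voxel_p=0.01, connectivity=5)


class TestApplyClusterCorrection:
    def _null(self):
        return funcnet.cluster_extent_threshold(
            (10, 10, 10), fwhm=0, voxel_p=0.005, alpha=0.05, n_iter=500, seed=1
        )

    def test_planted_strong_blob_survives(self, rng):
        null = self._null()
        t_map = rng.standard_normal((10, 10, 10)) * 0.5
        t_map[2:7, 2:7, 2:7] = 20.0  # 125 voxels, far beyond any extent minimum
        clusters = funcnet.apply_cluster_correction(t_map, df=39, voxel_p=0.005, null=null)
        assert clusters and clusters[0].size >= 125

    def test_blob_below_extent_minimum_removed(self, rng):
        null = funcnet.cluster_extent_threshold(
            (10, 10, 10), fwhm=2, voxel_p=0.01, alpha=0.05, n_iter=500, seed=1
        )
        assert null.min_cluster_size > 1
        t_map = np.zeros((10, 10, 10))
        t_map[0, 0, 0] = 30.0  # single-voxel blob
        clusters = funcnet.apply_cluster_correction(t_map, df=39, voxel_p=0.01, null=null)
        assert clusters == []

    def test_geometry_mismatch_errors(self):
        null = self._null()
        with pytest.raises(ValueError, match="geometry"):
            funcnet.apply_cluster_correction(np.zeros((5, 5, 5)), 39, 0.005, null)

    def test_one_sided_masks_select_direction(self):
        null = self._null()
        t_map = np.zeros((10, 10, 10))
        t_map[:3] = 10.0
        pos = funcnet.apply_cluster_correction(t_map, 39, 0.005, null, sided="pos")
        neg = funcnet.apply_cluster_correction(t_map, 39, 0.005, null, sided="neg")
        assert pos and not neg
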