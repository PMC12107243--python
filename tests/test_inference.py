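import numpy as np
import pytest

from voxelgraph.grid import scatter_to_grid
from voxelgraph.inference import (
    ClusterNullDistribution, DesignSpec, build_design, cluster_extract,
    correct_clusters, glm_contrast, intersection_map, monte_carlo_null,
    run_group_inference,
)
from voxelgraph.normalization import SubjectRecord


def _subjects(n_a, n_b, n_hc=0, rng=None, groups=("FND", "PC")):
    rng = rng or np.random.default_rng(0)
    out = []
    for g, n in [(groups[0], n_a), (groups[1], n_b), ("HC", n_hc)]:
        for i in range(n):
            out.append(SubjectRecord(id=f"{g}{i}", group=g, age=40, sex="F",
                                     ssri=bool(rng.random() < 0.3)))
    return out


def _grid_index(shape):
    return np.argwhere(np.ones(shape, bool))


class TestDesign:
    def test_requires_three_per_group(self):
        subs = _subjects(2, 5)
        with pytest.raises(ValueError, match="3 subjects"):
            build_design(subs, DesignSpec(("FND", "PC")))

    def test_healthy_controls_never_enter_contrast(self):
        subs = _subjects(5, 5, n_hc=4)
        rows, x, _ = build_design(subs, DesignSpec(("FND", "PC")))
        assert all(subs[i].group != "HC" for i in rows)
        assert len(rows) == 10

    def test_subtype_contrast_selects_by_subtype(self):
        subs = _subjects(0, 5)
        for i in range(6):
            subs.append(SubjectRecord(id=f"m{i}", group="FND", age=40, sex="F",
                                      subtype="motor" if i < 4 else "seiz"))
        rows, x, gcol = build_design(subs, DesignSpec(("motor", "PC")))
        assert len(rows) == 9
        assert x[:, gcol].sum() == 4


class TestGlmContrast:
    def test_null_false_positive_rate(self, rng):
        subs = _subjects(40, 40, rng=rng)
        vals = rng.normal(size=(80, 3000))
        z = glm_contrast(vals, subs, DesignSpec(("FND", "PC")))
        frac = (np.abs(z) > 1.96).mean()
        assert 0.03 <= frac <= 0.07

    def test_one_sd_shift_gives_strong_z(self, rng):
        subs = _subjects(30, 30, rng=rng)
        vals = rng.normal(size=(60, 500))
        vals[:30, :100] += 1.0            # group A raised by 1 HC-SD in region
        z = glm_contrast(vals, subs, DesignSpec(("FND", "PC")))
        assert z[:100].mean() > 3
        assert abs(z[100:].mean()) < 0.2

    def test_covariate_absorbs_group_difference(self, rng):
        subs = _subjects(30, 30, rng=rng)
        # FND mostly treated, PC mostly not; the value tracks treatment only
        for i, s in enumerate(subs):
            s.ssri = (i % 3 != 0) if s.group == "FND" else (i % 3 == 0)
        ssri = np.array([1.0 if s.ssri else 0.0 for s in subs])
        vals = ssri[:, None] * 2.0 + 0.01 * rng.normal(size=(60, 200))
        z_adj = glm_contrast(vals, subs, DesignSpec(("FND", "PC"), covariates=("ssri",)))
        z_raw = glm_contrast(vals, subs, DesignSpec(("FND", "PC"), covariates=()))
        assert abs(z_adj.mean()) < 0.2                  # null-centred once adjusted
        assert (np.abs(z_adj) > 1.96).mean() < 0.1
        assert z_raw.mean() > 1.0                       # confounded without it


class TestClusterExtract:
    def test_subthreshold_field_yields_nothing(self, rng):
        shape = (6, 6, 6)
        idx = _grid_index(shape)
        z = rng.uniform(-1.5, 1.5, size=len(idx))
        assert cluster_extract(z, idx, shape) == []

    def test_cube_in_null_field(self):
        shape = (8, 8, 8)
        idx = _grid_index(shape)
        vol = np.zeros(shape)
        vol[2:5, 2:5, 2:5] = 5.0
        z = vol[idx[:, 0], idx[:, 1], idx[:, 2]]
        clusters = cluster_extract(z, idx, shape)
        assert len(clusters) == 1
        assert clusters[0].extent == 27
        assert clusters[0].sign == 1
        assert clusters[0].peak_z == pytest.approx(5.0)

    def test_diagonal_blocks_merge_under_26_not_6(self):
        shape = (6, 6, 6)
        idx = _grid_index(shape)
        vol = np.zeros(shape)
        vol[0:2, 0:2, 0:2] = 4.0
        vol[2:4, 2:4, 2:4] = 4.0        # touches only at a corner
        z = vol[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert len(cluster_extract(z, idx, shape, connectivity=26)) == 1
        assert len(cluster_extract(z, idx, shape, connectivity=6)) == 2

    def test_signs_kept_separate(self):
        shape = (5, 5, 5)
        idx = _grid_index(shape)
        vol = np.zeros(shape)
        vol[0, 0, 0] = 5.0
        vol[0, 0, 1] = -5.0
        z = vol[idx[:, 0], idx[:, 1], idx[:, 2]]
        clusters = cluster_extract(z, idx, shape)
        assert sorted(c.sign for c in clusters) == [-1, 1]
        assert all(c.extent == 1 for c in clusters)


class TestMonteCarloNull:
    def test_fixed_seed_reproduces_distribution(self, rng):
        subs = _subjects(8, 8, rng=rng)
        shape = (5, 5, 5)
        idx = _grid_index(shape)
        vals = rng.normal(size=(16, len(idx)))
        a = monte_carlo_null(vals, subs, DesignSpec(("FND", "PC")), idx, shape,
                             n_iter=200, seed=3)
        b = monte_carlo_null(vals, subs, DesignSpec(("FND", "PC")), idx, shape,
                             n_iter=200, seed=3)
        assert np.array_equal(a.max_extents, b.max_extents)

    def test_small_iteration_count_warns(self, rng):
        subs = _subjects(8, 8, rng=rng)
        shape = (4, 4, 4)
        idx = _grid_index(shape)
        vals = rng.normal(size=(16, len(idx)))
        with pytest.warns(UserWarning, match="unstable"):
            monte_carlo_null(vals, subs, DesignSpec(("FND", "PC")), idx, shape,
                             n_iter=50, seed=1)

    def test_matches_per_iteration_glm_oracle(self, rng):
        """The batched permutation engine equals rerunning glm_contrast on
        relabelled subjects, for a handful of fixed permutations."""
        from voxelgraph import inference as inf
        subs = _subjects(6, 6, rng=rng)
        shape = (4, 4, 4)
        idx = _grid_index(shape)
        vals = rng.normal(size=(12, len(idx)))
        design = DesignSpec(("FND", "PC"))
        null = monte_carlo_null(vals, subs, design, idx, shape, n_iter=120, seed=9)
        # oracle: replay the same permutations through the plain GLM
        rows, x, gcol = build_design(subs, design)
        g = x[:, gcol]
        rng2 = np.random.default_rng(9)
        oracle = []
        for _ in range(120):
            gp = rng2.permutation(g)
            relabelled = []
            for take, s in zip(gp, [subs[i] for i in rows]):
                relabelled.append(SubjectRecord(
                    id=s.id, group="FND" if take else "PC", age=s.age,
                    sex=s.sex, ssri=s.ssri))
            z = glm_contrast(vals[rows], relabelled, design)
            clusters = cluster_extract(z, idx, shape)
            oracle.append(max((c.extent for c in clusters), default=0))
        assert np.array_equal(null.max_extents, np.array(oracle))


class TestCorrectClusters:
    def _cluster(self, extent, sign=1):
        from voxelgraph.inference import Cluster
        return Cluster(voxels=np.arange(extent), sign=sign, extent=extent,
                       peak_z=3.0, peak_coord=(0, 0, 0))

    def test_cluster_beating_every_null_gets_floor_p(self):
        null = ClusterNullDistribution(np.full(999, 3), seed=0)
        res = correct_clusters(np.zeros(50), [self._cluster(10)], null)
        assert res.clusters[0].p_corrected == pytest.approx(1 / 1000)
        assert res.corrected_mask.sum() == 10

    def test_dominated_cluster_removed_with_p_one(self):
        null = ClusterNullDistribution(np.full(200, 5), seed=0)
        res = correct_clusters(np.zeros(50), [self._cluster(1)], null)
        assert res.clusters[0].p_corrected == 1.0
        assert not res.corrected_mask.any()

    def test_empty_cluster_list_empty_mask(self):
        null = ClusterNullDistribution(np.zeros(100), seed=0)
        res = correct_clusters(np.zeros(10), [], null)
        assert not res.corrected_mask.any()

    def test_parameter_mismatch_refused(self):
        null = ClusterNullDistribution(np.zeros(100), seed=0, threshold=2.5)
        with pytest.raises(ValueError, match="parameters"):
            correct_clusters(np.zeros(10), [], null, threshold=1.96)


class TestIntersectionMap:
    def test_idempotent(self, rng):
        m = rng.random((4, 4, 4)) > 0.5
        assert np.array_equal(intersection_map([m, m]), m)

    def test_disjoint_masks_empty(self):
        a = np.zeros((3, 3, 3), bool)
        b = np.zeros((3, 3, 3), bool)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        assert not intersection_map([a, b]).any()

    def test_three_masks_share_one_voxel(self):
        masks = []
        for i in range(3):
            m = np.zeros((3, 3, 3), bool)
            m[1, 1, 1] = True
            m[i, 0, 0] = True
            masks.append(m)
        out = intersection_map(masks)
        assert out.sum() == 1 and out[1, 1, 1]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            intersection_map([np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool)])


def test_run_group_inference_recovers_injected_block(rng):
    """A 1-SD raised 3x3x3 block at n=15/15 survives correction and the
    corrected mask covers it."""
    shape = (8, 8, 8)
    idx = _grid_index(shape)
    subs = _subjects(15, 15, rng=rng)
    vals = rng.normal(size=(30, len(idx)))
    vol = np.zeros(shape, bool)
    vol[2:5, 2:5, 2:5] = True
    region = vol[idx[:, 0], idx[:, 1], idx[:, 2]]
    vals[:15, region] += 1.5
    res = run_group_inference(vals, subs, DesignSpec(("FND", "PC")), idx, shape,
                              n_iter=500, seed=5)
    assert (res.corrected_mask & region).sum() / region.sum() >= 0.8
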