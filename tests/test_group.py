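"""Group inference: t maps, sign-flip enumeration, pseudo-t, clusters, FWE."""

import numpy as np
import pytest

from rlbold.group import (
    cluster_extract,
    enumerate_sign_flips,
    one_sample_t,
    parametric_fwe,
    pseudo_t_map,
    snpm_cluster_test,
)


def _maps_from(values, shape=(1, 1, 1)):
    return [np.full(shape, v) for v in values]


def test_one_sample_t_closed_form():
    stat = one_sample_t(_maps_from([1.0, 2.0, 3.0]))
    # mean 2, sd 1, n 3 -> t = 2 sqrt(3)
    assert stat.data[0, 0, 0] == pytest.approx(2.0 * np.sqrt(3.0))
    assert stat.df == 2 and stat.n_subjects == 3


def test_one_sample_t_zero_variance_and_symmetry():
    stat = one_sample_t(_maps_from([2.0, 2.0, 2.0]))
    assert np.isnan(stat.data[0, 0, 0])  # zero variance flagged
    sym = one_sample_t(_maps_from([-1.5, 1.5]))
    assert sym.data[0, 0, 0] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        one_sample_t(_maps_from([1.0]))


def test_sign_flip_enumeration_exhaustive():
    signs = enumerate_sign_flips(6)
    assert signs.shape == (64, 6)
    as_tuples = {tuple(s) for s in map(tuple, signs)}
    assert len(as_tuples) == 64  # all distinct
    assert tuple([1] * 6) in as_tuples  # identity present
    assert np.array_equal(signs[0], np.ones(6))  # ... and first
    signs2 = enumerate_sign_flips(2)
    assert {tuple(s) for s in signs2} == {
        (1, 1), (1, -1), (-1, 1), (-1, -1)
    }
    with pytest.raises(ValueError):
        enumerate_sign_flips(0)


def test_sign_flip_subsampling_beyond_cap():
    signs = enumerate_sign_flips(25, cap=20, seed=3, n_random=500)
    assert signs.shape == (500, 25)
    assert np.array_equal(signs[0], np.ones(25))
    again = enumerate_sign_flips(25, cap=20, seed=3, n_random=500)
    assert np.array_equal(signs, again)


def test_pseudo_t_reduces_to_t_at_zero_fwhm():
    rng = np.random.default_rng(0)
    maps = [rng.normal(size=(5, 5, 3)) for _ in range(6)]
    t = one_sample_t(maps)
    pt = pseudo_t_map(maps, fwhm=0.0)
    assert np.allclose(t.data, pt.data, equal_nan=True)
    assert pt.kind == "pseudo_t"
    with pytest.raises(ValueError):
        pseudo_t_map(maps, fwhm=-1.0)


def test_pseudo_t_constant_variance_unchanged_by_smoothing():
    rng = np.random.default_rng(1)
    base = rng.normal(size=(4, 4, 2))
    # subject maps: shared pattern +/- constant offset -> constant variance
    maps = [base + off for off in (-1.0, -0.5, 0.5, 1.0)]
    t = one_sample_t(maps)
    pt = pseudo_t_map(maps, fwhm=1.0)
    assert np.allclose(t.data, pt.data)


def test_pseudo_t_shrinks_a_lone_high_variance_voxel():
    """Smoothing the variance image pulls an outlier voxel's denominator
    toward its low-variance neighbours, raising its pseudo-t above its t."""
    rng = np.random.default_rng(2)
    maps = [0.05 * rng.normal(size=(5, 5, 1)) + 1.0 for _ in range(6)]
    for s, m in enumerate(maps):
        m[2, 2, 0] = 1.0 + 2.0 * (-1) ** s  # huge variance at the centre
    t = one_sample_t(maps).data[2, 2, 0]
    pt = pseudo_t_map(maps, fwhm=1.0, voxel_size=(0.2, 0.2, 0.3)).data[2, 2, 0]
    assert pt > t


def _brute_force_components(binary, connectivity):
    """Union-find over the voxel graph, the oracle for cluster_extract."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    vox = [tuple(v) for v in np.argwhere(binary)]
    parent = {v: v for v in vox}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for v in vox:
        for off in offsets:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if w in parent:
                parent[find(v)] = find(w)
    sizes = {}
    for v in vox:
        sizes[find(v)] = sizes.get(find(v), 0) + 1
    return sorted(sizes.values(), reverse=True)


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_cluster_extract_matches_union_find_oracle(connectivity):
    rng = np.random.default_rng(4)
    for _ in range(10):
        stat = rng.normal(size=(8, 8, 4))
        cs = cluster_extract(stat, threshold=0.5, connectivity=connectivity)
        oracle = _brute_force_components(stat > 0.5, connectivity)
        assert sorted((c.size for c in cs.clusters), reverse=True) == oracle
        assert all(np.all(stat[tuple(v)] > 0.5 for v in c.voxels) for c in cs.clusters)


def test_cluster_corner_adjacency_by_connectivity():
    stat = np.zeros((3, 3, 1))
    stat[0, 0, 0] = stat[1, 1, 0] = 10.0  # touching only at a corner (in-plane)
    for conn, expected in ((6, 2), (18, 1), (26, 1)):
        cs = cluster_extract(stat, threshold=5.0, connectivity=conn)
        assert len(cs) == expected
    # face-sharing voxels always form one cluster
    stat2 = np.zeros((3, 3, 1))
    stat2[0, 0, 0] = stat2[0, 1, 0] = 10.0
    for conn in (6, 18, 26):
        assert len(cluster_extract(stat2, 5.0, conn)) == 1
    # all-subthreshold map gives the empty set
    assert len(cluster_extract(np.zeros((3, 3, 3)), 1.0)) == 0


def test_snpm_corrected_p_has_permutation_floor():
    rng = np.random.default_rng(5)
    maps = [rng.normal(size=(8, 8, 4)) + 3.0 for _ in range(6)]
    cs = snpm_cluster_test(maps, defining_threshold=2.0, variance_fwhm=0.0)
    assert cs.n_permutations == 64
    assert len(cs) > 0
    for c in cs.clusters:
        assert c.corrected_p >= 1.0 / 64.0


def test_snpm_invariant_to_global_sign_flip():
    """Flipping every subject's map only mirrors the null distribution, so
    the critical STCS is unchanged (positive tail of -maps = negative tail)."""
    rng = np.random.default_rng(6)
    maps = [rng.normal(size=(6, 6, 3)) for _ in range(5)]
    cs_pos = snpm_cluster_test(maps, defining_threshold=1.5, variance_fwhm=0.0)
    cs_neg = snpm_cluster_test([-m for m in maps], 1.5, variance_fwhm=0.0)
    assert cs_pos.critical_stcs == cs_neg.critical_stcs


def test_snpm_detects_planted_effect():
    """A strong common effect in a block of voxels survives correction."""
    rng = np.random.default_rng(7)
    hits = 0
    for rep in range(10):
        maps = [rng.normal(size=(8, 8, 4)) for _ in range(6)]
        for m in maps:
            m[2:5, 2:5, 1] += 3.0  # effect amplitude 3x noise SD
        cs = snpm_cluster_test(maps, defining_threshold=3.0, variance_fwhm=0.5)
        if cs.significant(0.05):
            hits += 1
    assert hits >= 9


def test_parametric_fwe_extent_filter():
    rng = np.random.default_rng(8)
    from rlbold.group import StatMap

    data = rng.normal(size=(10, 10, 4))
    data[1:3, 1:3, 1:3] = 50.0  # 8-voxel block, survives extent 5
    data[8, 8, 3] = 50.0  # isolated voxel, removed by extent
    stat = StatMap(data=data, kind="t", df=5, n_subjects=6)
    out, cs = parametric_fwe(stat, alpha=0.05, voxel_extent=5)
    assert all(c.size >= 5 for c in cs.clusters)
    assert np.isnan(out[8, 8, 3])
    assert not np.isnan(out[1, 1, 1])
    # zero map: nothing survives
    zero = StatMap(data=np.zeros((4, 4, 2)), kind="t", df=5, n_subjects=6)
    out0, cs0 = parametric_fwe(zero, alpha=0.05, voxel_extent=1)
    assert len(cs0) == 0 and np.all(np.isnan(out0))
    # alpha >= 1 degenerates to the unthresholded map (extent only)
    out1, cs1 = parametric_fwe(stat, alpha=1.0, voxel_extent=1)
    assert len(cs1) == 1 and cs1.clusters[0].size == data.size
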