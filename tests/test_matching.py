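"""Component indexing, volume filter, dilation, clustering, assignment,
and the end-to-end matching pipeline."""

import numpy as np
import pytest

from lesionmatch import (
    DISAPPEARED,
    NEW,
    LabelVolume,
    MatchConfig,
    PhantomSpec,
    cluster_within_scan,
    dilate_lesions,
    extract_lesions,
    filter_by_volume,
    generate_phantom_pair,
    intersection_matrix,
    label_components,
    match_pipeline,
    restrict_graph,
    solve_assignment,
)
from lesionmatch.matching import expand_to_lesion_edges
from lesionmatch.metrics import compare_graphs
from lesionmatch.registration import RegistrationConfig
from tests.conftest import brute_force_assignment


def _vol(arr, spacing=(1.0, 1.0, 1.0)):
    return LabelVolume(np.asarray(arr, dtype=np.int32), spacing=spacing)


class TestLabelComponents:
    def test_two_separated_blobs(self):
        arr = np.zeros((10, 10, 10), dtype=np.int32)
        arr[1:3, 1:3, 1:3] = 1
        arr[7:9, 7:9, 7:9] = 1
        out = label_components(_vol(arr))
        assert out.labels() == [1, 2]
        # raster-scan order: the blob encountered first gets index 1
        assert out.voxels[1, 1, 1] == 1
        assert out.voxels[7, 7, 7] == 2

    def test_diagonal_touch_depends_on_connectivity(self):
        arr = np.zeros((4, 4, 4), dtype=np.int32)
        arr[1, 1, 1] = 1
        arr[2, 2, 2] = 1  # corner neighbour
        assert len(label_components(_vol(arr), 26).labels()) == 1
        assert len(label_components(_vol(arr), 6).labels()) == 2

    def test_empty_mask(self):
        out = label_components(_vol(np.zeros((4, 4, 4))))
        assert out.labels() == []


class TestVolumeFilter:
    def test_boundary_is_strict(self):
        # 100 voxels at 1 mm isotropic = exactly 0.1 cm3: removed
        arr = np.zeros((10, 10, 10), dtype=np.int32)
        arr.flat[:100] = 1
        lesions = extract_lesions(_vol(arr))
        assert filter_by_volume(lesions, 0.1).indices == []

    def test_just_above_threshold_retained(self):
        arr = np.zeros((10, 10, 10), dtype=np.int32)
        arr.flat[:101] = 1
        lesions = extract_lesions(_vol(arr))
        assert filter_by_volume(lesions, 0.1).indices == [1]

    def test_zero_threshold_keeps_all_and_indices_unchanged(self):
        arr = np.zeros((10, 10, 10), dtype=np.int32)
        arr[0, 0, 0] = 4
        arr[5, 5, 5] = 9
        lesions = extract_lesions(_vol(arr))
        assert filter_by_volume(lesions, 0.0).indices == [4, 9]


class TestDilation:
    @pytest.mark.parametrize(
        "spacing, radius, expected",
        [
            ((1.0, 1.0, 1.0), 2.0, 33),  # full 3D ball of offsets
            ((1.0, 1.0, 5.0), 2.0, 13),  # thick slices: in-plane disk only
        ],
    )
    def test_single_voxel_ball_matches_brute_force(self, spacing, radius, expected):
        arr = np.zeros((11, 11, 11), dtype=np.int32)
        arr[5, 5, 5] = 1
        lesions = dilate_lesions(extract_lesions(_vol(arr, spacing)), radius)
        dilated = lesions.lesions[1].dilated_mask
        # independent enumeration of integer offsets within the physical ball
        sx, sy, sz = spacing
        count = 0
        for dz in range(-5, 6):
            for dy in range(-5, 6):
                for dx in range(-5, 6):
                    if (dx * sx) ** 2 + (dy * sy) ** 2 + (dz * sz) ** 2 <= radius**2:
                        count += 1
                        assert dilated[5 + dz, 5 + dy, 5 + dx]
        assert int(dilated.sum()) == count == expected

    def test_zero_radius_is_identity(self, small_volume):
        lesions = dilate_lesions(extract_lesions(small_volume), 0.0)
        for rec in lesions.lesions.values():
            np.testing.assert_array_equal(rec.dilated_mask, rec.mask)

    def test_mask_contained_in_dilated(self, small_volume):
        lesions = dilate_lesions(extract_lesions(small_volume), 3.0)
        for rec in lesions.lesions.values():
            assert np.all(rec.dilated_mask[rec.mask])


class TestClustering:
    def _two_lesions(self, gap_voxels, spacing=(1.0, 1.0, 1.0)):
        n = gap_voxels + 10
        arr = np.zeros((5, 5, n), dtype=np.int32)
        arr[2, 2, 2] = 1
        arr[2, 2, 2 + gap_voxels] = 2
        return extract_lesions(_vol(arr, spacing))

    def test_close_lesions_form_one_cluster(self):
        lesions = dilate_lesions(self._two_lesions(10), 25.0)
        cs = cluster_within_scan(lesions)
        assert cs.clusters == [(1, 2)]

    def test_distant_lesions_stay_singletons(self):
        lesions = dilate_lesions(self._two_lesions(200, (1.0, 1.0, 1.0)), 25.0)
        cs = cluster_within_scan(lesions)
        assert cs.clusters == [(1,), (2,)]

    def test_single_lesion_singleton(self):
        arr = np.zeros((5, 5, 5), dtype=np.int32)
        arr[2, 2, 2] = 1
        cs = cluster_within_scan(dilate_lesions(extract_lesions(_vol(arr)), 2.0))
        assert cs.clusters == [(1,)]
        assert cs.cluster_masks[0].sum() == 33

    def test_partition_property(self, default_phantom):
        lesions = dilate_lesions(extract_lesions(default_phantom.labels1), 25.0)
        cs = cluster_within_scan(lesions)
        members = [i for c in cs.clusters for i in c]
        assert sorted(members) == lesions.indices  # disjoint and covering


class TestIntersectionMatrix:
    def test_disjoint_masks_all_zero(self):
        a = np.zeros((6, 6, 6), dtype=np.int32)
        b = np.zeros((6, 6, 6), dtype=np.int32)
        a[0, 0, 0] = 1
        b[5, 5, 5] = 1
        c1 = cluster_within_scan(dilate_lesions(extract_lesions(_vol(a)), 0.0))
        c2 = cluster_within_scan(dilate_lesions(extract_lesions(_vol(b)), 0.0))
        assert intersection_matrix(c1, c2).sum() == 0.0

    def test_identical_500_voxel_masks(self):
        a = np.zeros((10, 10, 10), dtype=np.int32)
        a.flat[:500] = 1
        c = cluster_within_scan(dilate_lesions(extract_lesions(_vol(a)), 0.0))
        m = intersection_matrix(c, c)
        assert m.shape == (1, 1)
        assert m[0, 0] == pytest.approx(0.5)

    def test_shifted_masks_equal_and_count(self):
        rng = np.random.default_rng(3)
        a = np.zeros((8, 8, 8), dtype=np.int32)
        a[2:6, 2:6, 2:6] = (rng.random((4, 4, 4)) < 0.5).astype(np.int32)
        b = np.roll(a, 1, axis=2)
        if not a.any() or not b.any():
            pytest.skip("degenerate draw")
        c1 = cluster_within_scan(dilate_lesions(extract_lesions(_vol(a)), 0.0))
        c2 = cluster_within_scan(dilate_lesions(extract_lesions(_vol(b)), 0.0))
        m = intersection_matrix(c1, c2)
        expected = np.logical_and(a > 0, b > 0).sum() / 1000.0
        assert m.sum() == pytest.approx(expected)


class TestSolveAssignment:
    def test_single_cell(self):
        assert solve_assignment(np.array([[2.0]])) == {(0, 0)}

    def test_total_beats_greedy(self):
        # diagonal total 8 beats anti-diagonal 3
        assert solve_assignment(np.array([[5.0, 1.0], [2.0, 3.0]])) == {(0, 0), (1, 1)}

    def test_zero_cells_forbidden(self):
        # (1,1) has value 0 and must stay unmatched even though 5+0 ties 1+4
        assert solve_assignment(np.array([[5.0, 1.0], [4.0, 0.0]])) == {(0, 0)}

    def test_matches_brute_force_on_random_matrices(self):
        """Production solver equals exhaustive enumeration with the
        zero-forbidden rule and lexicographic tie-break (integer entries so
        ties are frequent)."""
        rng = np.random.default_rng(99)
        for _ in range(60):
            shape = rng.integers(1, 6, size=2)
            m = rng.integers(0, 5, size=shape).astype(float)
            total, pairs = brute_force_assignment(m)
            got = solve_assignment(m)
            assert got == pairs, f"matrix:\n{m}"

    def test_total_invariant_under_permutation(self):
        rng = np.random.default_rng(4)
        m = rng.random((5, 4))
        perm_r = rng.permutation(5)
        perm_c = rng.permutation(4)
        t1 = sum(m[i, j] for i, j in solve_assignment(m))
        mp = m[np.ix_(perm_r, perm_c)]
        t2 = sum(mp[i, j] for i, j in solve_assignment(mp))
        assert t1 == pytest.approx(t2)


class TestExpansion:
    def _lesion_set(self, arr, dilation=0.0):
        return dilate_lesions(extract_lesions(_vol(arr)), dilation)

    def test_singleton_pair_single_edge(self):
        a = np.zeros((6, 6, 6), dtype=np.int32)
        a[2:4, 2:4, 2:4] = 1
        s1 = self._lesion_set(a)
        s2 = self._lesion_set(a)
        c1, c2 = cluster_within_scan(s1), cluster_within_scan(s2)
        g = expand_to_lesion_edges({(0, 0)}, s1, s2, c1, c2)
        assert g.edges == {(1, 1)}

    def test_merge_expansion(self):
        a = np.zeros((6, 6, 12), dtype=np.int32)
        a[2:4, 2:4, 1:4] = 1
        a[2:4, 2:4, 7:10] = 2
        b = np.zeros((6, 6, 12), dtype=np.int32)
        b[2:4, 2:4, 1:10] = 5
        s1 = self._lesion_set(a, 3.0)
        s2 = self._lesion_set(b, 3.0)
        c1, c2 = cluster_within_scan(s1), cluster_within_scan(s2)
        assert c1.clusters == [(1, 2)]
        g = expand_to_lesion_edges({(0, 0)}, s1, s2, c1, c2)
        assert g.edges == {(1, 5), (2, 5)}

    def test_unmatched_clusters_become_sentinels(self):
        a = np.zeros((6, 6, 6), dtype=np.int32)
        a[1, 1, 1] = 1
        b = np.zeros((6, 6, 6), dtype=np.int32)
        b[4, 4, 4] = 7
        s1 = self._lesion_set(a)
        s2 = self._lesion_set(b)
        g = expand_to_lesion_edges(
            set(), s1, s2, cluster_within_scan(s1), cluster_within_scan(s2)
        )
        assert g.edges == {(1, DISAPPEARED), (NEW, 7)}


@pytest.fixture(scope="module")
def small_phantom_spec():
    return PhantomSpec(
        grid_shape=(50, 70, 70),
        spacing_mm=(3.0, 3.0, 3.0),
        n_lesions=6,
        volume_range_cm3=(0.3, 3.0),
        p_disappear=0.0,
        p_new=0.0,
        p_split=0.0,
        p_merge=0.0,
        deformation_amplitude_mm=0.0,
        seed=21,
    )


class TestMatchPipeline:
    def test_identical_scans_perfect_graph(self, small_phantom_spec, field_config):
        pair = generate_phantom_pair(small_phantom_spec)
        g, prov = match_pipeline(
            pair.labels1, pair.labels1, config=MatchConfig(
                registration=RegistrationConfig(mode="identity")
            )
        )
        n = len(pair.labels1.labels())
        assert g.edges == {(i, i) for i in range(1, n + 1)}
        assert prov["counts"]["edges"] == n

    def test_deleted_lesion_becomes_disappeared(self, small_phantom_spec):
        pair = generate_phantom_pair(small_phantom_spec)
        arr2 = pair.labels1.voxels.copy()
        victim = pair.labels1.labels()[0]
        arr2[arr2 == victim] = 0
        labels2 = LabelVolume(arr2, pair.labels1.spacing)
        g, _ = match_pipeline(
            pair.labels1, labels2,
            config=MatchConfig(registration=RegistrationConfig(mode="identity")),
        )
        assert (victim, DISAPPEARED) in g.edges
        for i in pair.labels1.labels():
            if i != victim:
                assert (i, i) in g.edges

    def test_pipeline_deterministic(self, default_phantom, field_config):
        run = lambda: match_pipeline(
            default_phantom.labels1,
            default_phantom.labels2,
            displacement_field=default_phantom.displacement_field,
            config=field_config,
        )[0]
        assert run() == run()

    def test_recovers_truth_with_supplied_field(self, default_phantom, field_config):
        g, _ = match_pipeline(
            default_phantom.labels1,
            default_phantom.labels2,
            displacement_field=default_phantom.displacement_field,
            config=field_config,
        )
        truth = restrict_graph(default_phantom.truth, g.n1, g.n2)
        assert compare_graphs(g, truth).f1 >= 0.95

    def test_dilation_monotonicity(self, default_phantom):
        """More dilation never loses real-real edges on a registered pair."""
        counts = []
        for radius in (5.0, 15.0, 25.0):
            cfg = MatchConfig(
                dilation_mm=radius,
                registration=RegistrationConfig(mode="field"),
            )
            g, _ = match_pipeline(
                default_phantom.labels1,
                default_phantom.labels2,
                displacement_field=default_phantom.displacement_field,
                config=cfg,
            )
            counts.append(len(g.real_edges))
        assert counts == sorted(counts)

    def test_filter_commutes_with_matching(self, small_phantom_spec):
        """Filtering small lesions before matching equals matching everything
        then restricting the graph, when no lesion sits near the threshold."""
        pair = generate_phantom_pair(small_phantom_spec)  # all lesions >= 0.3 cm3
        idcfg = RegistrationConfig(mode="identity")
        g_all, _ = match_pipeline(
            pair.labels1, pair.labels2,
            config=MatchConfig(min_volume_cm3=0.0, registration=idcfg),
        )
        g_filt, _ = match_pipeline(
            pair.labels1, pair.labels2,
            config=MatchConfig(min_volume_cm3=0.1, registration=idcfg),
        )
        assert restrict_graph(g_all, g_filt.n1, g_filt.n2) == g_filt

    def test_empty_scans_give_empty_graph(self):
        empty = LabelVolume(np.zeros((6, 6, 6), dtype=np.int32))
        g, _ = match_pipeline(
            empty, empty,
            config=MatchConfig(registration=RegistrationConfig(mode="identity")),
        )
        assert g.edges == frozenset()
        assert g.n1 == g.n2 == frozenset()
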