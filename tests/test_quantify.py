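"""Connected components, co-occurrence, persistence and statistics.

The connected-component labelling is checked against an independent
brute-force flood fill, and the t statistic against the textbook
pooled-variance formula.
"""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npreflect.quantify import (
    axial_persistence,
    connected_components,
    cooccurrence,
    per_cell_summary,
    two_sample_ttest,
)


def flood_fill_count(mask: np.ndarray, full: bool) -> list[int]:
    """Independent oracle: BFS flood fill, returns sorted component sizes."""
    mask = np.asarray(mask, dtype=bool)
    ndim = mask.ndim
    offsets = []
    for delta in np.ndindex(*(3,) * ndim):
        d = np.array(delta) - 1
        if not d.any():
            continue
        if full or np.abs(d).sum() == 1:
            offsets.append(d)
    seen = np.zeros_like(mask)
    sizes = []
    for idx in np.argwhere(mask):
        if seen[tuple(idx)]:
            continue
        q = deque([idx])
        seen[tuple(idx)] = True
        size = 0
        while q:
            p = q.popleft()
            size += 1
            for d in offsets:
                n = p + d
                if ((n >= 0).all() and (n < mask.shape).all()
                        and mask[tuple(n)] and not seen[tuple(n)]):
                    seen[tuple(n)] = True
                    q.append(n)
        sizes.append(size)
    return sorted(sizes)


class TestConnectedComponents:
    def test_diagonal_pixels_split_by_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert len(connected_components(mask, "full")) == 1
        assert len(connected_components(mask, "face")) == 2

    def test_empty_mask_gives_empty_table(self):
        table = connected_components(np.zeros((3, 3, 3), dtype=bool))
        assert len(table) == 0

    def test_checkerboard_counts_by_enumeration(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 == 0
        assert len(connected_components(board, "face")) == 8
        assert len(connected_components(board, "full")) == 1

    def test_physical_volume_and_intensity_columns(self):
        mask = np.zeros((3, 4, 4), dtype=bool)
        mask[1, 1:3, 1:3] = True
        inten = np.where(mask, 50.0, 0.0)
        table = connected_components(
            mask, voxel_size_nm=(200.0, 60.0, 60.0), intensity=inten
        )
        assert table.n_voxels.iloc[0] == 4
        assert table.volume_nm3.iloc[0] == pytest.approx(4 * 200 * 60 * 60)
        assert table.mean_intensity.iloc[0] == 50.0
        assert table.label.tolist() == [1]

    @given(st.integers(0, 10**9))
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_flood_fill_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 9, size=rng.integers(2, 4)))
        mask = rng.random(shape) < rng.uniform(0.2, 0.7)
        for conn, full in (("full", True), ("face", False)):
            table = connected_components(mask, conn)
            assert sorted(table.n_voxels.tolist()) == flood_fill_count(mask, full)


class TestCooccurrence:
    def test_identical_masks_give_100_both_ways(self, rng):
        mask = rng.random((5, 12, 12)) < 0.2
        if not mask.any():
            mask[0, 0, 0] = True
        res = cooccurrence(mask, mask)
        assert res.pct_a_in_b == 100.0 and res.pct_b_in_a == 100.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[:2, :2] = True
        b[5:, 5:] = True
        res = cooccurrence(a, b)
        assert res.pct_a_in_b == 0.0 and res.pct_b_in_a == 0.0

    def test_two_subblobs_inside_one_blob(self):
        # A: one large blob; B: two small blobs inside it — the low-res
        # modality shows one large structure where the high-res one
        # shows two, yet both directions co-occur fully.
        a = np.zeros((16, 16), dtype=bool)
        a[4:12, 4:12] = True
        b = np.zeros((16, 16), dtype=bool)
        b[5:7, 5:7] = True
        b[9:11, 9:11] = True
        res = cooccurrence(a, b)
        assert (res.n_a, res.n_b) == (1, 2)
        assert res.pct_a_in_b == 100.0 and res.pct_b_in_a == 100.0

    def test_overlap_count_bounded_by_source_count(self, rng):
        a = rng.random((6, 20, 20)) < 0.15
        b = rng.random((6, 20, 20)) < 0.15
        res = cooccurrence(a, b)
        assert res.n_a_in_b <= res.n_a and res.n_b_in_a <= res.n_b

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            cooccurrence(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestAxialPersistence:
    def test_consecutive_slices_counted(self):
        mask = np.zeros((8, 6, 6), dtype=bool)
        mask[3:6, 2, 2] = True
        assert axial_persistence(mask) == [3]

    def test_gap_in_prelabelled_region_flagged(self):
        # a path-connected component cannot skip a slice, but a
        # pre-labelled region can: slices {2,3,5} -> longest run 2
        labels = np.zeros((8, 6, 6), dtype=int)
        labels[2, 2, 2] = labels[3, 2, 2] = labels[5, 2, 2] = 1
        labels[1, 4, 4] = 2
        with pytest.warns(RuntimeWarning, match="gap"):
            runs = axial_persistence(labels)
        assert runs == [2, 1]

    def test_rcm_persists_longer_than_rsim_for_point_reflector(self):
        from npreflect import RCM, RSIM
        from npreflect.simulate import NoiseParams, SceneParams, Cluster, generate_ground_truth, render_scene

        params = SceneParams(shape=(24, 64, 64), n_clusters=0,
                             control_flag=True, background_fraction=0.0)
        truth = generate_ground_truth(params, seed=2)
        truth.np_clusters = [Cluster((2400.0, 1920.0, 1920.0), 1000.0, 1.0)]
        truth.control_flag = False
        runs = {}
        for preset in (RCM, RSIM):
            refl = render_scene(truth, preset,
                                NoiseParams(0.0, 0.0, 0))["reflectance"].data
            mask = refl > 0.4 * refl.max()  # mid-range detection threshold
            runs[preset.modality] = max(axial_persistence(mask))
        assert runs["RCM"] > runs["RSIM"]


class TestPerCellSummary:
    def test_control_scene_counts_zero(self, rcm_stacks, small_control):
        from npreflect.segmentation import segment_np

        _, control = rcm_stacks
        mask = segment_np([control["reflectance"]], [control["reflectance"]])[0]
        # detected volume is negligible, and no component is as large as
        # a real diffraction-limited spot
        summary = per_cell_summary(small_control.cell_mask, mask)
        assert summary["n_voxels"] < 0.001 * summary["cell_voxels"]
        filtered = per_cell_summary(small_control.cell_mask, mask, min_voxels=5)
        assert filtered["n_components"] == 0

    def test_np_outside_cell_not_counted(self):
        cell = np.zeros((4, 10, 10), dtype=bool)
        cell[:, :5, :5] = True
        np_mask = np.zeros_like(cell)
        np_mask[:, 7:9, 7:9] = True
        summary = per_cell_summary(cell, np_mask)
        assert summary["n_components"] == 0

    def test_five_disjoint_blobs_counted(self):
        cell = np.ones((3, 30, 30), dtype=bool)
        np_mask = np.zeros_like(cell)
        for k in range(5):
            np_mask[1, 2 + 5 * k, 3:5] = True
        summary = per_cell_summary(cell, np_mask)
        assert summary["n_components"] == 5

    def test_empty_cell_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            per_cell_summary(np.zeros((3, 3, 3), bool), np.ones((3, 3, 3), bool))


class TestTwoSampleTTest:
    def test_identical_groups_give_t0_p1(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_clear_shift_is_significant(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res["p"] < 0.001

    def test_matches_textbook_pooled_formula(self):
        a = np.array([4.0, 6.0, 8.0])
        b = np.array([5.0, 9.0, 13.0])
        sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
        t_manual = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        res = two_sample_ttest(a, b)
        assert res["t"] == pytest.approx(t_manual)

    def test_zero_variance_in_both_groups_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_ttest([2.0, 2.0], [3.0, 3.0])
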