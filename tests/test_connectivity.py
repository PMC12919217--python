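import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attsx import (
    CORTICAL_PARCELS,
    SUBCORTICAL_PARCELS,
    InjectionRecord,
    LabeledMatrix,
    ParcelAtlas,
    Tractogram,
    VolumeGrid,
    group_sum_images,
    l2_normalize,
    sinkhorn_balance,
    streamline_connectivity,
    tracer_connectivity,
)


def small_atlas():
    """4^3 two-parcel atlas with hand-placed masks for hand computation."""
    labels = np.zeros((4, 4, 4), dtype=np.int32)
    labels[0, 0, 0] = 1  # single-voxel cortical parcel "A"
    labels[2:4, 2:4, 2:4] = 2  # 8-voxel subcortical target "B"
    labels[0, 3, 0] = 3
    return ParcelAtlas(
        VolumeGrid(labels),
        {1: ("A", "cortical"), 2: ("B", "subcortical"), 3: ("C", "subcortical")},
    )


class TestL2Normalize:
    def test_single_voxel_becomes_one(self):
        v = np.zeros((4, 4, 4))
        v[1, 2, 3] = 5.0
        out = l2_normalize(VolumeGrid(v))
        assert out.values[1, 2, 3] == pytest.approx(1.0)

    def test_scale_invariance_and_unit_norm(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(size=(8, 8, 8))
        a = l2_normalize(VolumeGrid(v))
        b = l2_normalize(VolumeGrid(3.7 * v))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)
        assert np.sum(a.values**2) == pytest.approx(1.0, abs=1e-12)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            l2_normalize(VolumeGrid(np.zeros((4, 4, 4))))


class TestGroupSums:
    def test_single_record_equals_normalized(self):
        rng = np.random.default_rng(1)
        v = VolumeGrid(rng.uniform(size=(4, 4, 4)))
        sums = group_sum_images([InjectionRecord(v, "OFC")])
        np.testing.assert_allclose(sums["OFC"].values, l2_normalize(v).values)

    def test_two_identical_records_double(self):
        v = VolumeGrid(np.random.default_rng(2).uniform(size=(4, 4, 4)))
        sums = group_sum_images([InjectionRecord(v, "OFC"), InjectionRecord(v, "OFC")])
        np.testing.assert_allclose(sums["OFC"].values, 2 * l2_normalize(v).values)

    def test_two_parcels_two_keys(self):
        rng = np.random.default_rng(3)
        recs = [
            InjectionRecord(VolumeGrid(rng.uniform(size=(4, 4, 4))), p)
            for p in ("OFC", "dlPFC")
        ]
        assert set(group_sum_images(recs)) == {"OFC", "dlPFC"}

    def test_shape_mismatch_rejected(self):
        recs = [
            InjectionRecord(VolumeGrid(np.ones((4, 4, 4))), "OFC"),
            InjectionRecord(VolumeGrid(np.ones((5, 5, 5))), "OFC"),
        ]
        with pytest.raises(ValueError, match="mismatch"):
            group_sum_images(recs)


class TestTracerConnectivity:
    def test_hand_computed_means(self):
        atlas = small_atlas()
        img1 = np.zeros((4, 4, 4))
        img1[2:4, 2:4, 2:4] = 2.0  # constant 2 over B
        img1[0, 3, 0] = 6.0  # single-voxel C
        img2 = np.zeros((4, 4, 4))
        img2[2, 2, 2] = 8.0  # one voxel of the 8-voxel B mask -> mean 1
        sums = {"A": VolumeGrid(img1), "X": VolumeGrid(img2)}
        m = tracer_connectivity(sums, atlas, ["B", "C"])
        np.testing.assert_allclose(
            m.values, [[2.0, 6.0], [1.0, 0.0]], rtol=1e-12
        )
        assert m.row_labels == ["A", "X"] and m.col_labels == ["B", "C"]

    def test_own_parcel_excluded_in_association_matrix(self):
        atlas = small_atlas()
        img = np.ones((4, 4, 4))
        m = tracer_connectivity({"A": VolumeGrid(img)}, atlas, ["A", "B"])
        assert m.loc("A", "A") == 0.0
        assert m.loc("A", "B") == 1.0

    def test_unknown_target_rejected(self):
        atlas = small_atlas()
        with pytest.raises(KeyError):
            tracer_connectivity({"A": VolumeGrid(np.ones((4, 4, 4)))}, atlas, ["Z"])


class TestStreamlineConnectivity:
    def test_empty_tractogram_zero_matrix(self):
        atlas = small_atlas()
        m = streamline_connectivity(Tractogram([]), atlas, ["A"], ["B", "C"])
        assert not m.values.any()

    def test_multi_parcel_streamline_counts_all_pairs(self):
        atlas = small_atlas()
        # visits A (0,0,0), C (0,3,0) and B (3,3,3)
        line = np.array([[0, 0, 0], [0, 3, 0], [3, 3, 3]], dtype=float)
        t = Tractogram([line])
        sq = streamline_connectivity(t, atlas, ["A", "B", "C"], ["A", "B", "C"])
        expected = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        np.testing.assert_array_equal(sq.values, expected)

    def test_points_outside_grid_ignored(self):
        atlas = small_atlas()
        line = np.array([[-5, -5, -5], [20, 20, 20]], dtype=float)
        m = streamline_connectivity(Tractogram([line]), atlas, ["A"], ["B"])
        assert not m.values.any()


class TestSinkhorn:
    def test_permutation_matrix_fixed_point(self):
        perm = np.eye(3)[[2, 0, 1]]
        m = LabeledMatrix(perm, list("abc"), list("xyz"))
        out = sinkhorn_balance(m)
        np.testing.assert_allclose(out.values, perm, atol=1e-12)
        assert out.normalization == "sinkhorn"

    def test_2x2_closed_form(self):
        out = sinkhorn_balance(LabeledMatrix([[1, 2], [3, 4]], ["r0", "r1"], ["c0", "c1"]))
        p = np.sqrt(1 * 4) / (np.sqrt(1 * 4) + np.sqrt(2 * 3))
        np.testing.assert_allclose(
            out.values, [[p, 1 - p], [1 - p, p]], atol=1e-6
        )

    def test_constant_rectangular_matrix(self):
        m = LabeledMatrix(np.full((7, 6), 3.3), list("abcdefg"), list("uvwxyz"))
        out = sinkhorn_balance(m)
        np.testing.assert_allclose(out.values, 1 / 6, atol=1e-10)

    def test_zero_row_rejected(self):
        vals = np.ones((3, 3))
        vals[1] = 0.0
        with pytest.raises(ValueError, match="all-zero row"):
            sinkhorn_balance(LabeledMatrix(vals, list("abc"), list("xyz")))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.integers(2, 6), st.integers(2, 6),
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 50.0),
    )
    def test_balancing_contract_idempotence_scale_invariance(self, r, c, seed, scale):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.05, 5.0, size=(r, c))
        m = LabeledMatrix(vals, [f"r{i}" for i in range(r)], [f"c{j}" for j in range(c)])
        out = sinkhorn_balance(m, tol=1e-12)
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(out.values.sum(axis=0), r / c, atol=1e-10)
        again = sinkhorn_balance(out, tol=1e-12)
        np.testing.assert_allclose(again.values, out.values, atol=1e-9)
        scaled = sinkhorn_balance(
            LabeledMatrix(scale * vals, m.row_labels, m.col_labels), tol=1e-12
        )
        np.testing.assert_allclose(scaled.values, out.values, atol=1e-9)
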