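"""Tests for component screening, contralateral zeroing, anatomical
filtering and component merging."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tractnmf as t
from tractnmf.errors import DomainError, InvalidMaskError, InvalidSpecError


class TestRoiMean:
    def test_constant_map_gives_constant(self):
        assert t.roi_mean(np.ones(10), np.arange(4)) == 1.0

    def test_zero_on_mask_gives_zero(self):
        gray = np.zeros(6)
        gray[4] = 7.0
        assert t.roi_mean(gray, np.array([0, 1, 2])) == 0.0

    def test_direct_mean_example(self):
        assert t.roi_mean(np.array([2.0, 4.0, 0.0, 6.0]),
                          np.array([0, 1, 3])) == pytest.approx(4.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidMaskError):
            t.roi_mean(np.ones(4), np.array([], dtype=int))


class TestScreeningScores:
    def test_known_rows_give_known_scores(self):
        # rows: uniform 1; zero; 3 on roiA and 2 on roiB
        H = np.array([
            [1.0, 1.0, 1.0, 1.0],
            [0.0, 0.0, 0.0, 0.0],
            [3.0, 3.0, 2.0, 2.0],
        ])
        roiA, roiB = np.array([0, 1]), np.array([2, 3])
        res = t.screening_scores(H, roiA, roiB)
        assert [r.product_score for r in res] == [1.0, 0.0, 6.0]
        top = max(res, key=lambda r: r.product_score)
        assert top.component_id == 2

    def test_zero_score_component_never_selected_with_positive_scores(self):
        H = np.vstack([np.zeros(4), np.ones(4)])
        res = t.screening_scores(H, np.array([0, 1]), np.array([2, 3]))
        assert not res[0].selected
        assert res[1].selected

    def test_product_identity(self):
        rng = np.random.default_rng(0)
        H = rng.uniform(size=(6, 20))
        roiA, roiB = np.arange(5), np.arange(10, 16)
        for r in t.screening_scores(H, roiA, roiB):
            assert r.product_score == r.mean_roiA * r.mean_roiB

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        H = rng.uniform(size=(7, 30))
        roiA, roiB = np.arange(8), np.arange(15, 25)
        perm = rng.permutation(7)
        base = t.screening_scores(H, roiA, roiB)
        shuffled = t.screening_scores(H[perm], roiA, roiB)
        for new_idx, old_idx in enumerate(perm):
            assert shuffled[new_idx].product_score == pytest.approx(
                base[old_idx].product_score)
            assert shuffled[new_idx].selected == base[old_idx].selected


class TestZeroContralateral:
    def test_map_already_ipsilateral_unchanged(self, desk_geometry):
        gray = np.zeros(desk_geometry.n_vertices)
        gray[: desk_geometry.n_half] = 1.0
        out = t.zero_contralateral(gray, desk_geometry.hemisphere_of, "LEFT")
        np.testing.assert_array_equal(out, gray)

    def test_idempotent(self, desk_geometry):
        rng = np.random.default_rng(2)
        gray = rng.uniform(size=desk_geometry.n_vertices)
        once = t.zero_contralateral(gray, desk_geometry.hemisphere_of,
                                    "RIGHT")
        twice = t.zero_contralateral(once, desk_geometry.hemisphere_of,
                                     "RIGHT")
        np.testing.assert_array_equal(once, twice)

    def test_sum_equals_kept_hemisphere_sum(self, desk_geometry):
        rng = np.random.default_rng(3)
        gray = rng.uniform(size=desk_geometry.n_vertices)
        out = t.zero_contralateral(gray, desk_geometry.hemisphere_of, "LEFT")
        kept = gray[desk_geometry.hemisphere_of == "LEFT"].sum()
        assert out.sum() == pytest.approx(kept)

    def test_unknown_hemisphere_rejected(self, desk_geometry):
        with pytest.raises(DomainError):
            t.zero_contralateral(np.ones(desk_geometry.n_vertices),
                                 desk_geometry.hemisphere_of, "MIDLINE")


def _synthetic_candidate(geometry, mass_by_parcel):
    gray = np.zeros(geometry.n_vertices)
    for parcel, mass in mass_by_parcel.items():
        idx = geometry.vertices_of(parcel, "LEFT")
        gray[idx] = mass / len(idx)
    return gray


class TestAnatomicalFilter:
    def test_clean_atf_candidate_passes(self, desk_geometry):
        gray = _synthetic_candidate(
            desk_geometry, {"TEMPORAL_POLE": 0.4, "OFC": 0.2,
                            "PFC_OTHER": 0.2, "OTHER": 0.2})
        ok, diag = t.anatomical_filter(gray, np.ones(desk_geometry.n_voxels),
                                       desk_geometry, "ATF")
        assert ok
        assert diag["parietal_fraction"] == 0.0

    def test_parietal_heavy_atf_candidate_fails(self, desk_geometry):
        gray = _synthetic_candidate(
            desk_geometry, {"TEMPORAL_POLE": 0.25, "OFC": 0.25,
                            "PARIETAL": 0.5})
        ok, diag = t.anatomical_filter(gray, np.ones(desk_geometry.n_voxels),
                                       desk_geometry, "ATF")
        assert not ok
        assert diag["parietal_fraction"] == pytest.approx(0.5)

    def test_zero_mass_candidate_fails_with_diagnostic(self, desk_geometry):
        ok, diag = t.anatomical_filter(
            np.zeros(desk_geometry.n_vertices),
            np.ones(desk_geometry.n_voxels), desk_geometry, "ATF")
        assert not ok
        assert diag["reason"] == "ZERO_MASS"

    def test_otf_axis_aligned_core_passes(self, desk_geometry):
        gray = _synthetic_candidate(
            desk_geometry, {"OCCIPITAL": 0.5, "OFC": 0.25, "PFC_OTHER": 0.25})
        # white mass concentrated along the anterior-posterior axis
        pos = desk_geometry.voxel_position
        white = np.exp(-((pos[:, 1] - 0.5) ** 2 + (pos[:, 2] - 0.3) ** 2)
                       / (2 * 0.05 ** 2))
        ok, diag = t.anatomical_filter(gray, white, desk_geometry, "OTF")
        assert ok
        assert diag["axis_angle_deg"] < 30.0

    def test_axis_angle_zero_for_constructed_line(self):
        # eigen-decomposition oracle: points exactly on the A-P axis
        from tractnmf.select import principal_axis_angle
        pos = np.column_stack([np.linspace(0, 1, 50),
                               np.full(50, 0.5), np.full(50, 0.5)])
        assert principal_axis_angle(np.ones(50), pos) == pytest.approx(
            0.0, abs=1e-9)


class TestMergeComponents:
    def test_single_member_identity(self, desk_geometry):
        rng = np.random.default_rng(4)
        g = rng.uniform(size=desk_geometry.n_vertices)
        w = rng.uniform(size=desk_geometry.n_voxels)
        conn = t.merge_components([(g, w)], "ATF", "LEFT",
                                  desk_geometry.hemisphere_of)
        expected = t.zero_contralateral(g, desk_geometry.hemisphere_of,
                                        "LEFT")
        np.testing.assert_array_equal(conn.gray_map, expected)
        np.testing.assert_array_equal(conn.white_map, w)

    def test_order_independent(self, desk_geometry):
        rng = np.random.default_rng(5)
        members = [(rng.uniform(size=desk_geometry.n_vertices),
                    rng.uniform(size=desk_geometry.n_voxels))
                   for _ in range(3)]
        a = t.merge_components(members, "ATF", "LEFT",
                               desk_geometry.hemisphere_of)
        b = t.merge_components(members[::-1], "ATF", "LEFT",
                               desk_geometry.hemisphere_of)
        np.testing.assert_allclose(a.gray_map, b.gray_map)
        np.testing.assert_allclose(a.white_map, b.white_map)

    def test_two_members_sum(self, desk_geometry):
        g1 = np.ones(desk_geometry.n_vertices)
        g2 = 2.0 * np.ones(desk_geometry.n_vertices)
        w1 = np.ones(desk_geometry.n_voxels)
        w2 = 3.0 * np.ones(desk_geometry.n_voxels)
        conn = t.merge_components([(g1, w1), (g2, w2)], "OTF", "RIGHT",
                                  desk_geometry.hemisphere_of)
        right = desk_geometry.hemisphere_of == "RIGHT"
        assert conn.gray_map[right].sum() == pytest.approx(3.0 * right.sum())
        assert (conn.gray_map[~right] == 0).all()
        np.testing.assert_allclose(conn.white_map, 4.0)

    def test_empty_member_list_rejected(self, desk_geometry):
        with pytest.raises(InvalidSpecError):
            t.merge_components([], "ATF", "LEFT",
                               desk_geometry.hemisphere_of)


@given(st.integers(0, 2 ** 31 - 1))
def test_zero_contralateral_idempotence_property(seed):
    rng = np.random.default_rng(seed)
    n = 20
    hemi = np.array(["LEFT"] * (n // 2) + ["RIGHT"] * (n // 2))
    gray = rng.uniform(size=n)
    once = t.zero_contralateral(gray, hemi, "LEFT")
    twice = t.zero_contralateral(once, hemi, "LEFT")
    assert np.array_equal(once, twice)
    assert np.array_equal(once[hemi == "LEFT"], gray[hemi == "LEFT"])
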