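"""Tests for the synthetic cohort generator: geometry construction,
bundle mass allocation, noise models and cohort assembly."""

import numpy as np
import pytest

import tractnmf as t
from tractnmf.errors import InvalidSpecError


class TestMakeGeometry:
    def test_parcel_counts_follow_rounding_rule(self):
        geo = t.make_geometry(
            1000, 50,
            parcel_fractions={"OFC": 0.1, "PFC_OTHER": 0.2, "OTHER": 0.7},
            seed=0)
        for hemi in ("LEFT", "RIGHT"):
            counts = geo.parcel_counts(hemi)
            assert counts["OFC"] == 50
            assert counts["PFC_OTHER"] == 100
            assert counts["OTHER"] == 350

    def test_other_absorbs_rounding_residual(self):
        # 0.33/0.33/0.34 on 50 per hemisphere rounds to 17+17+17 = 51;
        # OTHER absorbs the residual so counts still sum to 50
        geo = t.make_geometry(
            100, 10,
            parcel_fractions={"OFC": 0.33, "PFC_OTHER": 0.33, "OTHER": 0.34},
            seed=0)
        counts = geo.parcel_counts("LEFT")
        assert sum(counts.values()) == 50

    def test_fractions_not_summing_to_one_rejected(self):
        with pytest.raises(InvalidSpecError):
            t.make_geometry(100, 10,
                            parcel_fractions={"OFC": 0.5, "PFC_OTHER": 0.4},
                            seed=0)

    def test_required_parcel_with_zero_vertices_rejected(self):
        with pytest.raises(InvalidSpecError):
            t.make_geometry(
                100, 10,
                parcel_fractions={"OFC": 0.0, "PFC_OTHER": 0.5, "OTHER": 0.5},
                seed=0)

    def test_odd_vertex_count_rejected(self):
        with pytest.raises(InvalidSpecError):
            t.make_geometry(101, 10, seed=0)

    def test_seed_determinism_and_hemisphere_symmetry(self):
        a = t.make_geometry(200, 30, seed=5)
        b = t.make_geometry(200, 30, seed=5)
        assert np.array_equal(a.parcel_of, b.parcel_of)
        assert np.array_equal(a.voxel_position, b.voxel_position)
        # right half repeats the left half's labels (mirror convention)
        half = a.n_half
        assert np.array_equal(a.parcel_of[:half], a.parcel_of[half:])


class TestMakeBundles:
    def test_ofc_fraction_one_puts_all_prefrontal_mass_in_ofc(
            self, desk_geometry):
        spec = t.CohortSpec(species_list=(t.SpeciesSpec("sp", 1, 1.0),),
                            seed=0)
        atf = t.make_bundles(desk_geometry, spec, "sp", "LEFT")[0]
        pfc_other = desk_geometry.vertices_of("PFC_OTHER")
        assert atf.gray_loading[pfc_other].sum() == 0.0
        assert atf.gray_loading[desk_geometry.vertices_of("OFC")].sum() > 0

    def test_half_fraction_balances_ofc_and_pfc_other_mass(self):
        # |OFC| = 50, |PFC_OTHER| = 100 per hemisphere: equal mass despite
        # the 1:2 size ratio
        geo = t.make_geometry(
            1000, 60,
            parcel_fractions={"OFC": 0.1, "PFC_OTHER": 0.2,
                              "TEMPORAL_POLE": 0.1, "OCCIPITAL": 0.1,
                              "PARIETAL": 0.1, "OTHER": 0.4},
            seed=1)
        spec = t.CohortSpec(species_list=(t.SpeciesSpec("sp", 1, 0.5),),
                            n_distractors=0, seed=1)
        atf = t.make_bundles(geo, spec, "sp", "LEFT")[0]
        m_ofc = atf.gray_loading[geo.vertices_of("OFC")].sum()
        m_other = atf.gray_loading[geo.vertices_of("PFC_OTHER")].sum()
        assert m_ofc == pytest.approx(m_other, abs=1e-9)

    def test_realized_fraction_exact_by_construction(self, desk_geometry):
        spec = t.CohortSpec(species_list=(t.SpeciesSpec("sp", 1, 0.37),),
                            seed=2)
        for b in t.make_bundles(desk_geometry, spec, "sp", "LEFT")[:2]:
            ofc = b.gray_loading[desk_geometry.vertices_of("OFC")].sum()
            pfc = b.gray_loading[
                desk_geometry.vertices_of(("OFC", "PFC_OTHER"))].sum()
            assert ofc / pfc == pytest.approx(b.ofc_fraction, abs=1e-9)

    def test_loadings_confined_to_requested_hemisphere(self, desk_geometry):
        spec = t.CohortSpec(species_list=(t.SpeciesSpec("sp", 1, 0.5),),
                            seed=0)
        for hemi in ("LEFT", "RIGHT"):
            for b in t.make_bundles(desk_geometry, spec, "sp", hemi):
                nz = np.flatnonzero(b.gray_loading)
                assert set(desk_geometry.hemisphere_of[nz]) == {hemi}

    def test_expected_bundle_classes_present(self, desk_geometry):
        spec = t.CohortSpec(species_list=(t.SpeciesSpec("sp", 1, 0.5),),
                            n_distractors=3, seed=0)
        classes = [b.bundle_class
                   for b in t.make_bundles(desk_geometry, spec, "sp", "LEFT")]
        assert classes.count("ATF") == 1
        assert classes.count("OTF") == 1
        assert classes.count("DISTRACTOR") == 3

    def test_invalid_ofc_fraction_rejected(self):
        with pytest.raises(InvalidSpecError):
            t.CohortSpec(species_list=(t.SpeciesSpec("sp", 1, 1.5),), seed=0)


class TestSampleConnectivity:
    def test_noiseless_single_bundle_equals_outer_product(
            self, desk_geometry, noiseless_spec):
        b = t.make_bundles(desk_geometry, noiseless_spec, "sp", "LEFT")[0]
        V = t.sample_connectivity(desk_geometry, [b], 3.0,
                                  t.NoiseModel("POISSON", 0.0), seed=0)
        expected = 3.0 * np.outer(b.gray_loading, b.white_loading)
        np.testing.assert_allclose(V.values, expected)

    def test_poisson_noise_yields_nonnegative_integers(
            self, desk_geometry, noiseless_spec):
        bundles = t.make_bundles(desk_geometry, noiseless_spec, "sp", "LEFT")
        V = t.sample_connectivity(desk_geometry, bundles, 50.0,
                                  t.NoiseModel("POISSON", 1.0), seed=0)
        assert V.values.min() >= 0
        np.testing.assert_array_equal(V.values, np.round(V.values))

    def test_replicate_mean_approaches_noiseless_signal(
            self, desk_geometry, noiseless_spec):
        # Monte-Carlo oracle: the mean over seeded Poisson replicates
        # converges to the noiseless matrix
        bundles = t.make_bundles(desk_geometry, noiseless_spec, "sp",
                                 "LEFT")[:1]
        clean = t.sample_connectivity(desk_geometry, bundles, 40.0,
                                      t.NoiseModel("POISSON", 0.0),
                                      seed=0).values

        def mean_of(n):
            acc = np.zeros_like(clean)
            for s in range(n):
                acc += t.sample_connectivity(
                    desk_geometry, bundles, 40.0,
                    t.NoiseModel("POISSON", 1.0), seed=s).values
            return acc / n

        dev10 = np.abs(mean_of(10) - clean).max()
        dev100 = np.abs(mean_of(100) - clean).max()
        assert dev100 < dev10

    def test_truncated_gaussian_clips_at_zero(self, desk_geometry,
                                              noiseless_spec):
        bundles = t.make_bundles(desk_geometry, noiseless_spec, "sp", "LEFT")
        V = t.sample_connectivity(desk_geometry, bundles, 1.0,
                                  t.NoiseModel("TRUNCATED_GAUSSIAN", 5.0),
                                  seed=0)
        assert V.values.min() >= 0.0


class TestMakeCohort:
    def test_study_design_yields_18_matrices(self, desk_geometry):
        spec = t.default_cohort_spec(seed=4)
        matrices, truth = t.make_cohort(spec, desk_geometry)
        assert len(matrices) == 18  # 3 species x 3 subjects x 2 hemispheres
        assert len({(m.subject_id, m.hemisphere) for m in matrices}) == 18

    def test_zero_hemisphere_sd_gives_identical_fractions(
            self, desk_geometry):
        spec = t.CohortSpec(species_list=(t.SpeciesSpec("sp", 2, 0.6),),
                            hemisphere_sd=0.0, seed=5)
        _, truth = t.make_cohort(spec, desk_geometry)
        atf = {(b.subject_id, b.hemisphere): b.ofc_fraction
               for b in truth if b.bundle_class == "ATF"}
        for subj in {s for s, _ in atf}:
            assert atf[(subj, "LEFT")] == atf[(subj, "RIGHT")]

    def test_seed_determinism_bit_identical(self, desk_geometry):
        spec = t.CohortSpec(species_list=(t.SpeciesSpec("sp", 1, 0.6),),
                            seed=6)
        m1, _ = t.make_cohort(spec, desk_geometry)
        m2, _ = t.make_cohort(spec, desk_geometry)
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_true_obi_monotone_in_ofc_fraction(self, desk_geometry):
        obis = []
        for f in (0.2, 0.5, 0.8):
            spec = t.CohortSpec(species_list=(t.SpeciesSpec("sp", 1, f),),
                                seed=7)
            atf = t.make_bundles(desk_geometry, spec, "sp", "LEFT")[0]
            obis.append(atf.true_obi(desk_geometry))
        assert obis[0] < obis[1] < obis[2]

    def test_all_matrices_nonnegative_finite(self, desk_geometry):
        spec = t.CohortSpec(species_list=(t.SpeciesSpec("sp", 1, 0.5),),
                            seed=8)
        matrices, _ = t.make_cohort(spec, desk_geometry)
        for m in matrices:
            assert np.isfinite(m.values).all()
            assert m.values.min() >= 0


def test_mirror_to_canonical_swaps_halves(desk_geometry):
    v = np.arange(desk_geometry.n_vertices, dtype=float)
    mirrored = t.mirror_to_canonical(v, desk_geometry, "RIGHT")
    half = desk_geometry.n_half
    assert np.array_equal(mirrored[:half], v[half:])
    assert np.array_equal(t.mirror_to_canonical(v, desk_geometry, "LEFT"), v)
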