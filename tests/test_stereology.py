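import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovistereo.config import COMPARTMENTS, StereologyConfig
from ovistereo.stereology import (
    gonadosomatic_index,
    morphometry_table,
    parenchyma_volume_ml,
    percent_reduction,
    somatic_index,
    summarize_tubule_profiles,
    total_tubule_length_m,
    tubular_fraction,
    volumetric_proportions,
)
from ovistereo.validation import cylinder_phantom_volume_ml


class TestTubuleProfiles:
    def test_constant_profiles(self):
        d, h = [200.0] * 30, [45.0] * 30
        assert summarize_tubule_profiles(d, h) == (200.0, 45.0)

    def test_two_point_mean(self):
        assert summarize_tubule_profiles([100, 300], [20, 40]) == (200.0, 30.0)

    @pytest.mark.parametrize(
        "d, h",
        [([], []), ([100], [60]), ([100, 200], [-1, 20]), ([100, 200], [20])],
    )
    def test_invalid_profiles_rejected(self, d, h):
        with pytest.raises(ValueError):
            summarize_tubule_profiles(d, h)


class TestVolumetricProportions:
    def test_degenerate_single_compartment(self):
        fields = np.zeros((3, 6))
        fields[:, 0] = 10  # every point in the lumen
        assert volumetric_proportions(fields).tolist() == [100, 0, 0, 0, 0, 0]

    def test_pooling_weights_every_point_equally(self):
        fields = [[10, 10, 0, 0, 0, 0], [0, 10, 10, 0, 0, 0]]
        assert volumetric_proportions(fields).tolist() == [25, 50, 25, 0, 0, 0]

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            volumetric_proportions(np.zeros((2, 6)))

    @given(
        st.lists(
            st.lists(st.integers(0, 500), min_size=6, max_size=6),
            min_size=1,
            max_size=10,
        ).filter(lambda f: sum(map(sum, f)) > 0)
    )
    @settings(deadline=None)
    def test_proportions_always_sum_to_100(self, fields):
        assert volumetric_proportions(np.array(fields)).sum() == pytest.approx(100.0)


class TestIndices:
    def test_gsi_simple(self):
        assert gonadosomatic_index(1, 100) == 1.0

    def test_gsi_matches_back_solved_body_masses(self):
        # published TW/GSI pairs pin down the body masses used in calibration
        assert gonadosomatic_index(109.78, 16633) == pytest.approx(0.66, abs=0.005)
        assert gonadosomatic_index(22.18, 17061) == pytest.approx(0.13, abs=0.005)

    def test_gsi_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gonadosomatic_index(0, 100)

    def test_somatic_index_bounds(self):
        assert somatic_index(0.0, 100, 1000) == 0.0
        assert somatic_index(1.0, 1, 100) == pytest.approx(1.0)

    def test_leydigosomatic_plug_in(self):
        # Leydig fraction 1.96% of a 109.78 g pair in a 16.6 kg lamb
        assert somatic_index(0.0196, 109.78, 16633) == pytest.approx(0.0129, abs=0.0002)


class TestParenchymaVolume:
    def test_defaults_are_identity_like(self):
        assert parenchyma_volume_ml(109.78) == pytest.approx(109.78)

    def test_nonparenchyma_discounted(self):
        cfg = StereologyConfig(nonparenchyma_fraction=0.1)
        assert parenchyma_volume_ml(100, cfg) == pytest.approx(90.0)


class TestTubuleLength:
    def test_cylinder_inversion(self):
        # 1 m of tubule with 200 µm diameter occupies pi*(100 µm)^2 * 1 m
        volume_ml = np.pi * 100**2 * 1e6 / 1e12
        assert total_tubule_length_m(volume_ml, 1.0, 200.0) == pytest.approx(1.0)

    def test_phantom_recovery_is_exact(self):
        for length, diam, fill in [(1.0, 200.0, 1.0), (3078.0, 204.6, 0.92), (15000.0, 90.0, 0.85)]:
            vol = cylinder_phantom_volume_ml(length, diam, fill)
            assert total_tubule_length_m(vol, fill, diam) == pytest.approx(length, rel=1e-12)

    def test_group_mean_plug_in(self):
        # control group means: 109.78 mL parenchyma, 92.18% tubular, 204.60 µm
        tlst = total_tubule_length_m(109.78, 0.9218, 204.60)
        assert tlst == pytest.approx(3078, abs=2)

    @given(st.floats(50, 500), st.floats(60, 600))
    @settings(deadline=None)
    def test_monotone_decreasing_in_diameter(self, d1, d2):
        lo, hi = sorted([d1, d2])
        if hi - lo < 1e-6:
            return
        assert total_tubule_length_m(100, 0.9, lo) > total_tubule_length_m(100, 0.9, hi)


class TestPercentReduction:
    @pytest.mark.parametrize(
        "control, treated, expected",
        [(204.60, 91.59, 55.23), (204.60, 87.94, 57.02), (0.66, 0.13, 80.30), (5.0, 5.0, 0.0)],
    )
    def test_examples(self, control, treated, expected):
        assert percent_reduction(control, treated) == pytest.approx(expected, abs=0.005)

    def test_total_reduction_is_100(self):
        assert percent_reduction(3.7, 0.0) == 100.0

    @given(st.floats(0.1, 1e6), st.floats(0, 1e6))
    def test_antisymmetric_around_equality(self, c, t):
        r = percent_reduction(c, t)
        assert r <= 100.0 * (1 + 1e-12)
        assert (r > 0) == (t < c)
        assert (r < 0) == (t > c)


class TestMorphometryTable:
    def test_per_gram_identity_and_proportion_sum(self, small_cohort):
        table = morphometry_table(small_cohort)
        assert np.allclose(table["TLST_per_g"] * table["TW"], table["TLST"])
        pct = table[list(COMPARTMENTS)].sum(axis=1)
        assert np.allclose(pct, 100.0)
        assert (table[["STD", "GEH", "GSI", "TLST"]] > 0).all().all()

    def test_tubular_fraction_from_dict(self):
        pct = dict(zip(COMPARTMENTS, [30, 55, 5, 2, 1, 7]))
        assert tubular_fraction(pct) == pytest.approx(0.90)
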