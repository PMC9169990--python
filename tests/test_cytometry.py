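import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovistereo.config import CELL_CLASSES, StereologyConfig
from ovistereo.cytometry import (
    NuclearGeometry,
    abercrombie_correct,
    abercrombie_factor,
    corrected_populations,
    daily_sperm_production,
    general_yield_percent,
    intrinsic_yields,
    inverse_abercrombie,
    meiotic_loss_percent,
    sertoli_indices,
    total_population,
)
from ovistereo.validation import sphere_slab_factor


class TestThicknessCorrection:
    def test_zero_diameter_is_identity(self):
        assert abercrombie_correct(10, 3, 0) == 10.0

    def test_closed_form(self):
        assert abercrombie_correct(10, 3, 7) == pytest.approx(3.0)
        assert inverse_abercrombie(3, 3, 7) == pytest.approx(10.0)
        assert inverse_abercrombie(5, 3, 0) == 5.0

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            abercrombie_factor(0, 5)
        with pytest.raises(ValueError):
            abercrombie_factor(3, -1)

    @given(st.floats(0, 1e4), st.floats(1e-3, 100), st.floats(0, 500))
    @settings(deadline=None)
    def test_round_trip_identity(self, x, thickness, diameter):
        back = abercrombie_correct(inverse_abercrombie(x, thickness, diameter), thickness, diameter)
        assert back == pytest.approx(x, rel=1e-9, abs=1e-12)

    @given(st.floats(1e-3, 100), st.floats(0, 500))
    def test_factor_in_unit_interval(self, thickness, diameter):
        f = abercrombie_factor(thickness, diameter)
        assert 0 < f <= 1
        if diameter == 0:
            assert f == 1
        elif diameter > 1e-6 * thickness:  # below this, T/(T+D) rounds to 1.0
            assert f < 1

    def test_matches_sphere_slab_sectioning(self):
        """The T/(T+D) factor equals the Monte-Carlo sphere-slab ratio."""
        rng = np.random.default_rng(42)
        thickness = 3.0
        for ratio in (0.5, 2.0, 4.0):
            diameter = ratio * thickness
            mc = sphere_slab_factor(diameter, thickness, n_spheres=400_000, rng=rng)
            assert mc == pytest.approx(abercrombie_factor(thickness, diameter), rel=0.02)


class TestCorrectedPopulations:
    def geometry(self, diam=3.0):
        return NuclearGeometry({c: diam for c in CELL_CLASSES}, section_thickness_um=3.0)

    def test_all_zero_counts(self):
        counts = pd.DataFrame(np.zeros((5, 5), dtype=int), columns=CELL_CLASSES)
        assert (corrected_populations(counts, self.geometry()) == 0).all()

    def test_single_tubule_scale(self):
        counts = pd.DataFrame([{c: 0 for c in CELL_CLASSES} | {"S": 10.55}])
        pops = corrected_populations(counts, self.geometry(diam=3.0))
        assert pops["S"] == pytest.approx(5.275)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            corrected_populations(pd.DataFrame(columns=CELL_CLASSES), self.geometry())


class TestYieldRatios:
    def test_control_scale(self):
        pops = {"A": 1.0, "PL": 12.37, "PQ": 0.0, "Ar": 0.0, "S": 1.0}
        assert intrinsic_yields(pops)["A_PL"] == pytest.approx(12.37)

    def test_all_zero_convention(self):
        pops = {c: 0.0 for c in CELL_CLASSES}
        assert all(v == 0.0 for v in intrinsic_yields(pops).values())

    def test_chain_identity_example(self):
        y = intrinsic_yields({"A": 2, "PL": 4, "PQ": 4, "Ar": 12, "S": 1})
        assert (y["A_PL"], y["PL_PQ"], y["PQ_Ar"], y["A_Ar"]) == (2, 1, 3, 6)
        assert y["A_Ar"] == y["A_PL"] * y["PL_PQ"] * y["PQ_Ar"]

    def test_zero_denominator_with_positive_numerator_is_undefined(self):
        with pytest.warns(UserWarning):
            y = intrinsic_yields({"A": 0.0, "PL": 2.0, "PQ": 1.0, "Ar": 1.0, "S": 1.0})
        assert np.isnan(y["A_PL"])

    @given(
        st.floats(0.01, 100), st.floats(0.01, 100), st.floats(0.01, 100), st.floats(0.01, 100)
    )
    def test_chain_identity_property(self, a, pl, pq, ar):
        y = intrinsic_yields({"A": a, "PL": pl, "PQ": pq, "Ar": ar, "S": 1.0})
        assert y["A_Ar"] == pytest.approx(y["A_PL"] * y["PL_PQ"] * y["PQ_Ar"], rel=1e-9)


class TestSertoliIndices:
    def test_no_germ_cells(self):
        idx = sertoli_indices({"A": 0, "PL": 0, "PQ": 0, "Ar": 0, "S": 1.0})
        assert all(v == 0.0 for v in idx.values())

    def test_control_plug_in_additivity(self):
        pops = {"A": 0.95, "PL": 11.46, "PQ": 15.44, "Ar": 50.29, "S": 5.27}
        idx = sertoli_indices(pops)
        assert idx["S_CG"] == pytest.approx(14.82, abs=0.01)
        # group-mean plug-in sits within 10% of the per-animal published mean
        assert idx["S_CG"] == pytest.approx(15.36, rel=0.10)

    @given(st.floats(0, 100), st.floats(0, 100), st.floats(0, 100), st.floats(0, 100),
           st.floats(0.01, 50))
    def test_additivity_property(self, a, pl, pq, ar, s):
        idx = sertoli_indices({"A": a, "PL": pl, "PQ": pq, "Ar": ar, "S": s})
        assert idx["S_CG"] == pytest.approx(
            idx["S_A"] + idx["S_PL"] + idx["S_PQ"] + idx["S_Ar"], rel=1e-9, abs=1e-12
        )


class TestYieldPercentages:
    def test_general_yield(self):
        assert general_yield_percent(53.79) == pytest.approx(21.01, abs=0.005)
        assert general_yield_percent(256) == 100.0
        assert general_yield_percent(0) == 0.0

    def test_meiotic_loss(self):
        assert meiotic_loss_percent(3.16) == pytest.approx(21.0)
        assert meiotic_loss_percent(4) == 0.0
        assert meiotic_loss_percent(0) == 100.0
        assert meiotic_loss_percent(5) == 0.0  # clamped when above theory


class TestProductionEstimates:
    def test_unit_conversion(self):
        # 1 cell per section, 3 m of tubule in 3 µm sections -> 1e6 sections
        assert total_population(1.0, 3e-6 * 1e6, 3.0) == pytest.approx(1e6)
        assert total_population(0.0, 100.0, 3.0) == 0.0

    def test_sertoli_population_plug_in(self):
        # control means: 5.27 Sertoli/section over 3835.7 m of tubule
        nsct = total_population(5.27, 3835.7, 3.0)
        assert nsct == pytest.approx(7.05e9, rel=0.05)

    def test_daily_production(self):
        cfg = StereologyConfig(sec_duration_days=1.0)
        assert daily_sperm_production(5.0, cfg) == 5.0
        assert daily_sperm_production(0.0) == 0.0
        assert daily_sperm_production(47.53e9) == pytest.approx(4.53e9, rel=0.005)
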