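"""Formation thermodynamics: reaction energies, corrections, constants,
stability ordering, and regression against published chelation tables."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metallokin import (
    Reaction,
    formation_constant,
    ph_corrected_formation,
    rank_stability,
    reaction_gibbs,
    standard_state_correction,
)
from metallokin import refdata
from metallokin.constants import LN10, rt_kcal
from metallokin.errors import ConfigError, SpeciesLookupError


def _rxn(reactants, products, **kw):
    return Reaction(reactants=tuple(reactants), products=tuple(products), **kw)


class TestReactionGibbs:
    def test_identity_reaction_is_zero(self):
        rxn = _rxn([("A", 1)], [("A", 1)])
        assert reaction_gibbs(rxn, {"A": -42.0}) == 0.0

    def test_simple_arithmetic(self):
        rxn = _rxn([("A", 1), ("B", 1)], [("C", 1)])
        assert reaction_gibbs(rxn, {"A": -10.0, "B": -5.0, "C": -20.0}) == -5.0

    def test_linear_in_coefficients(self):
        energies = {"A": -10.0, "B": -5.0, "C": -20.0}
        single = reaction_gibbs(_rxn([("A", 1), ("B", 1)], [("C", 1)]), energies)
        double = reaction_gibbs(_rxn([("A", 2), ("B", 2)], [("C", 2)]), energies)
        assert double == pytest.approx(2 * single, rel=1e-14)

    def test_missing_energy_names_label(self):
        rxn = _rxn([("A", 1)], [("Z", 1)])
        with pytest.raises(SpeciesLookupError, match="Z"):
            reaction_gibbs(rxn, {"A": 0.0})


class TestStandardStateCorrection:
    def test_balanced_species_count_is_zero(self):
        rxn = _rxn([("A", 1), ("B", 1)], [("C", 1), ("D", 1)])
        assert standard_state_correction(rxn, "one_molar_all") == 0.0

    def test_positive_delta_n(self):
        rxn = _rxn([("A", 1)], [("B", 1), ("C", 1)])  # dn = +1
        corr = standard_state_correction(rxn, "one_molar_all", T=298.15)
        assert corr == pytest.approx(rt_kcal(298.15) * math.log(24.46), rel=1e-12)
        assert corr == pytest.approx(1.89, abs=0.005)

    def test_negative_delta_n(self):
        rxn = _rxn([("A", 2), ("B", 1)], [("C", 1)])  # dn = -2
        corr = standard_state_correction(rxn, "one_molar_all", T=298.15)
        assert corr == pytest.approx(-3.79, abs=0.005)

    def test_none_convention(self):
        rxn = _rxn([("A", 1)], [("B", 2)])
        assert standard_state_correction(rxn, "none") == 0.0

    def test_unknown_convention_rejected(self):
        rxn = _rxn([("A", 1)], [("B", 1)])
        with pytest.raises(ConfigError):
            standard_state_correction(rxn, "two_molar")

    def test_protons_excluded_and_water_term_added(self):
        from conftest import scheme_species
        from metallokin import build_scheme_reaction

        species = scheme_species("18", 2)
        rxn = build_scheme_reaction("18", 2, n=0, ligand_label="L", complex_label="MLx")
        # products: complex + 4 water + 4 H+; reactants: 2 L + aqua ion
        # protons never count; dn = (1 + 4) - 3 = +2
        corr = standard_state_correction(rxn, "one_molar_all", species=species)
        assert corr == pytest.approx(2 * rt_kcal(298.15) * math.log(24.46), rel=1e-12)
        with_water = standard_state_correction(
            rxn, "one_molar_solutes_55M_water", species=species
        )
        assert with_water == pytest.approx(
            corr + 4 * rt_kcal(298.15) * math.log(55.34), rel=1e-12
        )


class TestPhCorrectedFormation:
    @pytest.mark.parametrize(
        "raw,x,pen,expected",
        [(-10.0, 1, 0.0, -10.0), (-10.0, 1, 2.2, -7.8), (-20.0, 3, 2.2, -13.4)],
    )
    def test_values(self, raw, x, pen, expected):
        assert ph_corrected_formation(raw, x, pen) == pytest.approx(expected, abs=1e-12)

    def test_negative_ligand_count_rejected(self):
        with pytest.raises(ValueError):
            ph_corrected_formation(-10.0, -1, 2.2)

    @given(raw=st.floats(-60, 0), pen=st.floats(0, 10), x=st.integers(0, 4))
    @settings(max_examples=100, derandomize=True)
    def test_affine_in_x_with_slope_penalty(self, raw, pen, x):
        base = ph_corrected_formation(raw, x, pen)
        step = ph_corrected_formation(raw, x + 1, pen)
        assert step - base == pytest.approx(pen, abs=1e-9)


class TestFormationConstant:
    def test_zero_energy_gives_unit_constant(self):
        kf, logkf = formation_constant(0.0)
        assert kf == 1.0
        assert logkf == 0.0

    @pytest.mark.parametrize("dgf,logkf", [(-20.7, 15.17), (-51.1, 37.45)])
    def test_published_spot_values(self, dgf, logkf):
        _, log_calc = formation_constant(dgf, T=298.15)
        assert log_calc == pytest.approx(logkf, abs=0.05)

    def test_log_space_avoids_overflow(self):
        kf, logkf = formation_constant(-500.0)
        assert math.isfinite(logkf)
        assert logkf == pytest.approx(500.0 / (rt_kcal(298.15) * LN10), rel=1e-12)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            formation_constant(-10.0, T=-1.0)

    @given(dgf=st.floats(-80, 80))
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_recovers_energy(self, dgf):
        kf, _ = formation_constant(dgf, T=298.15)
        assert -rt_kcal(298.15) * math.log(kf) == pytest.approx(dgf, abs=1e-9)

    @given(d1=st.floats(-60, 0), d2=st.floats(-60, 0))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_stability(self, d1, d2):
        if abs(d1 - d2) < 1e-6:
            return
        lo, hi = sorted([d1, d2])
        kf_lo, log_lo = formation_constant(lo)
        kf_hi, log_hi = formation_constant(hi)
        assert kf_lo > kf_hi and log_lo > log_hi


class TestTableRegression:
    @pytest.mark.parametrize("label", sorted(refdata.ALL_COMPLEXES))
    def test_logkf_consistent_with_printed_dgf(self, label):
        """The printed logKf must follow from the printed dGf within the
        rounding envelope of a 1-decimal free energy (+-0.05 log units)."""
        _, _, _, dgf, _, logkf = refdata.ALL_COMPLEXES[label]
        _, log_calc = formation_constant(dgf, T=298.15)
        assert log_calc == pytest.approx(logkf, abs=0.05)

    @pytest.mark.parametrize("label", sorted(refdata.ALL_COMPLEXES))
    def test_printed_kf_consistent_with_printed_logkf(self, label):
        _, _, _, _, kf, logkf = refdata.ALL_COMPLEXES[label]
        assert math.log10(kf) == pytest.approx(logkf, abs=0.01)


class TestRankStability:
    def test_cu_ordering_from_best_complexes(self):
        best = {"ASC": -13.7, "AG": -29.7, "AMD": -35.3, "PM": -35.8}
        assert rank_stability(best) == ["ASC", "AG", "AMD", "PM"]

    def test_fe_ordering_from_best_complexes(self):
        best = {"AG": -37.9, "ASC": -46.9, "AMD": -48.9, "PM": -58.9}
        assert rank_stability(best) == ["AG", "ASC", "AMD", "PM"]

    def test_singleton(self):
        assert rank_stability({"PM": -35.8}) == ["PM"]

    def test_ties_break_lexicographically(self):
        assert rank_stability({"B": -10.0, "A": -10.0}) == ["A", "B"]

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            rank_stability({})
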