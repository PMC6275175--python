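"""Delta/atom-fraction conversions, the FAME correction and the mixing model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plfasip import isotope
from plfasip.errors import (
    DegenerateEndmemberError,
    InvalidBiomarkerError,
    InvalidIsotopeValueError,
    InvalidMeasurementError,
)

C = isotope.DEFAULT_CONSTANTS
EM = isotope.DEFAULT_ENDMEMBERS

# frozen from an independent high-precision (Decimal) evaluation of
# AF = R/(1+R), R = 0.0111802 * (delta/1000 + 1)
AF_AT_STANDARD = 0.011056585166521259
AF_LITTER = 0.020843405133899445  # delta = 904.0
AF_SOIL = 0.010775492829704162    # delta = -25.7
EXCESS_PURE_LITTER_1000NMOL = 10.067912304195283


class TestAtomFractionConversion:
    @pytest.mark.parametrize(
        "delta, expected",
        [
            (-1000.0, 0.0),
            (0.0, AF_AT_STANDARD),
            (904.0, AF_LITTER),
            (-25.7, AF_SOIL),
        ],
    )
    def test_known_values(self, delta, expected):
        assert isotope.delta_to_atom_fraction(delta, C) == pytest.approx(
            expected, abs=1e-15
        )

    def test_inverse_at_zero(self):
        assert isotope.atom_fraction_to_delta(0.0, C) == pytest.approx(-1000.0)
        assert isotope.atom_fraction_to_delta(
            C.r_vpdb / (1 + C.r_vpdb), C
        ) == pytest.approx(0.0, abs=1e-9)

    @given(st.floats(min_value=-1000.0, max_value=2000.0))
    def test_round_trip(self, delta):
        back = isotope.atom_fraction_to_delta(
            isotope.delta_to_atom_fraction(delta, C), C
        )
        assert back == pytest.approx(delta, abs=1e-9)

    @given(
        st.floats(min_value=-999.0, max_value=2000.0),
        st.floats(min_value=1e-6, max_value=100.0),
    )
    def test_strictly_increasing(self, delta, step):
        assert isotope.delta_to_atom_fraction(
            delta + step, C
        ) > isotope.delta_to_atom_fraction(delta, C)

    @pytest.mark.parametrize("bad", [-1000.1, float("nan"), float("inf")])
    def test_invalid_delta_rejected(self, bad):
        with pytest.raises(InvalidIsotopeValueError):
            isotope.delta_to_atom_fraction(bad, C)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_invalid_atom_fraction_rejected(self, bad):
        with pytest.raises(InvalidIsotopeValueError):
            isotope.atom_fraction_to_delta(bad, C)

    def test_vectorized(self):
        deltas = np.array([-1000.0, 0.0, 904.0])
        afs = isotope.delta_to_atom_fraction(deltas, C)
        assert np.allclose(afs, [0.0, AF_AT_STANDARD, AF_LITTER])


class TestFameCorrection:
    def test_hand_computed_example(self):
        # ((17 * -30) - (-40)) / 16
        assert isotope.correct_fame_delta(-30.0, -40.0, 16) == pytest.approx(-29.375)

    @given(st.floats(min_value=-200, max_value=1000), st.integers(1, 30))
    def test_fixed_point_when_methanol_matches(self, x, n):
        assert isotope.correct_fame_delta(x, x, n) == pytest.approx(x, abs=1e-9)

    @given(
        st.floats(min_value=-100, max_value=1500),
        st.floats(min_value=-60, max_value=-20),
        st.integers(1, 30),
    )
    def test_forward_model_round_trip(self, delta_plfa, delta_meoh, n):
        fame = isotope.fame_forward_delta(delta_plfa, delta_meoh, n)
        back = isotope.correct_fame_delta(fame, delta_meoh, n)
        assert back == pytest.approx(delta_plfa, abs=1e-9)

    def test_invalid_carbon_count(self):
        with pytest.raises(InvalidBiomarkerError):
            isotope.correct_fame_delta(-30.0, -40.0, 0)


class TestExcess13C:
    def test_no_enrichment_is_zero(self):
        ex = isotope.excess_13c_mass(-25.7, -25.7, 123.0, C)
        assert ex.value == 0.0 and not ex.flagged

    def test_pure_litter_against_hand_computation(self):
        ex = isotope.excess_13c_mass(904.0, -25.7, 1000.0, C)
        assert ex.value == pytest.approx(EXCESS_PURE_LITTER_1000NMOL, abs=1e-12)

    @given(
        st.floats(min_value=-100, max_value=1000),
        st.floats(min_value=-100, max_value=1000),
        st.floats(min_value=0, max_value=1e4),
        st.floats(min_value=1e-3, max_value=10.0),
    )
    def test_linear_in_amount(self, dl, dc, amount, k):
        a = isotope.excess_13c_mass(dl, dc, amount, C).value
        b = isotope.excess_13c_mass(dl, dc, k * amount, C).value
        assert b == pytest.approx(k * a, rel=1e-9, abs=1e-12)

    def test_negative_excess_flagged_not_clipped(self):
        ex = isotope.excess_13c_mass(-30.0, -25.7, 100.0, C)
        assert ex.value < 0 and ex.flagged

    @given(st.floats(min_value=-100, max_value=999), st.floats(0.1, 100))
    def test_monotone_in_labeled_delta(self, d, step):
        lo = isotope.excess_13c_mass(d, -25.7, 50.0, C).value
        hi = isotope.excess_13c_mass(d + step, -25.7, 50.0, C).value
        assert hi > lo

    def test_negative_amount_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            isotope.excess_13c_mass(0.0, -25.7, -1.0, C)


class TestMixingModel:
    @pytest.mark.parametrize(
        "sample, reference, expected",
        [
            (904.0, -25.7, 100.0),   # pure litter
            (-25.7, -25.7, 0.0),     # no incorporation
            (439.15, -25.7, 50.0),   # midpoint of the mixing line
        ],
    )
    def test_endpoints_and_midpoint(self, sample, reference, expected):
        frac = isotope.fraction_litter_derived(sample, reference, EM)
        assert frac.value == pytest.approx(expected, abs=1e-9)
        assert not frac.flagged

    def test_out_of_range_flagged(self):
        frac = isotope.fraction_litter_derived(950.0, -25.7, EM)
        assert frac.value > 100 and frac.flagged

    @given(
        st.floats(min_value=-100, max_value=1000),
        st.floats(min_value=-100, max_value=1000),
    )
    def test_antisymmetric_in_sample_reference(self, a, b):
        f1 = isotope.fraction_litter_derived(a, b, EM).value
        f2 = isotope.fraction_litter_derived(b, a, EM).value
        assert f1 == pytest.approx(-f2, abs=1e-9)

    def test_degenerate_endmembers_rejected(self):
        with pytest.raises(DegenerateEndmemberError):
            isotope.MixingEndmembers(10.0, 10.0)

    def test_forward_mix_inverts(self):
        delta = isotope.mix_delta(0.37, EM)
        frac = isotope.fraction_litter_derived(delta, EM.delta_soil, EM)
        assert frac.value == pytest.approx(37.0, abs=1e-9)

    def test_atom_fraction_variant_close_but_distinct(self):
        # the mass-balance-exact variant differs slightly from the
        # delta-linear form away from the endpoints
        delta = isotope.mix_delta(0.5, EM)
        lin = isotope.fraction_litter_derived(delta, EM.delta_soil, EM).value
        af = isotope.fraction_litter_derived_atom_fraction(
            delta, EM.delta_soil, EM, C
        ).value
        assert lin == pytest.approx(50.0, abs=1e-9)
        assert af == pytest.approx(50.0, abs=0.5)
        assert af != pytest.approx(50.0, abs=1e-6)
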