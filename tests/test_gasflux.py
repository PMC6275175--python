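"""Two-point chamber flux estimation against an event-by-event mass balance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plfasip import gasflux, isotope
from plfasip.errors import (
    InvalidChamberError,
    InvalidIntervalError,
    InvalidMeasurementError,
)

C = isotope.DEFAULT_CONSTANTS


def chamber_oracle(
    production,
    source_delta,
    c_init=0.2,
    delta_init=-8.5,
    headspace=300.0,
    sample=15.0,
    soil=50.0,
    hours=4.5,
):
    """Independent mass-balance simulation of one chamber closure.

    Tracks total C and 13C masses (ug) explicitly through the three events:
    t0 sampling (before refill), withdrawal + N2 refill (removes mass
    proportionally, adds none), then linear accumulation of ``production``
    (ug C g^-1 day^-1) at ``source_delta`` until t1.  Returns the
    ChamberObservation the instruments would record, noise-free.
    """
    af = lambda d: isotope.delta_to_atom_fraction(d, C)
    mass = c_init * headspace
    mass13 = af(delta_init) * mass
    c0, d0 = mass / headspace, delta_init  # t0 sample, pre-refill
    keep = (headspace - sample) / headspace
    mass, mass13 = mass * keep, mass13 * keep
    added = production * soil * hours / 24.0
    mass += added
    mass13 += af(source_delta) * added
    c1 = mass / headspace
    d1 = isotope.atom_fraction_to_delta(mass13 / mass, C)
    return gasflux.ChamberObservation(
        c0=c0, c1=c1, t0=0.0, t1=hours,
        headspace_volume=headspace, sample_volume=sample,
        soil_dry_mass=soil, delta0=d0, delta1=d1,
    )


class TestDilution:
    def test_fifteen_ml_from_300(self):
        obs = chamber_oracle(10.0, 400.0, headspace=300.0, sample=15.0)
        assert gasflux.dilution_factor(obs) == pytest.approx(0.95)

    def test_no_withdrawal(self):
        obs = chamber_oracle(10.0, 400.0, sample=0.0)
        assert gasflux.dilution_factor(obs) == pytest.approx(1.0)

    @given(st.floats(min_value=1.0, max_value=100.0), st.floats(0.5, 50.0))
    def test_monotone_in_sample_volume(self, sample, step):
        a = chamber_oracle(10.0, 400.0, headspace=200.0, sample=min(sample, 150.0))
        b = chamber_oracle(10.0, 400.0, headspace=200.0,
                           sample=min(sample + step, 199.0))
        assert gasflux.dilution_factor(b) < gasflux.dilution_factor(a)

    def test_sample_exceeding_headspace_rejected(self):
        with pytest.raises(InvalidChamberError):
            gasflux.ChamberObservation(
                c0=0.2, c1=0.3, t0=0, t1=4.5,
                headspace_volume=100.0, sample_volume=100.0, soil_dry_mass=50.0,
            )


class TestTotalRate:
    @given(st.floats(min_value=0.0, max_value=200.0))
    def test_recovers_constant_production_exactly(self, production):
        obs = chamber_oracle(production, 400.0)
        assert gasflux.co2_rate(obs) == pytest.approx(
            production, rel=1e-9, abs=1e-9
        )

    def test_zero_when_only_dilution_acts(self):
        obs = chamber_oracle(0.0, 400.0)
        assert obs.c1 == pytest.approx(obs.c0 * gasflux.dilution_factor(obs))
        assert gasflux.co2_rate(obs) == pytest.approx(0.0, abs=1e-12)

    def test_halving_interval_doubles_rate(self):
        obs = chamber_oracle(40.0, 400.0)
        half = gasflux.ChamberObservation(
            c0=obs.c0, c1=obs.c1, t0=0.0, t1=obs.t1 / 2,
            headspace_volume=obs.headspace_volume,
            sample_volume=obs.sample_volume, soil_dry_mass=obs.soil_dry_mass,
        )
        assert gasflux.co2_rate(half) == pytest.approx(2 * gasflux.co2_rate(obs))

    @given(st.floats(min_value=5.0, max_value=200.0), st.floats(0.05, 2.0))
    def test_uncorrected_underestimates(self, production, c_init):
        obs = chamber_oracle(production, 400.0, c_init=c_init)
        assert gasflux.co2_rate_uncorrected(obs) < gasflux.co2_rate(obs)

    def test_bad_interval_rejected(self):
        with pytest.raises(InvalidIntervalError):
            gasflux.ChamberObservation(
                c0=0.2, c1=0.3, t0=4.5, t1=4.5,
                headspace_volume=300.0, sample_volume=15.0, soil_dry_mass=50.0,
            )


class TestIsotopeRate:
    @given(st.floats(min_value=1.0, max_value=200.0),
           st.floats(min_value=-25.0, max_value=900.0))
    def test_recovers_production_and_source_delta(self, production, source):
        obs = chamber_oracle(production, source)
        total = gasflux.co2_rate(obs)
        assert total == pytest.approx(production, rel=1e-9)
        assert gasflux.evolved_delta(obs, C) == pytest.approx(source, abs=1e-6)

    def test_uniform_labeling_passthrough(self):
        obs = chamber_oracle(50.0, -8.5, delta_init=-8.5)
        assert obs.delta1 == pytest.approx(-8.5, abs=1e-9)
        assert gasflux.evolved_delta(obs, C) == pytest.approx(-8.5, abs=1e-9)

    @given(st.floats(min_value=1.0, max_value=200.0),
           st.floats(min_value=0.0, max_value=900.0))
    def test_observed_delta1_between_initial_and_source(self, production, source):
        obs = chamber_oracle(production, source, delta_init=-8.5)
        lo, hi = sorted([-8.5, source])
        assert lo - 1e-9 <= obs.delta1 <= hi + 1e-9

    def test_c13_bounded_by_total_times_source_ceiling(self, noisy_dataset):
        # respired CO2 can never be more 13C-enriched than the litter source
        rates = gasflux.rates_from_table(noisy_dataset.gas, C)
        af_ceiling = isotope.delta_to_atom_fraction(
            noisy_dataset.config.endmembers.delta_litter, C
        )
        pos = rates[rates["total_rate"] > 0]
        assert (pos["c13_rate"] <= pos["total_rate"] * af_ceiling + 1e-12).all()

    def test_missing_deltas_rejected(self):
        obs = gasflux.ChamberObservation(
            c0=0.2, c1=0.5, t0=0, t1=4.5,
            headspace_volume=300.0, sample_volume=15.0, soil_dry_mass=50.0,
        )
        with pytest.raises(InvalidMeasurementError):
            gasflux.c13_rate(obs, C)


class TestVectorizedTable:
    def test_matches_scalar_path(self):
        rows = []
        expected = []
        for production, source in [(10.0, 400.0), (90.0, 450.0), (7.0, -25.7)]:
            obs = chamber_oracle(production, source)
            rows.append(
                dict(
                    bottle_id=f"b{production}", co2_t0=obs.c0, co2_t1=obs.c1,
                    delta13C_t0=obs.delta0, delta13C_t1=obs.delta1,
                    t0_h=obs.t0, t1_h=obs.t1, headspace_ml=obs.headspace_volume,
                    sample_ml=obs.sample_volume, soil_dw_g=obs.soil_dry_mass,
                )
            )
            expected.append(
                (gasflux.co2_rate(obs), gasflux.c13_rate(obs, C),
                 gasflux.evolved_delta(obs, C))
            )
        out = gasflux.rates_from_table(pd.DataFrame(rows), C)
        for i, (total, c13, ev) in enumerate(expected):
            assert out.loc[i, "total_rate"] == pytest.approx(total)
            assert out.loc[i, "c13_rate"] == pytest.approx(c13)
            assert out.loc[i, "evolved_delta"] == pytest.approx(ev)


class TestPartitioning:
    def test_reference_equals_evolved_gives_zero(self):
        r = gasflux.litter_derived_respiration(
            -25.7, -25.7, 80.0, isotope.DEFAULT_ENDMEMBERS
        )
        assert r.litter_derived_pct == pytest.approx(0.0)
        assert r.litter_derived_c == pytest.approx(0.0)

    def test_pure_litter_endpoint(self):
        r = gasflux.litter_derived_respiration(
            904.0, -25.7, 80.0, isotope.DEFAULT_ENDMEMBERS
        )
        assert r.litter_derived_pct == pytest.approx(100.0)
        assert r.litter_derived_c == pytest.approx(80.0)

    def test_midpoint(self):
        mid = isotope.mix_delta(0.5)
        r = gasflux.litter_derived_respiration(
            mid, -25.7, 89.1, isotope.DEFAULT_ENDMEMBERS
        )
        assert r.litter_derived_pct == pytest.approx(50.0)
        assert r.litter_derived_c == pytest.approx(44.55)


def test_ppm_conversion_round_number():
    # 400 ppm at 17.5 C, 1 atm: n/V = 1/(22414 * 290.65/273.15) mol/mL
    expected = 400e-6 * 12.011e6 / (gasflux.MOLAR_VOLUME_STP * 290.65 / 273.15)
    assert gasflux.ppm_to_ug_c_per_ml(400.0) == pytest.approx(expected)
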