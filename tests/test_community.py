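"""Biomarker catalog, group aggregation and community summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plfasip import community, isotope
from plfasip.errors import (
    InvalidBiomarkerError,
    InvalidMeasurementError,
    MissingReferenceError,
    UndefinedRatioError,
)

ASSIGNED = {
    "fungi": ["18:2ω6"],
    "gram_negative": ["16:1ω7", "cy17:0", "18:1ω7"],
    "gram_positive": ["a15:0", "a17:0", "i15:0", "i16:0", "i17:0"],
    "actinomycetes": ["10Me16:0", "10Me17:0", "10Me18:0"],
    "microfauna": ["20:4"],
}


class TestCatalog:
    def test_default_has_24_biomarkers(self, catalog):
        assert len(catalog) == 24

    def test_group_assignments_match_convention(self, catalog):
        for group, names in ASSIGNED.items():
            assert sorted(community.members(catalog, group)) == sorted(names)

    def test_unassigned_fill_the_rest(self, catalog):
        n_assigned = sum(len(v) for v in ASSIGNED.values())
        assert len(community.members(catalog, "unassigned")) == 24 - n_assigned

    def test_catalog_n_carbons_agree_with_name_parser(self, catalog):
        for name, row in catalog.iterrows():
            assert community.parse_n_carbons(name) == row["n_carbons"]

    @pytest.mark.parametrize(
        "name, expected",
        [
            ("18:2ω6", 18),
            ("10Me16:0", 17),   # the 10-methyl branch adds a carbon
            ("cy17:0", 17),
            ("a15:0", 15),
            ("i16:0", 16),
            ("20:4", 20),
            ("18:1w7", 18),     # ascii omega accepted
        ],
    )
    def test_carbon_count_parsing(self, name, expected):
        assert community.parse_n_carbons(name) == expected

    def test_unparseable_name_rejected(self):
        with pytest.raises(InvalidBiomarkerError):
            community.parse_n_carbons("phytol")

    def test_unknown_biomarkers_routed_to_unassigned(self, catalog):
        mapped, unknown = community.assign_groups(
            pd.Series(["18:2ω6", "mystery:0"]), catalog
        )
        assert mapped.tolist() == ["fungi", "unassigned"]
        assert unknown == ["mystery:0"]


def toy_measurements():
    return pd.DataFrame(
        {
            "biomarker": ["18:2ω6", "16:1ω7", "cy17:0"],
            "amount": [10.0, 5.0, 5.0],
            "delta": [904.0, -25.7, -25.7],
        }
    )


class TestAggregation:
    def test_hand_summed_group_biomass(self, catalog):
        m = toy_measurements()
        assert community.aggregate_group(m, catalog, "fungi").biomass == 10.0
        assert community.aggregate_group(m, catalog, "gram_negative").biomass == 10.0
        assert community.aggregate_group(m, catalog, community.TOTAL).biomass == 20.0

    def test_empty_group_is_zero(self, catalog):
        assert community.aggregate_group(
            toy_measurements(), catalog, "microfauna"
        ).biomass == 0.0

    def test_partition_conservation(self, catalog, noisy_dataset):
        sample = noisy_dataset.measurements.query(
            "sample_id == sample_id.iloc[0]"
        ).rename(columns={"amount_nmolC_per_g": "amount"})
        total = community.aggregate_group(sample, catalog, community.TOTAL).biomass
        parts = sum(
            community.aggregate_group(sample, catalog, g).biomass
            for g in community.GROUP_LABELS
        )
        assert parts == pytest.approx(total, rel=1e-12)

    def test_excess_additivity_with_shared_delta(self, catalog):
        # per-biomarker excess sums to the excess of the pooled amount when
        # all members share one delta
        m = toy_measurements()
        ctrl = {b: -25.7 for b in m["biomarker"]}
        gn = community.aggregate_group(m, catalog, "gram_negative", ctrl)
        m2 = pd.DataFrame({"biomarker": ["16:1ω7"], "amount": [10.0], "delta": [-25.7]})
        pooled = community.aggregate_group(m2, catalog, "gram_negative", ctrl)
        assert gn.excess_13c == pytest.approx(pooled.excess_13c, abs=1e-15)

    def test_excess_against_isotope_core(self, catalog):
        m = toy_measurements()
        ctrl = {b: -25.7 for b in m["biomarker"]}
        fungi = community.aggregate_group(m, catalog, "fungi", ctrl)
        direct = isotope.excess_13c_mass(904.0, -25.7, 10.0)
        assert fungi.excess_13c == pytest.approx(direct.value)

    def test_missing_control_raises(self, catalog):
        with pytest.raises(MissingReferenceError):
            community.aggregate_group(
                toy_measurements(), catalog, "fungi", control_deltas={}
            )


class TestRatios:
    def test_hand_computed(self):
        r = community.community_ratios(
            {"fungi": 10.0, "gram_negative": 100.0, "gram_positive": 100.0}
        )
        assert r.fungal_bacterial == pytest.approx(0.05)
        assert r.gram_pos_neg == pytest.approx(1.0)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, k):
        base = {"fungi": 10.0, "gram_negative": 80.0, "gram_positive": 120.0,
                "actinomycetes": 30.0}
        scaled = {g: k * v for g, v in base.items()}
        for flag in (False, True):
            a = community.community_ratios(base, include_actinomycetes=flag)
            b = community.community_ratios(scaled, include_actinomycetes=flag)
            assert b.fungal_bacterial == pytest.approx(a.fungal_bacterial)
            assert b.gram_pos_neg == pytest.approx(a.gram_pos_neg)

    def test_actinomycete_inclusion_lowers_fb(self):
        base = {"fungi": 10.0, "gram_negative": 80.0, "gram_positive": 120.0,
                "actinomycetes": 30.0}
        excl = community.community_ratios(base).fungal_bacterial
        incl = community.community_ratios(
            base, include_actinomycetes=True
        ).fungal_bacterial
        assert incl < excl

    def test_all_zero_rejected(self):
        with pytest.raises(UndefinedRatioError):
            community.community_ratios({"fungi": 1.0})

    def test_mean_of_ratios_vs_ratio_of_means(self):
        per_sample = pd.DataFrame(
            {
                "sample_id": ["a"] * 3 + ["b"] * 3,
                "group": ["fungi", "gram_negative", "gram_positive"] * 2,
                "biomass": [10.0, 100.0, 100.0, 30.0, 100.0, 100.0],
            }
        )
        mor = community.mean_community_ratios(per_sample)
        rom = community.mean_community_ratios(per_sample, method="ratio_of_means")
        assert mor.fungal_bacterial == pytest.approx((0.05 + 0.15) / 2)
        assert rom.fungal_bacterial == pytest.approx(20.0 / 200.0)


class TestRelativeAbundance:
    def test_two_biomarkers(self):
        ra = community.relative_abundance(pd.Series({"a": 30.0, "b": 70.0}))
        assert ra["a"] == pytest.approx(30.0)
        assert ra["b"] == pytest.approx(70.0)

    def test_single_biomarker_is_100(self):
        assert community.relative_abundance(
            pd.Series({"x": 5.0})
        )["x"] == pytest.approx(100.0)

    def test_sums_to_100_per_sample(self, noisy_dataset):
        table = community.relative_abundance_table(
            noisy_dataset.measurements.rename(columns={"amount_nmolC_per_g": "amount"})
        )
        sums = table.groupby("sample_id")["rel_abundance_pct"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_order_invariance(self):
        s = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        shuffled = s.loc[["c", "a", "b"]]
        a = community.relative_abundance(s)
        b = community.relative_abundance(shuffled)
        for k in s.index:
            assert a[k] == pytest.approx(b[k])

    def test_all_zero_sample_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            community.relative_abundance(pd.Series({"a": 0.0, "b": 0.0}))


class TestMineralN:
    def test_sum_and_commutativity(self):
        assert community.total_mineral_n(100.0, 50.0) == 150.0
        assert community.total_mineral_n(0.0, 0.0) == 0.0
        assert community.total_mineral_n(3.0, 4.0) == community.total_mineral_n(4.0, 3.0)

    def test_negative_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            community.total_mineral_n(-1.0, 5.0)
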