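import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gojirisk.deterministic_risk import (
    carcinogenic_risk,
    classify,
    compute_deterministic_risk,
    hazard_index,
    hazard_quotient,
    rank_risks,
)
from gojirisk.data_model import default_registry
from gojirisk.errors import DomainError, EmptyDataError

REGISTRY = default_registry()

# Published per-chemical HQ values (plantation / supermarket), used as inputs
# to the aggregation operations.
PLANTATION_HQ = {
    "dichlorvos": 3.60e-5, "omethoate": 6.70e-5, "malathion": 5.03e-7,
    "cypermethrin": 7.25e-6, "fenvalerate": 0.0004,
    "Pb": 0.0008, "Cd": 0.0009, "Cu": 0.0018, "Ni": 0.0004, "Zn": 0.0005,
    "As": 0.0057,
}
SUPERMARKET_HQ = {
    "dichlorvos": 1.51e-5,
    "Pb": 0.0002, "Cd": 0.0003, "Cu": 0.0016, "Ni": 0.0004, "Zn": 0.0004,
    "As": 0.0008,
}


class TestHazardQuotient:
    @pytest.mark.parametrize(
        "expo,adi,expected",
        [(0.0017, 0.3, 0.0057), (0.0729, 40.0, 0.0018), (0.0, 1.0, 0.0)],
        ids=["As-plantation", "Cu-plantation", "zero-exposure"],
    )
    def test_examples(self, expo, adi, expected):
        # expected values carry the rounding of their printed inputs
        assert hazard_quotient(expo, adi) == pytest.approx(expected, rel=0.02)

    def test_nonpositive_adi_rejected(self):
        with pytest.raises(DomainError):
            hazard_quotient(0.1, 0.0)


class TestHazardIndex:
    def test_plantation_partition_from_published_hqs(self, registry):
        res = hazard_index(PLANTATION_HQ, registry)
        assert res.hi_m == pytest.approx(0.0101, rel=0.01)
        assert res.hi_total == pytest.approx(0.0106, rel=0.01)
        assert res.hi_total == res.hi_p + res.hi_m  # exact additivity
        assert res.share_p + res.share_m == pytest.approx(100.0, abs=1e-9)

    def test_single_chemical(self, registry):
        res = hazard_index({"As": 0.004}, registry)
        assert res.hi_total == 0.004
        assert res.share_m == pytest.approx(100.0)

    def test_empty_map_is_error(self, registry):
        with pytest.raises(EmptyDataError):
            hazard_index({}, registry)

    @settings(derandomize=True, max_examples=50)
    @given(
        hqs=st.dictionaries(
            st.sampled_from(["dichlorvos", "fenvalerate", "Pb", "Cu", "As", "Zn"]),
            st.floats(0, 1),
            min_size=1,
        )
    )
    def test_partition_matches_class_filtered_sums(self, hqs):
        res = hazard_index(hqs, REGISTRY)
        pest = sum(v for k, v in hqs.items() if k in ("dichlorvos", "fenvalerate"))
        metal = sum(v for k, v in hqs.items() if k in ("Pb", "Cu", "As", "Zn"))
        assert res.hi_p == pytest.approx(pest, rel=1e-12, abs=1e-300)
        assert res.hi_m == pytest.approx(metal, rel=1e-12, abs=1e-300)


class TestCarcinogenicRisk:
    @pytest.mark.parametrize(
        "expo,expected",
        [(0.00013, 1.95e-7), (1.97e-5, 2.9550e-8), (0.0, 0.0)],
        ids=["plantation", "supermarket", "zero"],
    )
    def test_slope_factor_with_unit_conversion(self, expo, expected):
        assert carcinogenic_risk(expo, 1.5) == pytest.approx(expected, rel=0.01)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(DomainError):
            carcinogenic_risk(0.1, -1.0)


class TestRankings:
    def test_plantation_pesticide_order(self):
        pest = {k: v for k, v in PLANTATION_HQ.items()
                if k in ("dichlorvos", "omethoate", "malathion", "cypermethrin", "fenvalerate")}
        assert rank_risks(pest) == [
            "fenvalerate", "omethoate", "dichlorvos", "cypermethrin", "malathion"
        ]

    def test_supermarket_metal_order(self):
        metals = {k: v for k, v in SUPERMARKET_HQ.items() if k != "dichlorvos"}
        order = rank_risks(metals)
        assert order[0] == "Cu" and order[-1] == "Pb"

    def test_ties_break_lexicographically(self):
        assert rank_risks({"b": 0.5, "a": 0.5, "c": 1.0}) == ["c", "a", "b"]


class TestClassification:
    @pytest.mark.parametrize(
        "value,kind,expected",
        [
            (0.0106, "hi", "acceptable"),
            (1.5, "hi", "concern"),
            (1.99e-7, "cancer", "negligible"),
            (5e-5, "cancer", "intermediate"),
            (2e-4, "cancer", "concern"),
        ],
    )
    def test_thresholds(self, value, kind, expected):
        assert classify(value, kind) == expected


class TestFullChain:
    def test_mean_concentrations_to_risk(self, registry, factors):
        """Deterministic chain on two chemicals against hand arithmetic."""
        res = compute_deterministic_risk({"As": 0.20, "Cu": 8.70}, factors, registry)
        assert res.hq["As"] == pytest.approx(0.005626, rel=1e-3)
        assert res.hq["Cu"] == pytest.approx(0.001836, rel=1e-3)
        assert res.r["As"] == pytest.approx(1.966e-7, rel=1e-3)
        assert res.hi_p == 0.0
        assert res.share_m == pytest.approx(100.0)
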