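import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilmp.characterization import profile_from_percentages
from soilmp.data_model import (
    DEFAULT_BACKGROUND_C0,
    DEFAULT_HAZARD_TABLE,
    Polymer,
    PolymerHazardTable,
    RiskConfig,
    ValidationError,
)
from soilmp.risk import (
    RI_DISCREPANCY_NOTE,
    aggregate_pli,
    build_report,
    classify_h,
    classify_pli,
    classify_ri,
    contamination_factor,
    ecological_risk_index,
    pollution_load_index,
    polymer_hazard_index,
    toxicity_coefficient,
)

# printed seasonal reference rows: C_i, CF_i, PLI, H, T_i
TABLE = {
    "summer": (664.00, 135.51, 11.64, 425.32, 0.64),
    "autumn": (354.00, 72.24, 8.50, 400.00, 1.13),
    "winter": (456.00, 93.06, 9.65, 418.41, 0.92),
    "spring": (540.00, 110.20, 10.50, 420.71, 0.78),
    "one year": (503.50, 102.76, 10.14, 419.80, 0.83),
}


class TestContaminationFactor:
    @pytest.mark.parametrize("c_i, expected", [(664, 135.51), (354, 72.24)])
    def test_seasonal_values(self, c_i, expected):
        assert contamination_factor(c_i, 4.9) == pytest.approx(expected, abs=0.01)

    def test_identity(self):
        assert contamination_factor(4.9, 4.9) == 1.0

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValidationError):
            contamination_factor(100.0, 0.0)


class TestPollutionLoadIndex:
    @pytest.mark.parametrize("cf, expected", [(135.51, 11.64), (1, 1), (102.76, 10.14)])
    def test_values(self, cf, expected):
        assert pollution_load_index(cf) == pytest.approx(expected, abs=0.01)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            pollution_load_index(-1.0)

    def test_aggregate_is_geometric_mean(self):
        assert aggregate_pli([4.0, 9.0]) == pytest.approx(6.0)


class TestHazardIndex:
    def test_annual_vector(self):
        profile = {"PES": 96.03, "PE": 2.83, "PP": 1.14}
        h = polymer_hazard_index(profile, DEFAULT_HAZARD_TABLE)
        assert h == pytest.approx(419.81, abs=0.01)

    @pytest.mark.parametrize(
        "profile, expected", [({"PES": 100.0}, 400.0), ({"PE": 100.0}, 1100.0)]
    )
    def test_pure_polymers(self, profile, expected):
        assert polymer_hazard_index(profile, DEFAULT_HAZARD_TABLE) == expected

    def test_fraction_scale_switch(self):
        h = polymer_hazard_index(
            {"PES": 1.0}, DEFAULT_HAZARD_TABLE, percent_as_fraction=True
        )
        assert h == 400.0

    def test_unscored_polymer_rejected(self):
        table = PolymerHazardTable({Polymer.PES: 4.0})
        with pytest.raises(ValidationError, match="hazard score"):
            polymer_hazard_index({"PES": 50.0, "PE": 50.0}, table)

    def test_permutation_invariant_and_linear(self):
        a = polymer_hazard_index({"PES": 60.0, "PE": 30.0, "PP": 10.0}, DEFAULT_HAZARD_TABLE)
        b = polymer_hazard_index({"PP": 10.0, "PES": 60.0, "PE": 30.0}, DEFAULT_HAZARD_TABLE)
        assert a == b
        # linear in each share
        base = polymer_hazard_index({"PES": 60.0}, DEFAULT_HAZARD_TABLE)
        assert polymer_hazard_index({"PES": 120.0}, DEFAULT_HAZARD_TABLE) == 2 * base


class TestToxicityAndRisk:
    @pytest.mark.parametrize(
        "h, c, expected", [(419.80, 503.5, 0.83), (400.00, 354, 1.13)]
    )
    def test_toxicity(self, h, c, expected):
        assert toxicity_coefficient(h, c) == pytest.approx(expected, abs=0.005)

    def test_zero_h_gives_zero(self):
        assert toxicity_coefficient(0.0, 100.0) == 0.0

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValidationError):
            toxicity_coefficient(400.0, 0.0)

    @pytest.mark.parametrize(
        "t, cf, expected", [(1, 1, 1.0), (0.64, 135.51, 86.73), (0.83, 102.76, 85.29)]
    )
    def test_ri_is_product(self, t, cf, expected):
        assert ecological_risk_index(t, cf) == pytest.approx(expected, abs=0.01)


class TestClassification:
    @pytest.mark.parametrize(
        "pli, label",
        [(8.50, "low"), (10.0, "medium"), (11.64, "medium"), (25, "high"), (30, "extremely high")],
    )
    def test_pli_classes(self, pli, label):
        assert classify_pli(pli) == label

    @pytest.mark.parametrize(
        "h, label", [(419.80, "III"), (5, "I"), (10, "II"), (1000, "IV")]
    )
    def test_h_levels(self, h, label):
        assert classify_h(h) == label

    @pytest.mark.parametrize(
        "ri, label", [(86.73, "I"), (150, "II"), (0, "I"), (1200, "V")]
    )
    def test_ri_levels(self, ri, label):
        assert classify_ri(ri) == label

    @given(st.floats(min_value=0, max_value=1e6))
    @settings(max_examples=200, deadline=None)
    def test_classifiers_total_and_monotone(self, x):
        for classify, order in [
            (classify_pli, ("low", "medium", "high", "extremely high")),
            (classify_h, ("I", "II", "III", "IV")),
            (classify_ri, ("I", "II", "III", "IV", "V")),
        ]:
            a = classify(x)
            b = classify(x * 1.5 + 1)
            assert a in order and b in order
            assert order.index(a) <= order.index(b)


class TestFormulaIdentities:
    @given(
        st.floats(min_value=0.1, max_value=5000),
        st.floats(min_value=0.1, max_value=100),
    )
    @settings(max_examples=100, deadline=None)
    def test_chain_identities(self, c_i, pes_share):
        profile = {"PES": pes_share, "PE": 100 - pes_share}
        cf = contamination_factor(c_i, DEFAULT_BACKGROUND_C0)
        pli = pollution_load_index(cf)
        h = polymer_hazard_index(profile, DEFAULT_HAZARD_TABLE)
        t = toxicity_coefficient(h, c_i)
        ri = ecological_risk_index(t, cf)
        assert pli**2 == pytest.approx(cf, rel=1e-12)
        assert t * c_i == pytest.approx(h, rel=1e-12)
        assert ri * DEFAULT_BACKGROUND_C0 == pytest.approx(h, rel=1e-12)


class TestBuildReport:
    def test_reproduces_reference_table(self, config):
        from soilmp.synthetic import ANNUAL, SEASONS

        concentrations = {
            **{s.value: config.exact_soil_concentration(s) for s in SEASONS},
            "one year": config.exact_soil_concentration(ANNUAL),
        }
        profiles = {
            **{
                s.value: profile_from_percentages(
                    "polymer", config.exact_polymer_percent(s)
                )
                for s in SEASONS
            },
            "one year": profile_from_percentages(
                "polymer", config.exact_polymer_percent(ANNUAL)
            ),
        }
        reports = {r.stratum: r for r in build_report(concentrations, profiles)}
        for stratum, (c_i, cf, pli, h, t) in TABLE.items():
            r = reports[stratum]
            assert r.c_i == pytest.approx(c_i, abs=0.01)
            assert r.cf_i == pytest.approx(cf, abs=0.01)
            assert r.pli == pytest.approx(pli, abs=0.01)
            assert r.h == pytest.approx(h, abs=0.05)
            assert r.t_i == pytest.approx(t, abs=0.01)
            assert r.h_level == "III"
            assert r.ri_level == "I"

    def test_background_equal_to_concentration_gives_unit_indices(self):
        config = RiskConfig(background_c0=500.0)
        reports = build_report(
            {"x": 500.0}, {"x": {"PES": 100.0}}, config
        )
        assert reports[0].cf_i == 1.0
        assert reports[0].pli == 1.0

    def test_missing_profile_errors(self):
        with pytest.raises(ValidationError, match="missing stratum"):
            build_report({"x": 100.0}, {})

    def test_discrepancy_note_mentions_concentration_column(self):
        assert "C_i" in RI_DISCREPANCY_NOTE and "T_i × CF_i" in RI_DISCREPANCY_NOTE
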