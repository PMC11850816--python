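import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilmp.characterization import (
    OVERFLOW_LABEL,
    SIZE_CLASS_LABELS,
    assign_size_class,
    blank_assessment,
    burden_per_gram,
    burden_per_individual,
    composition_profile,
    filter_confirmed,
    profile_from_percentages,
    seasonal_summary,
    soil_concentration,
)
from soilmp.data_model import (
    BlankRecord,
    FaunaSample,
    Matrix,
    Polymer,
    Season,
    SoilSample,
    ValidationError,
)

from .conftest import make_particle


def soil_sample(n_confirmed, n_unconfirmed=0, season=Season.SUMMER, mass=50.0, sid="s"):
    parts = tuple(
        make_particle(season=season, sample_id=sid) for _ in range(n_confirmed)
    ) + tuple(
        make_particle(
            season=season, sample_id=sid, polymer=Polymer.NONE, confirmed=False
        )
        for _ in range(n_unconfirmed)
    )
    return SoilSample(sid, season, mass, parts)


class TestConfirmationFilter:
    def test_two_of_hundred_unconfirmed(self):
        parts = soil_sample(98, 2).particles
        confirmed, rate = filter_confirmed(parts)
        assert len(confirmed) == 98
        assert rate == pytest.approx(98.00)

    def test_all_confirmed_rate_100(self):
        confirmed, rate = filter_confirmed(soil_sample(5).particles)
        assert rate == 100.0

    def test_survey_scale_realization(self):
        # 495/504 is the closest integer realization of the reported 98.22%
        _, rate = filter_confirmed(soil_sample(495, 9).particles)
        assert rate == pytest.approx(98.21, abs=0.005)


class TestBlankAssessment:
    def test_all_zero_blanks_no_correction(self):
        blanks = [BlankRecord(Season.SUMMER, f"b{i}", 0) for i in range(5)]
        decision = blank_assessment(blanks, [soil_sample(25)])
        assert decision.decision == "no_correction"
        assert decision.blank_mean == 0.0

    def test_survey_level_contamination_below_threshold(self):
        # 11 particles over 20 blanks vs samples averaging 25.2 particles
        counts = [1] * 11 + [0] * 9
        blanks = [
            BlankRecord(Season.SUMMER, f"b{i}", c) for i, c in enumerate(counts)
        ]
        samples = [soil_sample(25), soil_sample(25), soil_sample(26), soil_sample(25), soil_sample(25)]
        decision = blank_assessment(blanks, samples)
        assert decision.decision == "no_correction"
        assert decision.fraction == pytest.approx(0.55 / 25.2, rel=1e-9)

    def test_heavy_contamination_flags_correction(self):
        blanks = [BlankRecord(Season.SUMMER, "b", 10)]
        decision = blank_assessment(blanks, [soil_sample(20)])
        assert decision.decision == "correct"
        assert decision.correction_per_sample == 10

    def test_empty_blank_list_errors(self):
        with pytest.raises(ValidationError, match="blank"):
            blank_assessment([], [soil_sample(5)])


class TestConcentrationAndBurden:
    @pytest.mark.parametrize(
        "n, mass, expected", [(25, 50.0, 500.0), (0, 50.0, 0.0), (33, 50.0, 660.0)]
    )
    def test_soil_concentration(self, n, mass, expected):
        assert soil_concentration(soil_sample(n, mass=mass)) == expected

    def test_concentration_counts_only_confirmed(self):
        assert soil_concentration(soil_sample(25, n_unconfirmed=5)) == 500.0

    def test_burden_per_individual(self):
        parts = tuple(
            make_particle(matrix=Matrix.EARTHWORM, sample_id="f") for _ in range(10)
        )
        sample = FaunaSample("f", Season.SUMMER, Matrix.EARTHWORM, 5, 2.0, parts)
        assert burden_per_individual(sample) == 2.0
        assert burden_per_gram(sample) == 5.0

    def test_survey_total_burden_quotient(self):
        # 419 particles from 62 pooled individuals
        parts = tuple(
            make_particle(matrix=Matrix.EARTHWORM, sample_id="f") for _ in range(419)
        )
        sample = FaunaSample("f", Season.SUMMER, Matrix.EARTHWORM, 62, 10.0, parts)
        assert burden_per_individual(sample) == pytest.approx(6.758, abs=0.001)


class TestSeasonalSummary:
    def test_annual_mean_is_mean_of_seasonal_means(self):
        samples = [
            soil_sample(33, season=Season.SUMMER, sid="a"),  # 660
            soil_sample(34, season=Season.SUMMER, sid="a2"),  # 680 -> mean 670
            soil_sample(18, season=Season.AUTUMN, sid="b"),  # 360
            soil_sample(17, season=Season.AUTUMN, sid="b2"),  # 340 -> mean 350
        ]
        out = seasonal_summary(samples, "soil_concentration")
        annual = out[-1]
        assert annual.stratum == "one year"
        assert annual.mean == pytest.approx((670 + 350) / 2)

    def test_identical_values_have_zero_sd(self):
        samples = [soil_sample(25, season=s, sid=str(s)) for s in Season]
        for summary in seasonal_summary(samples, "soil_concentration"):
            assert summary.mean == 500.0
            assert summary.sd == 0.0

    def test_survey_seasonal_means_give_annual_503_5(self):
        counts = {
            Season.SUMMER: 664,
            Season.AUTUMN: 354,
            Season.WINTER: 456,
            Season.SPRING: 540,
        }
        samples = [
            soil_sample(n, season=s, mass=1000.0, sid=s.value)
            for s, n in counts.items()
        ]
        annual = seasonal_summary(samples, "soil_concentration")[-1]
        assert annual.mean == pytest.approx(503.5)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            seasonal_summary([], "soil_concentration")

    def test_unknown_metric_errors(self):
        with pytest.raises(ValidationError, match="metric"):
            seasonal_summary([soil_sample(1)], "banana")


class TestSizeClasses:
    @pytest.mark.parametrize(
        "length, label",
        [
            (500.0, "≤500"),
            (500.5, "501–1000"),
            (750.0, "501–1000"),
            (1000.0, "501–1000"),
            (4467.90, "3501–4500"),
            (152.03, "≤500"),
            (4600.0, OVERFLOW_LABEL),
        ],
    )
    def test_boundaries(self, length, label):
        assert assign_size_class(length) == label

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError):
            assign_size_class(0.0)

    @given(st.floats(min_value=1e-6, max_value=4999.99))
    @settings(max_examples=200, deadline=None)
    def test_total_on_mp_range(self, length):
        assert assign_size_class(length) in SIZE_CLASS_LABELS + (OVERFLOW_LABEL,)

    @given(
        st.floats(min_value=1e-3, max_value=4999.0),
        st.floats(min_value=1e-3, max_value=4999.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone(self, a, b):
        order = SIZE_CLASS_LABELS + (OVERFLOW_LABEL,)
        a, b = sorted((a, b))
        assert order.index(assign_size_class(a)) <= order.index(assign_size_class(b))


class TestCompositionProfile:
    def test_shape_percentages(self):
        parts = [make_particle() for _ in range(96)] + [
            make_particle(shape="fragment", length_um=311.52, width_um=253.89)
            for _ in range(4)
        ]
        profile = composition_profile(parts, "shape")
        assert profile["fiber"] == 96.0
        assert profile["fragment"] == 4.0

    def test_single_particle_100pct(self):
        profile = composition_profile([make_particle()], "color")
        assert profile["blue"] == 100.0
        assert profile["red"] == 0.0  # zero categories present

    def test_sum_is_100(self, dataset):
        for attribute in ("shape", "color", "polymer", "size_class"):
            profile = composition_profile(dataset.particles, attribute)
            assert sum(profile.percentages.values()) == pytest.approx(100.0, abs=0.01)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            composition_profile([], "shape")

    def test_exact_vectors_reproduce_config(self, config):
        profile = profile_from_percentages("polymer", config.exact_polymer_percent(Season.SUMMER))
        assert profile["PES"] == pytest.approx(93.98)
        shape = profile_from_percentages("shape", config.exact_shape_percent())
        assert shape["fiber"] == pytest.approx(96.03)

    def test_bad_percentages_rejected(self):
        with pytest.raises(ValidationError):
            profile_from_percentages("shape", {"fiber": 60.0, "fragment": 30.0})
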