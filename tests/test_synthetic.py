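import dataclasses
import math

import numpy as np
import pytest

from soilmp.data_model import Matrix, Polymer, Season, validate_particle
from soilmp.synthetic import (
    SEASONS,
    GeneratorConfig,
    SizeDistribution,
    default_config,
    draw_particles,
    generate_blanks,
    generate_fauna,
    generate_soil,
    generate_year,
    invert_polymer_split,
)
from soilmp.risk import polymer_hazard_index
from soilmp.data_model import DEFAULT_HAZARD_TABLE

TABLE_H = {
    Season.SUMMER: 425.32,
    Season.AUTUMN: 400.00,
    Season.WINTER: 418.41,
    Season.SPRING: 420.71,
}


class TestCalibration:
    def test_seasonal_soil_means_match_survey(self, config):
        assert config.soil.mean == {
            Season.SUMMER: 664.0,
            Season.AUTUMN: 354.0,
            Season.WINTER: 456.0,
            Season.SPRING: 540.0,
        }

    def test_autumn_polymer_split_inverts_h(self):
        # H = 400 exactly means no polyethylene: 4*97.74 + 4*2.26 = 400
        vec = invert_polymer_split(97.74, 400.00)
        assert vec[Polymer.PE] == 0.0
        assert vec[Polymer.PP] == pytest.approx(2.26)

    @pytest.mark.parametrize("season", SEASONS)
    def test_inverted_seasonal_vectors_reproduce_h(self, config, season):
        vec = config.exact_polymer_percent(season)
        h = polymer_hazard_index(vec, DEFAULT_HAZARD_TABLE)
        assert h == pytest.approx(TABLE_H[season], abs=0.01)

    def test_winter_earthworm_burden_from_annual_mean(self, config):
        # annual mean-of-means is 6.84 items/ind; winter is the unprinted one
        means = config.earthworm.burden_mean
        assert np.mean(list(means.values())) == pytest.approx(6.84)
        assert means[Season.WINTER] == pytest.approx(6.54, abs=1e-9)

    def test_earwig_individual_weight_derived(self, config):
        # annual burden / annual per-gram burden
        assert config.earwig.mean_individual_weight_g == pytest.approx(
            0.0133, abs=2e-4
        )

    def test_probability_vectors_sum_to_one(self, config):
        config.validate()
        assert sum(config.soil.color.values()) == pytest.approx(1.0, abs=1e-9)
        for season in SEASONS:
            for taxon in (config.earthworm, config.earwig):
                assert sum(taxon.polymer[season].values()) == pytest.approx(
                    1.0, abs=1e-9
                )

    def test_blank_rate_gives_expected_annual_total_of_11(self, config):
        n_blanks = 4 * config.blanks.n_per_season
        assert n_blanks * config.blanks.rate == pytest.approx(11.0)

    def test_config_yaml_round_trip(self, config, tmp_path):
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        restored = GeneratorConfig.from_yaml(path)
        assert restored.to_dict() == config.to_dict()


class TestDeterminism:
    def test_identical_seeds_identical_datasets(self):
        a = generate_year(default_config(seed=42))
        b = generate_year(default_config(seed=42))
        assert a == b

    def test_different_seeds_differ(self):
        a = generate_year(default_config(seed=1))
        b = generate_year(default_config(seed=2))
        assert a.particles != b.particles

    def test_generated_data_passes_validation(self, dataset):
        for p in dataset.particles:
            validate_particle(p)


class TestSoilGeneration:
    def test_five_samples_per_season(self, config):
        samples = generate_soil(config, Season.WINTER)
        assert len(samples) == 5
        assert all(s.dry_mass_g == 50.0 for s in samples)

    def test_zero_sd_gives_exact_particle_count(self, config):
        cfg = dataclasses.replace(
            config,
            confirmation_rate=1.0,
            soil=dataclasses.replace(
                config.soil,
                mean={s: 500.0 for s in SEASONS},
                sd={s: 0.0 for s in SEASONS},
            ),
        )
        for sample in generate_soil(cfg, Season.SUMMER):
            # 500 items/kg x 0.05 kg
            assert len(sample.particles) == 25

    def test_invalid_season_rejected(self, config):
        with pytest.raises(ValueError):
            generate_soil(config, "monsoon")

    def test_fiber_fraction_recovered_at_large_n(self, config):
        rng = np.random.default_rng(5)
        n = 10_000
        parts = draw_particles(
            config, Matrix.SOIL, Season.SUMMER, "x", n, rng, n_unconfirmed=0
        )
        frac = sum(p.shape.value == "fiber" for p in parts) / n
        se = math.sqrt(0.9603 * (1 - 0.9603) / n)
        assert abs(frac - 0.9603) <= 3 * se


class TestSizeDistributions:
    @pytest.mark.parametrize(
        "dist_name", ["fiber_length", "fragment_length", "fiber_width", "fragment_width"]
    )
    def test_soil_moment_recovery_within_5pct(self, config, dist_name):
        dist = getattr(config.soil, dist_name)
        rng = np.random.default_rng(11)
        x = dist.sample(20_000, rng)
        assert np.all((x >= dist.min) & (x <= dist.max))
        assert abs(x.mean() - dist.mean) / dist.mean < 0.05
        assert abs(x.std(ddof=1) - dist.sd) / dist.sd < 0.05

    def test_zero_sd_degenerates_to_constant(self):
        dist = SizeDistribution(100.0, 0.0, 50.0, 200.0)
        assert np.all(dist.sample(5, np.random.default_rng(0)) == 100.0)


class TestFaunaGeneration:
    def test_reproducible_and_pool_sizes_in_range(self, config):
        rng1 = np.random.default_rng(3)
        rng2 = np.random.default_rng(3)
        a = generate_fauna(config, Season.SPRING, Matrix.EARWIG, rng1)
        b = generate_fauna(config, Season.SPRING, Matrix.EARWIG, rng2)
        assert a == b
        assert len(a) == 5
        assert all(5 <= s.n_individuals <= 10 for s in a)

    def test_poisson_limit_recovers_spring_earthworm_mean(self, config):
        cfg = dataclasses.replace(
            config,
            earthworm=dataclasses.replace(config.earthworm, dispersion=math.inf),
        )
        rng = np.random.default_rng(17)
        mean = 10.47
        n = 10_000
        burdens = []
        # accumulate individuals across many pooled samples
        while sum(s.n_individuals for s in burdens) < n:
            burdens.extend(generate_fauna(cfg, Season.SPRING, Matrix.EARTHWORM, rng))
        n_ind = sum(s.n_individuals for s in burdens)
        total = sum(sum(p.confirmed for p in s.particles) for s in burdens)
        se = math.sqrt(mean / n_ind)
        assert abs(total / n_ind - mean) <= 3 * se

    def test_invalid_taxon_rejected(self, config):
        with pytest.raises(Exception):
            generate_fauna(config, Season.SPRING, Matrix.SOIL)


class TestBlanks:
    def test_zero_rate_gives_all_zeros(self, config):
        cfg = dataclasses.replace(
            config, blanks=dataclasses.replace(config.blanks, rate=0.0)
        )
        blanks = generate_blanks(cfg, Season.SUMMER)
        assert [b.n_particles for b in blanks] == [0] * 5

    def test_reproducible(self, config):
        a = generate_blanks(config, Season.AUTUMN, np.random.default_rng(9))
        b = generate_blanks(config, Season.AUTUMN, np.random.default_rng(9))
        assert a == b
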