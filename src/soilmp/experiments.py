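"""Simulation experiments over the synthetic cohort.

These are the computations behind the package's verification studies:
exact-vector reproduction of the seasonal risk-index table, parameter
recovery at large particle counts, and the operating characteristics
(power and type-I error) of the seasonal one-way ANOVA at the study's
design size of five samples per season.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
from scipy.stats import f_oneway

from .characterization import ANNUAL, composition_profile, profile_from_percentages
from .data_model import Matrix, RiskConfig, RiskIndexReport, Season
from .risk import build_report
from .stats import compare_seasons
from .synthetic import (
    SEASONS,
    GeneratorConfig,
    default_config,
    draw_particles,
    generate_soil,
    simulate_measured_concentrations,
)

__all__ = [
    "exact_table",
    "anova_power",
    "anova_type1_error",
    "summer_flagged_rate",
    "recover_particle_parameters",
]


def exact_table(
    config: GeneratorConfig | None = None,
    risk_config: RiskConfig | None = None,
) -> dict[str, RiskIndexReport]:
    """The seasonal risk-index table computed from the configured
    concentrations and exact polymer vectors (zero sampling noise)."""
    config = config or default_config()
    strata = [s.value for s in SEASONS] + [ANNUAL]
    concentrations = {label: config.exact_soil_concentration(label) for label in strata}
    profiles = {
        label: profile_from_percentages("polymer", config.exact_polymer_percent(label))
        for label in strata
    }
    return {r.stratum: r for r in build_report(concentrations, profiles, risk_config)}


def anova_power(
    config: GeneratorConfig | None = None,
    n_reps: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Fraction of replicates in which the seasonal ANOVA rejects equality
    of means, at the configured seasonal means/SDs with n samples/season."""
    config = config or default_config()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        groups = [
            simulate_measured_concentrations(config, season, rng)
            for season in SEASONS
        ]
        if f_oneway(*groups).pvalue <= alpha:
            hits += 1
    return hits / n_reps


def anova_type1_error(
    config: GeneratorConfig | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the seasonal ANOVA when all seasonal means are
    equal (set to the annual mean, pooled SD)."""
    config = config or default_config()
    mean = config.exact_soil_concentration(ANNUAL)
    sd = float(np.mean(list(config.soil.sd.values())))
    null = dataclasses.replace(
        config,
        soil=dataclasses.replace(
            config.soil,
            mean={s: mean for s in SEASONS},
            sd={s: sd for s in SEASONS},
        ),
    )
    return anova_power(null, n_reps=n_reps, seed=seed, alpha=alpha)


def summer_flagged_rate(
    config: GeneratorConfig | None = None,
    n_reps: int = 200,
    seed: int = 0,
) -> float:
    """Fraction of replicate years in which the post-hoc comparison flags
    summer as significantly higher than every other season."""
    config = config or default_config()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        samples = []
        for season in SEASONS:
            samples.extend(generate_soil(config, season, rng))
        comparison = compare_seasons(samples, "soil_concentration")
        hits += comparison.highest == "summer"
    return hits / n_reps


def recover_particle_parameters(
    config: GeneratorConfig | None = None,
    n: int = 10_000,
    seed: int = 0,
    season: Season = Season.SUMMER,
) -> dict[str, Mapping[str, float]]:
    """Empirical vs configured composition and size moments at large n.

    Returns, per attribute, the empirical value, the configured target and
    the acceptance radius (3 binomial SEs for shares, 5% for moments).
    """
    config = config or default_config()
    rng = np.random.default_rng(seed)
    particles = draw_particles(
        config, Matrix.SOIL, season, "recovery", n, rng, n_unconfirmed=0
    )
    out: dict[str, dict[str, float]] = {}

    def record(name: str, empirical: float, target: float, radius: float) -> None:
        out[name] = {
            "empirical": empirical,
            "target": target,
            "radius": radius,
            "within": float(abs(empirical - target) <= radius),
        }

    def share_radius(p: float) -> float:
        return 3 * math.sqrt(max(p * (1 - p), 1e-12) / n)

    shape = composition_profile(particles, "shape")
    record(
        "fiber_fraction",
        shape["fiber"] / 100.0,
        config.soil.fiber_frac,
        share_radius(config.soil.fiber_frac),
    )
    color = composition_profile(particles, "color")
    for c, target in config.soil.color.items():
        record(f"color_{c.value}", color[c.value] / 100.0, target, share_radius(target))
    polymer = composition_profile(particles, "polymer")
    for p, target in config.soil.polymer[season].items():
        record(
            f"polymer_{p.value}", polymer[p.value] / 100.0, target, share_radius(target)
        )

    lengths = {"fiber": [], "fragment": []}
    for particle in particles:
        lengths[particle.shape.value].append(particle.length_um)
    for shape_name, dist in (
        ("fiber", config.soil.fiber_length),
        ("fragment", config.soil.fragment_length),
    ):
        x = np.asarray(lengths[shape_name])
        record(f"{shape_name}_length_mean", float(x.mean()), dist.mean, 0.05 * dist.mean)
        record(
            f"{shape_name}_length_sd", float(x.std(ddof=1)), dist.sd, 0.05 * dist.sd
        )
    return out
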