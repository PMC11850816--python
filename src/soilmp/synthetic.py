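"""Seeded generator for synthetic seasonal monitoring data.

Emulates one survey year in a single agricultural plot: five 50-g soil
samples per season, five pooled macroinvertebrate samples per taxon per
season (earthworms pooled 3-5 individuals, earwigs 5-10), and five
procedural blanks per season.  All distributional parameters live in
:class:`GeneratorConfig`; the defaults are calibrated to the survey the
package models (seasonal mean concentrations, shape/color/polymer
composition, fiber and fragment size statistics, per-individual body
burdens, blank contamination totals).

Two facts about the calibration are derived rather than copied:

* The seasonal polyethylene/polypropylene shares are not reported directly;
  they are recovered by inverting the polymer hazard index
  ``H = sum(P_n * S_n)`` (percent scale, scores PES=4, PE=11, PP=4), which
  reduces to ``PE% = (H - 400) / 7`` for a three-polymer mixture.
* The winter earthworm burden mean is recovered from the annual
  mean-of-means (4 * 6.84 - summer - autumn - spring = 6.54 items/ind).

Lengths and widths follow lognormal distributions truncated to the observed
ranges.  For soil the lognormal parameters are solved numerically so that
the *truncated* distribution has the configured mean and SD (matching the
untruncated moments first and truncating afterwards would bias the SD by up
to ~18%).  Fauna length distributions reuse the soil parameters restricted
to the taxon-specific observed ranges, reflecting ingestion from the
ambient soil particle pool.

All randomness flows from ``GeneratorConfig.seed`` through a
``numpy.random.SeedSequence`` spawn tree; identical configs give
byte-identical CSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import yaml
from scipy.optimize import fsolve
from scipy.stats import norm, truncnorm

from .data_model import (
    BlankRecord,
    Color,
    FaunaSample,
    Matrix,
    ParticleRecord,
    Polymer,
    Season,
    Shape,
    SoilSample,
    ValidationError,
)

__all__ = [
    "SizeDistribution",
    "SoilConfig",
    "TaxonConfig",
    "BlankConfig",
    "GeneratorConfig",
    "SyntheticDataset",
    "default_config",
    "invert_polymer_split",
    "generate_soil",
    "simulate_measured_concentrations",
    "generate_fauna",
    "generate_blanks",
    "generate_year",
    "draw_particles",
]

SEASONS = (Season.SUMMER, Season.AUTUMN, Season.WINTER, Season.SPRING)

#: Label of the pooled-year stratum in reports.
ANNUAL = "one year"

_PROB_TOL = 1e-9


def invert_polymer_split(pes_pct: float, h_target: float) -> dict[Polymer, float]:
    """Recover {PES, PE, PP} percentages from a PES share and a target H.

    With hazard scores PES=4, PE=11, PP=4 and percentages summing to 100,
    H = 400 + 7*PE%, so PE% = (H - 400)/7; PP% takes the remainder.
    Negative shares produced by rounding are clamped to zero.
    """
    pe = max(0.0, (h_target - 400.0) / 7.0)
    pp = max(0.0, 100.0 - pes_pct - pe)
    return {Polymer.PES: pes_pct, Polymer.PE: pe, Polymer.PP: pp}


@dataclass(frozen=True)
class SizeDistribution:
    """Truncated lognormal for particle lengths or widths, in µm.

    ``mean``/``sd`` are the targeted moments; ``min``/``max`` the truncation
    range.  If ``mu``/``sigma`` are given they are used directly (the
    moments are then descriptive only); otherwise they are solved so the
    truncated distribution attains ``mean``/``sd``, falling back to plain
    untruncated moment matching if no solution exists inside the range.
    """

    mean: float
    sd: float
    min: float
    max: float
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd: must be non-negative")
        if not self.min < self.max:
            raise ValidationError("min/max: truncation range must satisfy min < max")

    def params(self) -> tuple[float, float]:
        """Lognormal (mu, sigma) actually used for sampling."""
        if self.mu is not None and self.sigma is not None:
            return self.mu, self.sigma
        return _solve_truncated_lognormal(self.mean, self.sd, self.min, self.max)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        mu, sigma = self.params()
        lo = norm.cdf((math.log(self.min) - mu) / sigma)
        hi = norm.cdf((math.log(self.max) - mu) / sigma)
        u = rng.uniform(lo, hi, size=n)
        return np.exp(mu + sigma * norm.ppf(u))

    def class_probabilities(self, edges: np.ndarray) -> np.ndarray:
        """Exact probabilities of falling in (edges[i], edges[i+1]]."""
        mu, sigma = self.params()
        lo = norm.cdf((math.log(self.min) - mu) / sigma)
        hi = norm.cdf((math.log(self.max) - mu) / sigma)
        with np.errstate(divide="ignore"):
            z = (np.log(np.clip(edges, 1e-300, None)) - mu) / sigma
        cdf = np.clip((norm.cdf(z) - lo) / (hi - lo), 0.0, 1.0)
        return np.diff(cdf)


def _truncated_lognormal_moments(
    mu: float, sigma: float, a: float, b: float
) -> tuple[float, float]:
    al = (math.log(a) - mu) / sigma
    be = (math.log(b) - mu) / sigma
    z = norm.cdf(be) - norm.cdf(al)
    m1 = math.exp(mu + sigma**2 / 2) * (norm.cdf(be - sigma) - norm.cdf(al - sigma)) / z
    m2 = (
        math.exp(2 * mu + 2 * sigma**2)
        * (norm.cdf(be - 2 * sigma) - norm.cdf(al - 2 * sigma))
        / z
    )
    var = max(m2 - m1 * m1, 0.0)
    return m1, math.sqrt(var)


def _naive_lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - s2 / 2, math.sqrt(s2)


@lru_cache(maxsize=None)
def _solve_truncated_lognormal(
    mean: float, sd: float, a: float, b: float
) -> tuple[float, float]:
    mu0, s0 = _naive_lognormal_params(mean, sd)

    def residual(p: np.ndarray) -> list[float]:
        mu, sigma = float(p[0]), abs(float(p[1]))
        # keep the solver inside a numerically representable region
        if not (-50 < mu < 50) or not (1e-8 < sigma < 10):
            return [1e12, 1e12]
        try:
            m, s = _truncated_lognormal_moments(mu, sigma, a, b)
        except (OverflowError, ZeroDivisionError):
            return [1e12, 1e12]
        return [m - mean, s - sd]

    sol, _, ier, _ = fsolve(residual, [mu0, s0], full_output=True)
    if ier == 1:
        m, s = _truncated_lognormal_moments(sol[0], abs(sol[1]), a, b)
        if abs(m - mean) < 1e-6 * mean and abs(s - sd) < 1e-6 * max(sd, 1.0):
            return float(sol[0]), float(abs(sol[1]))
    # infeasible targets (e.g. mean near a range edge): accept truncation bias
    return mu0, s0


def _check_prob(vector: Mapping, name: str) -> None:
    total = sum(vector.values())
    if abs(total - 1.0) > _PROB_TOL:
        raise ValidationError(f"{name}: probabilities sum to {total!r}, not 1")
    if any(v < 0 for v in vector.values()):
        raise ValidationError(f"{name}: negative probability")


@dataclass(frozen=True)
class SoilConfig:
    mean: dict[Season, float]  # items/kg dw
    sd: dict[Season, float]
    conc_min: float = 280.0  # truncation of per-sample target concentration
    conc_max: float = 760.0
    n_samples: int = 5
    dry_mass_g: float = 50.0
    fiber_frac: float = 0.9603
    color: dict[Color, float] = field(default_factory=dict)
    polymer: dict[Season, dict[Polymer, float]] = field(default_factory=dict)
    polymer_annual: dict[Polymer, float] = field(default_factory=dict)
    fiber_length: SizeDistribution = field(
        default_factory=lambda: SizeDistribution(1321.91, 966.68, 152.03, 4467.90)
    )
    fragment_length: SizeDistribution = field(
        default_factory=lambda: SizeDistribution(311.52, 168.76, 134.13, 1041.84)
    )
    fiber_width: SizeDistribution = field(
        default_factory=lambda: SizeDistribution(19.89, 8.29, 9.84, 56.54)
    )
    fragment_width: SizeDistribution = field(
        default_factory=lambda: SizeDistribution(253.89, 116.79, 110.70, 603.13)
    )

    def validate(self) -> None:
        if any(s < 0 for s in self.sd.values()):
            raise ValidationError("soil.sd: negative SD")
        if not self.conc_min < self.conc_max:
            raise ValidationError("soil concentration truncation: min must be < max")
        _check_prob(self.color, "soil.color")
        _check_prob(
            {Shape.FIBER: self.fiber_frac, Shape.FRAGMENT: 1 - self.fiber_frac},
            "soil.shape",
        )
        for season, vec in self.polymer.items():
            _check_prob(vec, f"soil.polymer[{season}]")
        _check_prob(self.polymer_annual, "soil.polymer_annual")


@dataclass(frozen=True)
class TaxonConfig:
    taxon: Matrix
    burden_mean: dict[Season, float]  # confirmed items per individual
    dispersion: float = 5.0  # negative binomial k; inf -> Poisson
    n_individuals_range: tuple[int, int] = (3, 5)
    mean_individual_weight_g: float = 0.1
    weight_sigma: float = 0.1  # lognormal noise (mean-preserving) on pooled weight
    fiber_frac: float = 0.95
    color: dict[Color, float] = field(default_factory=dict)
    polymer: dict[Season, dict[Polymer, float]] = field(default_factory=dict)
    fiber_length: SizeDistribution | None = None
    fragment_length: SizeDistribution | None = None
    fiber_width: SizeDistribution | None = None
    fragment_width: SizeDistribution | None = None

    def validate(self) -> None:
        if any(m < 0 for m in self.burden_mean.values()):
            raise ValidationError("burden_mean: negative mean burden")
        if not self.dispersion > 0:
            raise ValidationError("dispersion: must be positive (inf for Poisson)")
        lo, hi = self.n_individuals_range
        if not (1 <= lo <= hi):
            raise ValidationError("n_individuals_range: need 1 <= lo <= hi")
        if not self.mean_individual_weight_g > 0:
            raise ValidationError("mean_individual_weight_g: must be positive")
        _check_prob(self.color, f"{self.taxon}.color")
        for season, vec in self.polymer.items():
            _check_prob(vec, f"{self.taxon}.polymer[{season}]")


@dataclass(frozen=True)
class BlankConfig:
    n_per_season: int = 5
    rate: float = 11.0 / 20.0  # Poisson mean per blank; 20 blanks/yr -> 11 expected

    def validate(self) -> None:
        if self.rate < 0:
            raise ValidationError("blank rate: must be non-negative")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    confirmation_rate: float = 0.9822  # FTIR-credible fraction of particles
    soil: SoilConfig = None  # type: ignore[assignment]
    earthworm: TaxonConfig = None  # type: ignore[assignment]
    earwig: TaxonConfig = None  # type: ignore[assignment]
    blanks: BlankConfig = field(default_factory=BlankConfig)

    def validate(self) -> None:
        if not 0 < self.confirmation_rate <= 1:
            raise ValidationError("confirmation_rate: must be in (0, 1]")
        self.soil.validate()
        self.earthworm.validate()
        self.earwig.validate()
        self.blanks.validate()

    def taxon_config(self, taxon: Matrix) -> TaxonConfig:
        if taxon is Matrix.EARTHWORM:
            return self.earthworm
        if taxon is Matrix.EARWIG:
            return self.earwig
        raise ValidationError(f"taxon: {taxon} is not a fauna taxon")

    # -- exact-vector accessors (percent scale) ------------------------------

    def exact_soil_concentration(self, stratum: Season | str) -> float:
        """Configured mean concentration; the pooled year is the unweighted
        mean of the four seasonal means."""
        if stratum == ANNUAL:
            return float(np.mean([self.soil.mean[s] for s in SEASONS]))
        return self.soil.mean[Season(stratum)]

    def exact_polymer_percent(self, stratum: Season | str) -> dict[Polymer, float]:
        if stratum == ANNUAL:
            vec = self.soil.polymer_annual
        else:
            vec = self.soil.polymer[Season(stratum)]
        return {p: 100.0 * f for p, f in vec.items()}

    def exact_shape_percent(self) -> dict[Shape, float]:
        return {
            Shape.FIBER: 100.0 * self.soil.fiber_frac,
            Shape.FRAGMENT: 100.0 * (1 - self.soil.fiber_frac),
        }

    def exact_color_percent(self) -> dict[Color, float]:
        return {c: 100.0 * f for c, f in self.soil.color.items()}

    # -- round-tripping -------------------------------------------------------

    def to_dict(self) -> dict:
        def size(d: SizeDistribution | None):
            if d is None:
                return None
            return {"mean": d.mean, "sd": d.sd, "min": d.min, "max": d.max,
                    "mu": d.mu, "sigma": d.sigma}

        def taxon(t: TaxonConfig) -> dict:
            return {
                "taxon": t.taxon.value,
                "burden_mean": {s.value: v for s, v in t.burden_mean.items()},
                "dispersion": t.dispersion,
                "n_individuals_range": list(t.n_individuals_range),
                "mean_individual_weight_g": t.mean_individual_weight_g,
                "weight_sigma": t.weight_sigma,
                "fiber_frac": t.fiber_frac,
                "color": {c.value: v for c, v in t.color.items()},
                "polymer": {
                    s.value: {p.value: v for p, v in vec.items()}
                    for s, vec in t.polymer.items()
                },
                "fiber_length": size(t.fiber_length),
                "fragment_length": size(t.fragment_length),
                "fiber_width": size(t.fiber_width),
                "fragment_width": size(t.fragment_width),
            }

        return {
            "seed": self.seed,
            "confirmation_rate": self.confirmation_rate,
            "soil": {
                "mean": {s.value: v for s, v in self.soil.mean.items()},
                "sd": {s.value: v for s, v in self.soil.sd.items()},
                "conc_min": self.soil.conc_min,
                "conc_max": self.soil.conc_max,
                "n_samples": self.soil.n_samples,
                "dry_mass_g": self.soil.dry_mass_g,
                "fiber_frac": self.soil.fiber_frac,
                "color": {c.value: v for c, v in self.soil.color.items()},
                "polymer": {
                    s.value: {p.value: v for p, v in vec.items()}
                    for s, vec in self.soil.polymer.items()
                },
                "polymer_annual": {
                    p.value: v for p, v in self.soil.polymer_annual.items()
                },
                "fiber_length": size(self.soil.fiber_length),
                "fragment_length": size(self.soil.fragment_length),
                "fiber_width": size(self.soil.fiber_width),
                "fragment_width": size(self.soil.fragment_width),
            },
            "earthworm": taxon(self.earthworm),
            "earwig": taxon(self.earwig),
            "blanks": {"n_per_season": self.blanks.n_per_season,
                       "rate": self.blanks.rate},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        def size(v):
            return None if v is None else SizeDistribution(**v)

        def taxon(v: dict) -> TaxonConfig:
            return TaxonConfig(
                taxon=Matrix(v["taxon"]),
                burden_mean={Season(s): x for s, x in v["burden_mean"].items()},
                dispersion=float(v["dispersion"]),
                n_individuals_range=tuple(v["n_individuals_range"]),
                mean_individual_weight_g=v["mean_individual_weight_g"],
                weight_sigma=v["weight_sigma"],
                fiber_frac=v["fiber_frac"],
                color={Color(c): x for c, x in v["color"].items()},
                polymer={
                    Season(s): {Polymer(p): x for p, x in vec.items()}
                    for s, vec in v["polymer"].items()
                },
                fiber_length=size(v["fiber_length"]),
                fragment_length=size(v["fragment_length"]),
                fiber_width=size(v["fiber_width"]),
                fragment_width=size(v["fragment_width"]),
            )

        s = d["soil"]
        soil = SoilConfig(
            mean={Season(k): v for k, v in s["mean"].items()},
            sd={Season(k): v for k, v in s["sd"].items()},
            conc_min=s["conc_min"],
            conc_max=s["conc_max"],
            n_samples=s["n_samples"],
            dry_mass_g=s["dry_mass_g"],
            fiber_frac=s["fiber_frac"],
            color={Color(c): v for c, v in s["color"].items()},
            polymer={
                Season(k): {Polymer(p): v for p, v in vec.items()}
                for k, vec in s["polymer"].items()
            },
            polymer_annual={Polymer(p): v for p, v in s["polymer_annual"].items()},
            fiber_length=size(s["fiber_length"]),
            fragment_length=size(s["fragment_length"]),
            fiber_width=size(s["fiber_width"]),
            fragment_width=size(s["fragment_width"]),
        )
        return cls(
            seed=int(d["seed"]),
            confirmation_rate=float(d["confirmation_rate"]),
            soil=soil,
            earthworm=taxon(d["earthworm"]),
            earwig=taxon(d["earwig"]),
            blanks=BlankConfig(**d["blanks"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: Table of seasonal polymer-hazard-index values used to invert the
#: unreported PE/PP shares (percent-scale H with scores PES=4, PE=11, PP=4).
_SEASONAL_H = {
    Season.SUMMER: 425.32,
    Season.AUTUMN: 400.00,
    Season.WINTER: 418.41,
    Season.SPRING: 420.71,
}

_SEASONAL_PES_PCT = {
    Season.SUMMER: 93.98,
    Season.AUTUMN: 97.74,
    Season.WINTER: 96.49,
    Season.SPRING: 97.04,
}


def _fauna_polymer(
    pes_pct: dict[Season, float],
    absent: dict[Season, tuple[Polymer, ...]],
) -> dict[Season, dict[Polymer, float]]:
    """Seasonal fauna polymer fractions: printed PES share; the unreported
    remainder split equally over PE/PP except polymers recorded absent."""
    out: dict[Season, dict[Polymer, float]] = {}
    for season, pes in pes_pct.items():
        rest = (100.0 - pes) / 100.0
        gone = absent.get(season, ())
        present = [p for p in (Polymer.PE, Polymer.PP) if p not in gone]
        vec = {Polymer.PES: pes / 100.0, Polymer.PE: 0.0, Polymer.PP: 0.0}
        for p in present:
            vec[p] = rest / len(present) if present else 0.0
        if not present and rest > 1e-12:
            raise ValidationError(f"fauna polymer [{season}]: remainder unassignable")
        out[season] = vec
    return out


def default_config(seed: int = 0) -> GeneratorConfig:
    """The calibrated study conditions: one year, one citrus-orchard plot."""
    soil_polymer = {
        s: {p: v / 100.0 for p, v in
            invert_polymer_split(_SEASONAL_PES_PCT[s], _SEASONAL_H[s]).items()}
        for s in SEASONS
    }
    soil = SoilConfig(
        mean={
            Season.SUMMER: 664.0,
            Season.AUTUMN: 354.0,
            Season.WINTER: 456.0,
            Season.SPRING: 540.0,
        },
        # winter/spring SDs are not reported; default to the mean of the two
        # reported seasonal SDs.
        sd={
            Season.SUMMER: 90.20,
            Season.AUTUMN: 70.92,
            Season.WINTER: (90.20 + 70.92) / 2,
            Season.SPRING: (90.20 + 70.92) / 2,
        },
        color={
            Color.BLUE: 0.6679,
            Color.RED: 0.1850,
            Color.BLACK: 0.1173,
            Color.WHITE: 0.0020,
            # green/yellow shares are unreported; the remainder is split evenly
            Color.GREEN: 0.0139,
            Color.YELLOW: 0.0139,
        },
        polymer=soil_polymer,
        polymer_annual={Polymer.PES: 0.9603, Polymer.PE: 0.0283, Polymer.PP: 0.0114},
    )

    soil_fib_mu, soil_fib_sigma = soil.fiber_length.params()
    soil_frag_mu, soil_frag_sigma = soil.fragment_length.params()

    def fauna_length(dist: SizeDistribution, lo: float, hi: float,
                     mu: float, sigma: float) -> SizeDistribution:
        # ambient soil length distribution restricted to the taxon's
        # observed range
        return SizeDistribution(dist.mean, dist.sd, lo, hi, mu=mu, sigma=sigma)

    worm_spring = 10.47
    worm_autumn = 5.28
    worm_summer = 5.07
    # winter mean recovered from the annual mean-of-means 6.84 items/ind
    worm_winter = 4 * 6.84 - (worm_spring + worm_autumn + worm_summer)

    earthworm = TaxonConfig(
        taxon=Matrix.EARTHWORM,
        burden_mean={
            Season.SUMMER: worm_summer,
            Season.AUTUMN: worm_autumn,
            Season.WINTER: worm_winter,
            Season.SPRING: worm_spring,
        },
        n_individuals_range=(3, 5),
        # annual burden / annual per-gram burden
        mean_individual_weight_g=6.84 / 37.29,
        fiber_frac=0.9430,
        color={
            Color.BLUE: 0.7684,
            Color.RED: 0.1601,
            Color.BLACK: 0.0418,
            Color.GREEN: 0.0194,
            Color.YELLOW: 0.0094,
            Color.WHITE: 0.0009,  # unlisted remainder
        },
        polymer=_fauna_polymer(
            {
                Season.SUMMER: 98.17,
                Season.AUTUMN: 96.29,
                Season.WINTER: 97.25,
                Season.SPRING: 87.24,
            },
            absent={
                Season.SUMMER: (Polymer.PP,),
                Season.WINTER: (Polymer.PP,),
            },
        ),
        fiber_length=fauna_length(
            soil.fiber_length, 107.31, 4257.73, soil_fib_mu, soil_fib_sigma
        ),
        fragment_length=fauna_length(
            soil.fragment_length, 102.78, 844.20, soil_frag_mu, soil_frag_sigma
        ),
        fiber_width=SizeDistribution(20.11, 7.54, 8.74, 46.99),
        fragment_width=SizeDistribution(145.53, 87.87, 54.04, 484.71),
    )

    earwig = TaxonConfig(
        taxon=Matrix.EARWIG,
        burden_mean={
            Season.SUMMER: 3.18,
            Season.AUTUMN: 2.04,
            Season.WINTER: 1.90,
            Season.SPRING: 1.10,
        },
        n_individuals_range=(5, 10),
        mean_individual_weight_g=2.06 / 155.07,
        fiber_frac=0.95,
        color={
            Color.BLUE: 0.6559,
            Color.RED: 0.2291,
            Color.BLACK: 0.0703,
            Color.YELLOW: 0.0233,
            Color.GREEN: 0.0214,
            Color.WHITE: 0.0,
        },
        polymer=_fauna_polymer(
            {
                Season.SUMMER: 90.23,
                Season.AUTUMN: 100.0,
                Season.WINTER: 96.48,
                Season.SPRING: 97.58,
            },
            absent={
                Season.AUTUMN: (Polymer.PE, Polymer.PP),
                Season.SPRING: (Polymer.PP,),
            },
        ),
        fiber_length=fauna_length(
            soil.fiber_length, 108.56, 4260.53, soil_fib_mu, soil_fib_sigma
        ),
        fragment_length=fauna_length(
            soil.fragment_length, 98.40, 314.77, soil_frag_mu, soil_frag_sigma
        ),
        fiber_width=SizeDistribution(19.02, 8.17, 7.77, 51.05),
        fragment_width=SizeDistribution(133.44, 59.32, 64.59, 244.50),
    )

    config = GeneratorConfig(
        seed=seed,
        soil=soil,
        earthworm=earthworm,
        earwig=earwig,
    )
    config.validate()
    return config


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _draw_categorical(vector: Mapping, n: int, rng: np.random.Generator) -> list:
    cats = list(vector.keys())
    probs = np.asarray([vector[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(cats), size=n, p=probs)
    return [cats[i] for i in idx]


def draw_particles(
    config: GeneratorConfig,
    matrix: Matrix,
    season: Season,
    sample_id: str,
    n_confirmed: int,
    rng: np.random.Generator,
    n_unconfirmed: int | None = None,
) -> list[ParticleRecord]:
    """Draw ``n_confirmed`` polymer-confirmed particles (plus unconfirmed
    cellulose-like extras) with attributes from the config's categorical
    vectors and size distributions."""
    if matrix is Matrix.SOIL:
        fiber_frac = config.soil.fiber_frac
        color_vec = config.soil.color
        polymer_vec = config.soil.polymer[season]
        dists = {
            (Shape.FIBER, "length"): config.soil.fiber_length,
            (Shape.FRAGMENT, "length"): config.soil.fragment_length,
            (Shape.FIBER, "width"): config.soil.fiber_width,
            (Shape.FRAGMENT, "width"): config.soil.fragment_width,
        }
    else:
        t = config.taxon_config(matrix)
        fiber_frac = t.fiber_frac
        color_vec = t.color
        polymer_vec = t.polymer[season]
        dists = {
            (Shape.FIBER, "length"): t.fiber_length,
            (Shape.FRAGMENT, "length"): t.fragment_length,
            (Shape.FIBER, "width"): t.fiber_width,
            (Shape.FRAGMENT, "width"): t.fragment_width,
        }

    if n_unconfirmed is None:
        r = config.confirmation_rate
        n_unconfirmed = int(rng.poisson(n_confirmed * (1 - r) / r)) if r < 1 else 0

    n = n_confirmed + n_unconfirmed
    shapes = [
        Shape.FIBER if u < fiber_frac else Shape.FRAGMENT
        for u in rng.uniform(size=n)
    ]
    colors = _draw_categorical(color_vec, n, rng)
    polymers = _draw_categorical(polymer_vec, n_confirmed, rng)
    polymers += [Polymer.NONE] * n_unconfirmed

    lengths = np.empty(n)
    widths = np.empty(n)
    for shape in (Shape.FIBER, Shape.FRAGMENT):
        idx = [i for i, s in enumerate(shapes) if s is shape]
        if not idx:
            continue
        lengths[idx] = dists[(shape, "length")].sample(len(idx), rng)
        widths[idx] = dists[(shape, "width")].sample(len(idx), rng)

    records = []
    for i in range(n):
        shape = shapes[i]
        length = float(lengths[i])
        width = float(widths[i])
        if shape is Shape.FIBER and width >= length:
            width = 0.5 * length  # degenerate short-fiber guard
        records.append(
            ParticleRecord(
                matrix=matrix,
                season=season,
                sample_id=sample_id,
                shape=shape,
                color=colors[i],
                length_um=length,
                width_um=width,
                polymer=polymers[i],
                confirmed=polymers[i] is not Polymer.NONE,
            )
        )
    return records


def simulate_measured_concentrations(
    config: GeneratorConfig,
    season: Season,
    rng: np.random.Generator,
    n_samples: int | None = None,
) -> np.ndarray:
    """Measured per-sample soil concentrations (items/kg) for one season.

    A truncated-normal target concentration is discretised to a whole
    confirmed-particle count at the analyzed mass and converted back; this
    is the quantity the concentration metric recovers from a sample.
    """
    season = Season(season)
    soil = config.soil
    mean, sd = soil.mean[season], soil.sd[season]
    n = soil.n_samples if n_samples is None else n_samples
    if sd == 0:
        targets = np.full(n, mean)
    else:
        a = (soil.conc_min - mean) / sd
        b = (soil.conc_max - mean) / sd
        targets = truncnorm.ppf(rng.uniform(size=n), a, b, loc=mean, scale=sd)
    counts = np.round(targets * soil.dry_mass_g / 1000.0)
    return counts * 1000.0 / soil.dry_mass_g


def generate_soil(
    config: GeneratorConfig,
    season: Season,
    rng: np.random.Generator | None = None,
) -> list[SoilSample]:
    """Five soil samples for one season.

    The per-sample target concentration is a truncated normal draw
    (configured mean/SD, range [conc_min, conc_max] items/kg); the confirmed
    particle count is ``round(concentration * dry_mass_g / 1000)``.
    """
    season = Season(season)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    soil = config.soil
    samples = []
    concentrations = simulate_measured_concentrations(config, season, rng)
    for i, conc in enumerate(concentrations):
        n_confirmed = int(round(conc * soil.dry_mass_g / 1000.0))
        sample_id = f"soil-{season.value}-{i + 1}"
        particles = draw_particles(
            config, Matrix.SOIL, season, sample_id, n_confirmed, rng
        )
        samples.append(
            SoilSample(
                sample_id=sample_id,
                season=season,
                dry_mass_g=soil.dry_mass_g,
                particles=tuple(particles),
            )
        )
    return samples


def generate_fauna(
    config: GeneratorConfig,
    season: Season,
    taxon: Matrix,
    rng: np.random.Generator | None = None,
) -> list[FaunaSample]:
    """Five pooled fauna samples for one season and taxon.

    Per-individual confirmed burden is negative binomial with the seasonal
    mean and config dispersion (``inf`` gives the Poisson limit); pooled wet
    weight is n_individuals x mean individual weight x mean-preserving
    lognormal noise.
    """
    season = Season(season)
    t = config.taxon_config(Matrix(taxon))
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mean = t.burden_mean[season]
    lo, hi = t.n_individuals_range
    samples = []
    for i in range(5):
        n_ind = int(rng.integers(lo, hi + 1))
        if math.isinf(t.dispersion):
            burdens = rng.poisson(mean, size=n_ind)
        else:
            k = t.dispersion
            burdens = rng.negative_binomial(k, k / (k + mean), size=n_ind)
        n_confirmed = int(burdens.sum())
        weight = (
            n_ind
            * t.mean_individual_weight_g
            * float(np.exp(rng.normal(-t.weight_sigma**2 / 2, t.weight_sigma)))
        )
        sample_id = f"{t.taxon.value}-{season.value}-{i + 1}"
        particles = draw_particles(
            config, t.taxon, season, sample_id, n_confirmed, rng
        )
        samples.append(
            FaunaSample(
                sample_id=sample_id,
                season=season,
                taxon=t.taxon,
                n_individuals=n_ind,
                wet_weight_g=weight,
                particles=tuple(particles),
            )
        )
    return samples


def generate_blanks(
    config: GeneratorConfig,
    season: Season,
    rng: np.random.Generator | None = None,
) -> list[BlankRecord]:
    """Procedural blanks: Poisson counts at the configured rate per blank."""
    season = Season(season)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return [
        BlankRecord(
            season=season,
            blank_id=f"blank-{season.value}-{i + 1}",
            n_particles=int(rng.poisson(config.blanks.rate)),
        )
        for i in range(config.blanks.n_per_season)
    ]


@dataclass(frozen=True)
class SyntheticDataset:
    soil: tuple[SoilSample, ...]
    fauna: tuple[FaunaSample, ...]
    blanks: tuple[BlankRecord, ...]

    @property
    def particles(self) -> tuple[ParticleRecord, ...]:
        out: list[ParticleRecord] = []
        for s in self.soil:
            out.extend(s.particles)
        for f in self.fauna:
            out.extend(f.particles)
        return tuple(out)


def generate_year(config: GeneratorConfig) -> SyntheticDataset:
    """One full survey year; every stream gets its own child seed so the
    dataset is a pure function of ``config``."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    streams = iter(ss.spawn(4 * 4))  # 4 seasons x (soil, worm, earwig, blanks)
    soil: list[SoilSample] = []
    fauna: list[FaunaSample] = []
    blanks: list[BlankRecord] = []
    for season in SEASONS:
        soil.extend(generate_soil(config, season, np.random.default_rng(next(streams))))
        fauna.extend(
            generate_fauna(
                config, season, Matrix.EARTHWORM, np.random.default_rng(next(streams))
            )
        )
        fauna.extend(
            generate_fauna(
                config, season, Matrix.EARWIG, np.random.default_rng(next(streams))
            )
        )
        blanks.extend(
            generate_blanks(config, season, np.random.default_rng(next(streams)))
        )
    return SyntheticDataset(tuple(soil), tuple(fauna), tuple(blanks))
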