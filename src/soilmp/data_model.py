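"""Domain types, validation and CSV dialects for microplastic survey data.

One detected particle is a :class:`ParticleRecord`; field samples group
particles together with the normalising denominator (dry soil mass, or
individual count + pooled wet weight for fauna).  Category sets are closed:
the survey design observed exactly two shapes, six colors and three polymer
types, and downstream percentage arithmetic relies on the sets being total,
so unknown tokens are errors rather than an "other" bucket.

Units are fixed here and never converted downstream of this module's types:
lengths and widths in µm, masses in g.  Concentrations (items/kg dry weight
for soil, items/g wet weight for fauna) are computed in
:mod:`soilmp.characterization`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Matrix",
    "Season",
    "Shape",
    "Color",
    "Polymer",
    "SizeClass",
    "ParticleRecord",
    "SoilSample",
    "FaunaSample",
    "BlankRecord",
    "PolymerHazardTable",
    "RiskConfig",
    "RiskIndexReport",
    "ValidationError",
    "validate_particle",
    "read_particle_table",
    "write_particle_table",
    "read_soil_samples",
    "write_soil_samples",
    "read_fauna_samples",
    "write_fauna_samples",
    "read_blanks",
    "write_blanks",
    "MP_SIZE_LIMIT_UM",
]

#: Upper size bound of the microplastic definition (< 5 mm), in µm.
MP_SIZE_LIMIT_UM = 5000.0


class Matrix(enum.StrEnum):
    SOIL = "soil"
    EARTHWORM = "earthworm"
    EARWIG = "earwig"


class Season(enum.StrEnum):
    SUMMER = "summer"
    AUTUMN = "autumn"
    WINTER = "winter"
    SPRING = "spring"


class Shape(enum.StrEnum):
    FIBER = "fiber"
    FRAGMENT = "fragment"


class Color(enum.StrEnum):
    BLUE = "blue"
    RED = "red"
    BLACK = "black"
    GREEN = "green"
    YELLOW = "yellow"
    WHITE = "white"


class Polymer(enum.StrEnum):
    """FTIR-confirmed polymer identity; NONE marks unconfirmed particles."""

    PES = "PES"
    PE = "PE"
    PP = "PP"
    NONE = "none"


#: Length classes as used in the survey, contiguous half-open intervals
#: (lo, hi]; see :func:`soilmp.characterization.assign_size_class`.
SizeClass = str


class ValidationError(ValueError):
    """A record violates a domain invariant; message names the field."""


@dataclass(frozen=True, slots=True)
class ParticleRecord:
    matrix: Matrix
    season: Season
    sample_id: str
    shape: Shape
    color: Color
    length_um: float
    width_um: float
    polymer: Polymer
    confirmed: bool


def validate_particle(record: ParticleRecord) -> ParticleRecord:
    """Check every particle invariant; return the record unchanged if valid.

    Raises :class:`ValidationError` naming the offending field otherwise.
    """
    if not record.length_um > 0:
        raise ValidationError("length_um: length must be positive")
    if not record.width_um > 0:
        raise ValidationError("width_um: width must be positive")
    if record.length_um >= MP_SIZE_LIMIT_UM:
        raise ValidationError(
            f"length_um: {record.length_um} µm exceeds MP size limit "
            f"(< {MP_SIZE_LIMIT_UM:g} µm)"
        )
    if record.confirmed != (record.polymer is not Polymer.NONE):
        raise ValidationError(
            "confirmed: confirmation flag must match polymer identity "
            "(confirmed=false iff polymer=none)"
        )
    if record.shape is Shape.FIBER and not record.width_um < record.length_um:
        raise ValidationError("width_um: fiber width must be less than its length")
    return record


@dataclass(frozen=True, slots=True)
class SoilSample:
    sample_id: str
    season: Season
    dry_mass_g: float
    particles: tuple[ParticleRecord, ...] = ()

    def __post_init__(self) -> None:
        if not self.dry_mass_g > 0:
            raise ValidationError("dry_mass_g: analyzed dry mass must be positive")
        for p in self.particles:
            if p.matrix is not Matrix.SOIL:
                raise ValidationError(
                    f"particles: {p.matrix} particle in soil sample {self.sample_id}"
                )
            if p.season is not self.season:
                raise ValidationError(
                    f"particles: season mismatch in soil sample {self.sample_id}"
                )


@dataclass(frozen=True, slots=True)
class FaunaSample:
    sample_id: str
    season: Season
    taxon: Matrix
    n_individuals: int
    wet_weight_g: float
    particles: tuple[ParticleRecord, ...] = ()

    def __post_init__(self) -> None:
        if self.taxon not in (Matrix.EARTHWORM, Matrix.EARWIG):
            raise ValidationError(f"taxon: {self.taxon} is not a fauna taxon")
        if self.n_individuals < 1:
            raise ValidationError("n_individuals: pooled sample needs >= 1 individual")
        if not self.wet_weight_g > 0:
            raise ValidationError("wet_weight_g: pooled wet weight must be positive")
        for p in self.particles:
            if p.matrix is not self.taxon:
                raise ValidationError(
                    f"particles: matrix {p.matrix} does not match taxon {self.taxon}"
                )


@dataclass(frozen=True, slots=True)
class BlankRecord:
    season: Season
    blank_id: str
    n_particles: int

    def __post_init__(self) -> None:
        if self.n_particles < 0:
            raise ValidationError("n_particles: blank count cannot be negative")


@dataclass(frozen=True)
class PolymerHazardTable:
    """Per-polymer hazard scores S_n (dimensionless, >= 0)."""

    scores: Mapping[Polymer, float]

    def __post_init__(self) -> None:
        for polymer, s in self.scores.items():
            if s < 0:
                raise ValidationError(f"scores: hazard score for {polymer} is negative")

    def __getitem__(self, polymer: Polymer) -> float:
        return self.scores[polymer]

    def __contains__(self, polymer: Polymer) -> bool:
        return polymer in self.scores


#: Hazard scores used throughout: polyester and polypropylene score 4,
#: polyethylene 11.
DEFAULT_HAZARD_TABLE = PolymerHazardTable(
    {Polymer.PES: 4.0, Polymer.PE: 11.0, Polymer.PP: 4.0}
)

#: Background reference concentration C_o, items/kg dry weight.
DEFAULT_BACKGROUND_C0 = 4.9

#: Class breakpoints; intervals closed on the left (a boundary value falls
#: in the upper class).
DEFAULT_PLI_BREAKS = (10.0, 20.0, 30.0)
DEFAULT_H_BREAKS = (10.0, 100.0, 1000.0)
DEFAULT_RI_BREAKS = (150.0, 300.0, 600.0, 1200.0)


@dataclass(frozen=True)
class RiskConfig:
    background_c0: float = DEFAULT_BACKGROUND_C0
    hazard_table: PolymerHazardTable = DEFAULT_HAZARD_TABLE
    pli_breaks: tuple[float, ...] = DEFAULT_PLI_BREAKS
    h_breaks: tuple[float, ...] = DEFAULT_H_BREAKS
    ri_breaks: tuple[float, ...] = DEFAULT_RI_BREAKS
    #: polymer percentages enter H on the 0-100 percent scale by default;
    #: set to True to interpret them as 0-1 fractions instead.
    percent_as_fraction: bool = False

    def __post_init__(self) -> None:
        if not self.background_c0 > 0:
            raise ValidationError("background_c0: must be positive")
        for name in ("pli_breaks", "h_breaks", "ri_breaks"):
            breaks = getattr(self, name)
            if any(b >= a for b, a in zip(breaks, breaks[1:])):
                raise ValidationError(f"{name}: thresholds must be strictly increasing")


@dataclass(frozen=True)
class RiskIndexReport:
    """Index chain for one stratum (a season or the pooled year)."""

    stratum: str
    c_i: float  # items/kg dry weight
    cf_i: float
    pli: float
    h: float
    t_i: float
    ri: float
    pli_class: str
    h_level: str
    ri_level: str


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

_PARTICLE_COLUMNS = [
    "matrix",
    "season",
    "sample_id",
    "shape",
    "color",
    "length_um",
    "width_um",
    "polymer",
    "confirmed",
]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {', '.join(missing)}")


def _coerce_enum(token: str, enum_cls: type[enum.StrEnum], column: str) -> enum.StrEnum:
    try:
        return enum_cls(token)
    except ValueError:
        allowed = ", ".join(m.value for m in enum_cls)
        raise ValidationError(
            f"{column}: unknown category {token!r} (allowed: {allowed})"
        ) from None


def read_particle_table(path: str | Path) -> list[ParticleRecord]:
    """Read a particle CSV; every row is validated against the invariants."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _PARTICLE_COLUMNS, path)
    records = []
    for row in df.itertuples(index=False):
        try:
            length = float(row.length_um)
            width = float(row.width_um)
        except ValueError as exc:
            raise ValidationError(f"{path}: unparsable numeric field ({exc})") from None
        if row.confirmed not in ("True", "False", "true", "false"):
            raise ValidationError(f"confirmed: unparsable boolean {row.confirmed!r}")
        record = ParticleRecord(
            matrix=_coerce_enum(row.matrix, Matrix, "matrix"),
            season=_coerce_enum(row.season, Season, "season"),
            sample_id=row.sample_id,
            shape=_coerce_enum(row.shape, Shape, "shape"),
            color=_coerce_enum(row.color, Color, "color"),
            length_um=length,
            width_um=width,
            polymer=_coerce_enum(row.polymer, Polymer, "polymer"),
            confirmed=row.confirmed in ("True", "true"),
        )
        records.append(validate_particle(record))
    return records


def write_particle_table(records: Iterable[ParticleRecord], path: str | Path) -> None:
    rows = [
        {
            "matrix": r.matrix.value,
            "season": r.season.value,
            "sample_id": r.sample_id,
            "shape": r.shape.value,
            "color": r.color.value,
            "length_um": repr(r.length_um),
            "width_um": repr(r.width_um),
            "polymer": r.polymer.value,
            "confirmed": str(r.confirmed),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_PARTICLE_COLUMNS).to_csv(path, index=False)


def read_soil_samples(
    samples_path: str | Path, particles: Iterable[ParticleRecord] = ()
) -> list[SoilSample]:
    """Read soil sample metadata and attach matching particles by sample_id."""
    path = Path(samples_path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["sample_id", "season", "dry_mass_g"], path)
    by_sample: dict[str, list[ParticleRecord]] = {}
    for p in particles:
        by_sample.setdefault(p.sample_id, []).append(p)
    return [
        SoilSample(
            sample_id=row.sample_id,
            season=_coerce_enum(row.season, Season, "season"),
            dry_mass_g=float(row.dry_mass_g),
            particles=tuple(by_sample.get(row.sample_id, ())),
        )
        for row in df.itertuples(index=False)
    ]


def write_soil_samples(samples: Iterable[SoilSample], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "season": s.season.value,
            "dry_mass_g": repr(s.dry_mass_g),
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=["sample_id", "season", "dry_mass_g"]).to_csv(
        path, index=False
    )


def read_fauna_samples(
    samples_path: str | Path, particles: Iterable[ParticleRecord] = ()
) -> list[FaunaSample]:
    path = Path(samples_path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(
        df, ["sample_id", "season", "taxon", "n_individuals", "wet_weight_g"], path
    )
    by_sample: dict[str, list[ParticleRecord]] = {}
    for p in particles:
        by_sample.setdefault(p.sample_id, []).append(p)
    return [
        FaunaSample(
            sample_id=row.sample_id,
            season=_coerce_enum(row.season, Season, "season"),
            taxon=_coerce_enum(row.taxon, Matrix, "taxon"),
            n_individuals=int(row.n_individuals),
            wet_weight_g=float(row.wet_weight_g),
            particles=tuple(by_sample.get(row.sample_id, ())),
        )
        for row in df.itertuples(index=False)
    ]


def write_fauna_samples(samples: Iterable[FaunaSample], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "season": s.season.value,
            "taxon": s.taxon.value,
            "n_individuals": s.n_individuals,
            "wet_weight_g": repr(s.wet_weight_g),
        }
        for s in samples
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "season", "taxon", "n_individuals", "wet_weight_g"]
    ).to_csv(path, index=False)


def read_blanks(path: str | Path) -> list[BlankRecord]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["season", "blank_id", "n_particles"], path)
    return [
        BlankRecord(
            season=_coerce_enum(row.season, Season, "season"),
            blank_id=row.blank_id,
            n_particles=int(row.n_particles),
        )
        for row in df.itertuples(index=False)
    ]


def write_blanks(blanks: Iterable[BlankRecord], path: str | Path) -> None:
    rows = [
        {"season": b.season.value, "blank_id": b.blank_id, "n_particles": b.n_particles}
        for b in blanks
    ]
    pd.DataFrame(rows, columns=["season", "blank_id", "n_particles"]).to_csv(
        path, index=False
    )
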