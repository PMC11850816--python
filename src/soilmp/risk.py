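"""Microplastic pollution risk indices and their hazard-level schemes.

Three chained indices for one stratum (a season or the pooled year):

* contamination factor   ``CF_i = C_i / C_o``   with background
  ``C_o = 4.9`` items/kg dry weight,
* pollution load index   ``PLI = sqrt(CF_i)``   (low < 10, medium 10–20,
  high 20–30, extremely high > 30),
* polymer hazard index   ``H = sum(P_n * S_n)`` over polymer shares P_n
  (percent scale) with hazard scores PES = 4, PE = 11, PP = 4
  (levels I < 10, II 10–100, III 100–1000, IV > 1000),
* toxicity coefficient   ``T_i = H / C_i``,
* ecological risk index  ``RI = T_i * CF_i``    (levels I < 150, II 150–300,
  III 300–600, IV 600–1200, V > 1200).

Algebraically ``RI = H / C_o``; the source table this chain reproduces
prints an RI column that instead equals the raw concentration ``C_i`` and
cannot be derived from the stated equations.  This implementation follows
the equations; :data:`RI_DISCREPANCY_NOTE` carries the footnote that every
rendered report includes.

Class intervals are closed on the left (a value on a printed boundary such
as PLI = 10 falls in the upper class); the printed "10–20" style is
ambiguous at the edges and the convention is fixed here once.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .characterization import CompositionProfile, seasonal_summary
from .data_model import (
    Polymer,
    PolymerHazardTable,
    RiskConfig,
    RiskIndexReport,
    SoilSample,
    ValidationError,
)

__all__ = [
    "contamination_factor",
    "pollution_load_index",
    "aggregate_pli",
    "classify_pli",
    "polymer_hazard_index",
    "classify_h",
    "toxicity_coefficient",
    "ecological_risk_index",
    "classify_ri",
    "build_report",
    "build_report_from_samples",
    "RI_DISCREPANCY_NOTE",
]

RI_DISCREPANCY_NOTE = (
    "Note: RI is computed as T_i × CF_i (equivalently H/C_o). The source "
    "table's RI column numerically equals the raw concentration C_i for "
    "every stratum and cannot be derived from the stated equations; it is "
    "not reproduced here."
)

PLI_CLASSES = ("low", "medium", "high", "extremely high")
H_LEVELS = ("I", "II", "III", "IV")
RI_LEVELS = ("I", "II", "III", "IV", "V")


def contamination_factor(c_i: float, c_0: float) -> float:
    """CF_i = C_i / C_o (both items/kg dry weight)."""
    if not c_0 > 0:
        raise ValidationError("c_0: background concentration must be positive")
    if c_i < 0:
        raise ValidationError("c_i: concentration cannot be negative")
    return c_i / c_0


def pollution_load_index(cf: float) -> float:
    """PLI = sqrt(CF_i) for a single stratum."""
    if cf < 0:
        raise ValidationError("cf: contamination factor cannot be negative")
    return math.sqrt(cf)


def aggregate_pli(plis: Iterable[float]) -> float:
    """Cross-stratum PLI: geometric mean of per-stratum PLI values.

    Not part of the single-site seasonal table; provided for multi-site use.
    """
    values = np.asarray(list(plis), dtype=float)
    if values.size == 0:
        raise ValidationError("plis: need at least one value")
    if np.any(values < 0):
        raise ValidationError("plis: negative PLI")
    return float(np.exp(np.mean(np.log(values))))


def _classify(value: float, breaks: Sequence[float], labels: Sequence[str]) -> str:
    # intervals closed on the left: value == break falls in the upper class
    if value < 0:
        raise ValidationError("value: index values are non-negative")
    for b, label in zip(breaks, labels):
        if value < b:
            return label
    return labels[len(breaks)]


def classify_pli(pli: float, breaks: Sequence[float] = (10.0, 20.0, 30.0)) -> str:
    return _classify(pli, breaks, PLI_CLASSES)


def polymer_hazard_index(
    profile: CompositionProfile | Mapping[Polymer | str, float],
    table: PolymerHazardTable,
    percent_as_fraction: bool = False,
) -> float:
    """H = sum over polymers of share x hazard score.

    Shares enter on the 0–100 percent scale by default (100% PES with score
    4 gives H = 400); ``percent_as_fraction`` switches to the 0–1 scale for
    cross-study comparability.
    """
    if isinstance(profile, CompositionProfile):
        shares = dict(profile.percentages)
    else:
        shares = {str(k): float(v) for k, v in profile.items()}
    h = 0.0
    for name, share in shares.items():
        if share == 0:
            continue
        polymer = Polymer(name)
        if polymer not in table:
            raise ValidationError(f"polymer: no hazard score for {polymer}")
        h += share * table[polymer]
    return h * 100.0 if percent_as_fraction else h


def classify_h(h: float, breaks: Sequence[float] = (10.0, 100.0, 1000.0)) -> str:
    return _classify(h, breaks, H_LEVELS)


def toxicity_coefficient(h: float, c_i: float) -> float:
    """T_i = H / C_i; zero H gives zero regardless of concentration."""
    if h == 0:
        return 0.0
    if not c_i > 0:
        raise ValidationError("c_i: concentration must be positive")
    return h / c_i


def ecological_risk_index(t: float, cf: float) -> float:
    """RI = T_i x CF_i (see RI_DISCREPANCY_NOTE)."""
    if t < 0 or cf < 0:
        raise ValidationError("t/cf: index inputs are non-negative")
    return t * cf


def classify_ri(
    ri: float, breaks: Sequence[float] = (150.0, 300.0, 600.0, 1200.0)
) -> str:
    return _classify(ri, breaks, RI_LEVELS)


def build_report(
    concentrations: Mapping[str, float],
    polymer_profiles: Mapping[str, CompositionProfile | Mapping],
    config: RiskConfig | None = None,
) -> list[RiskIndexReport]:
    """Chain C_i -> CF -> PLI -> H -> T -> RI for each stratum.

    ``concentrations`` maps stratum label -> items/kg; ``polymer_profiles``
    maps the same labels to polymer percentage vectors.  Values are kept at
    full precision; round only when rendering.
    """
    config = config or RiskConfig()
    if not concentrations:
        raise ValidationError("concentrations: no strata")
    reports = []
    for stratum, c_i in concentrations.items():
        try:
            profile = polymer_profiles[stratum]
        except KeyError:
            raise ValidationError(
                f"polymer_profiles: missing stratum {stratum!r}"
            ) from None
        cf = contamination_factor(c_i, config.background_c0)
        pli = pollution_load_index(cf)
        h = polymer_hazard_index(
            profile, config.hazard_table, config.percent_as_fraction
        )
        t = toxicity_coefficient(h, c_i)
        ri = ecological_risk_index(t, cf)
        reports.append(
            RiskIndexReport(
                stratum=stratum,
                c_i=c_i,
                cf_i=cf,
                pli=pli,
                h=h,
                t_i=t,
                ri=ri,
                pli_class=classify_pli(pli, config.pli_breaks),
                h_level=classify_h(h, config.h_breaks),
                ri_level=classify_ri(ri, config.ri_breaks),
            )
        )
    return reports


def build_report_from_samples(
    samples: Sequence[SoilSample],
    polymer_profiles: Mapping[str, CompositionProfile | Mapping],
    config: RiskConfig | None = None,
) -> list[RiskIndexReport]:
    """As :func:`build_report`, with seasonal C_i computed from soil samples
    (per-season mean concentration; pooled year = mean of seasonal means)."""
    summaries = seasonal_summary(samples, "soil_concentration")
    concentrations = {s.stratum: s.mean for s in summaries}
    return build_report(concentrations, polymer_profiles, config)
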