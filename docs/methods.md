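# Methods

`soilmp` models a one-year microplastic (MP) monitoring campaign in a single
agricultural plot: seasonal soil sampling, body-burden measurement in two
soil macroinvertebrates (the earthworm *Aporrectodea caliginosa* and the
earwig *Anisolabis maritima*), compositional characterization of the
recovered particles, and a chain of pollution risk indices. Because no
particle-level field data are distributed with the study it models, the
package ships a calibrated synthetic-data generator; every downstream stage
is exercised end to end on that cohort.

## Data model

A detected particle carries its matrix (soil, earthworm, earwig), season,
shape (fiber or fragment), color (six observed colors), length and width in
µm, polymer identity (PES, PE, PP) and an FTIR confirmation flag. The
category sets are closed: the campaign observed exhaustive lists, and the
percentage arithmetic downstream relies on the categories being total, so
unknown tokens are validation errors rather than an "other" bucket.
Particles at or above 5000 µm violate the MP definition (< 5 mm) and are
rejected. `confirmed=false` is equivalent to `polymer=none`; unconfirmed
(cellulose-like) particles are retained on read and excluded by an explicit
filter before any metric.

Units are fixed at the boundary: µm for dimensions, g for masses,
items/kg dry weight for soil concentrations, items per individual and
items/g wet weight for fauna burdens.

## Synthetic cohort

The generator emulates the campaign design: 5 soil samples per season at
50 g analyzed dry mass, 5 pooled fauna samples per taxon per season
(earthworms pooled 3–5 individuals, earwigs 5–10), 5 procedural blanks per
season. Defaults are the calibrated study conditions:

| parameter | default | note |
|---|---|---|
| soil mean concentration (items/kg) | summer 664, autumn 354, winter 456, spring 540 | seasonal calibration targets |
| soil concentration SD | 90.20, 70.92, 80.56, 80.56 | winter/spring SDs unreported; set to the mean of the two reported SDs |
| concentration truncation | [280, 760] items/kg | the observed range, applied in all seasons |
| fiber share | 96.03% (soil), 94.30% (earthworm), 95% (earwig) | |
| colors (soil) | blue 66.79, red 18.50, black 11.73, white 0.20, green/yellow 1.39 each (%) | green/yellow unreported; remainder split evenly |
| polymers (soil, seasonal) | PES 93.98/97.74/96.49/97.04%; PE = (H−400)/7; PP remainder | PE/PP shares recovered by inverting the hazard index (see below) |
| polymers (soil, annual) | PES 96.03, PE 2.83, PP 1.14 (%) | reported annual shares, stored separately from the seasonal vectors |
| confirmation rate | 98.22% | cellulose-like extras are added around the confirmed counts |
| earthworm burden (items/ind) | 5.07, 5.28, 6.54, 10.47 | winter unreported; recovered from the annual mean-of-means 6.84 |
| earwig burden (items/ind) | 3.18, 2.04, 1.90, 1.10 | annual mean 2.055 |
| burden dispersion | negative binomial k = 5 (k = ∞ gives Poisson) | overdispersion consistent with the large reported SDs |
| individual wet weight | earthworm 0.1834 g, earwig 0.0133 g | annual burden ÷ annual per-gram burden |
| blank rate | 0.55 particles/blank | 20 blanks/year × 0.55 = 11 expected annual blank particles |

Per-sample soil concentrations are truncated-normal draws discretised to a
whole confirmed-particle count at 50 g and converted back; fauna burdens
are per-individual negative-binomial draws summed over the pool; pooled wet
weight gets mean-preserving lognormal noise (σ = 0.1).

**Size distributions.** Lengths and widths are lognormal, truncated to the
observed ranges. The lognormal parameters are solved numerically so the
*truncated* distribution attains the configured mean and SD: matching the
untruncated moments first and then truncating biases the SD by up to ~18%
for the fiber-length distribution, which would defeat moment recovery.
Where the targets are infeasible inside the range the solver falls back to
untruncated matching and the truncation bias is accepted. Fauna length
distributions reuse the soil lognormal parameters restricted to each
taxon's observed range (fauna length means/SDs are unreported; ingestion
from the ambient soil pool is the natural default). Fauna widths use the
reported taxon-specific moments.

**Polymer-share inversion.** Seasonal PE/PP splits are unreported. With
three polymers summing to 100% and hazard scores PES = 4, PE = 11, PP = 4,
the hazard index reduces to H = 400 + 7·PE%, so the seasonal PE share is
recovered from the seasonal H values and PP takes the remainder (negative
rounding artifacts clamped to 0). Fauna PE/PP remainders are unconstrained
by any index; they are split evenly except where a polymer was recorded
absent in a season.

**Determinism.** All randomness descends from `GeneratorConfig.seed`
through a `SeedSequence` spawn tree (one child stream per season × data
stream), so a full year is a pure function of the config and CSV output is
byte-identical across runs.

**What the generator does not emulate.** Spatial structure within the
plot, weather covariates, mechanistic soil-to-fauna transfer, selective
ingestion, and correlations between particle attributes (shape, color,
polymer and size are drawn independently). Passing tests therefore show
that the pipeline's arithmetic and inference behave correctly under the
calibrated marginal distributions — not that those independence assumptions
hold in real soil.

## Characterization

Confirmation filtering precedes every metric. Blank assessment is
advisory: a correction is only recommended when the mean blank count
exceeds 5% (configurable) of the mean per-sample count; at the calibrated
blank rate the ratio is ≈ 2%, so no correction is applied.

Seasonal summaries report the sample SD (ddof = 1) over per-sample values.
The pooled-year mean is the **unweighted mean of the four seasonal means**:
that is the only convention under which {664, 354, 456, 540} gives the
annual 503.50 items/kg. The annual SD is the pooled per-sample SD and the
annual n the total sample count; both are reported alongside so the
convention is inspectable. Fauna metrics use pooled-sample denominators
(items per individual uses the pool's individual count), so
between-individual variance is understated relative to unpooled sampling.

Length classes are the campaign's seven bins. The printed labels have
1-µm typographic gaps ("≤500, 501–1000, …"); they are implemented as
contiguous half-open intervals (0,500], (500,1000], …, (3500,4500] so
binning is total and monotone on (0, 5000); lengths above 4500 µm map to an
overflow label with a logged warning.

## Risk indices

For a stratum with mean concentration C_i (items/kg dw):

- CF_i = C_i / C_o, with background C_o = 4.9 items/kg dw;
- PLI = √CF_i, classed low (< 10), medium (10–20), high (20–30),
  extremely high (> 30); a geometric-mean aggregate PLI is provided for
  multi-site use;
- H = Σ P_n·S_n over polymer shares P_n on the **percent** scale with
  scores PES = 4, PE = 11, PP = 4 (a 100%-PES stratum gives H = 400; a
  fraction-scale switch exists for cross-study comparability), levels
  I (< 10), II (10–100), III (100–1000), IV (> 1000);
- T_i = H / C_i and RI = T_i × CF_i, levels I (< 150) through V (> 1200).

All class intervals are closed on the left (PLI = 10 is "medium",
H = 1000 is "IV"); the published "10–20"-style ranges are ambiguous at the
edges and the convention is fixed once here.

Algebraically RI = H / C_o (≈ 85–87 for every stratum here, level I). The
published table this chain reproduces prints an RI column that instead
equals C_i for every stratum; that column cannot be derived from the stated
equations, so the implementation follows the equations and every rendered
report carries a footnote stating the discrepancy rather than silently
reproducing either side.

The exact-vector mode feeds the configured concentrations and polymer
vectors directly into this chain (no particle draws). This is deliberate:
with whole particles at 50 g per sample, per-sample concentrations move in
20 items/kg steps and a seasonal mean of, e.g., 354 items/kg is not exactly
realizable, so reproduction of the reference table to ±0.01 is defined on
the exact path, while the sampled path demonstrates the same chain under
sampling noise.

## Inference

One-way ANOVA (F = MS_between/MS_within, df (k−1, N−k)), two-sided Pearson
correlation, and Pearson chi-square on contingency tables without
continuity correction, all via `scipy.stats` behind a validating surface.
The seasonal comparison runs the omnibus ANOVA and, when significant at
α = 0.05, Tukey HSD pairwise comparisons (no post-hoc procedure is named in
the source; Tukey is the standard companion). Levene's test is computed and
logged but never gates the analysis. Identical groups give F = 0, p = 1;
groups with zero variance both within and between are rejected as
degenerate.

Simulation studies at the design size (5 samples/season, 200 or 1000
replicates — sizes chosen so each study runs in seconds): the omnibus test
rejects in ≈ 100% of replicates at the calibrated seasonal means/SDs, and
the type-I error under equal means is ≈ 0.05. A stricter property — summer
flagged as significantly higher than *all* three other seasons by Tukey HSD
— replicates in only ≈ ⅓ of years at these effect sizes, because the
summer-vs-spring contrast (664 vs 540 at SD ≈ 80–90, n = 5) has modest
power; a single year's claim of that form should be read accordingly.

Published correlation coefficients between burden and body size
(r = 0.5, 0.37) and between burden and soil concentration (r = 0.08, 0.2)
depend on unpublished per-individual data and sample sizes and are not
reproducible; the Pearson machinery is provided and tested on constructed
examples instead. Similarly, the reported seasonal fauna SDs and the
printed RI column are not reproduction targets.

## Known limitations

- Attribute independence in the generator (above).
- The annual-vs-pooled averaging ambiguity for fauna burdens (an annual
  mean of 6.84 by mean-of-means vs 419/62 = 6.76 pooled) is resolved in
  favor of mean-of-means; both readings are within rounding of each other.
- A 504-particle cohort at "98.22%" confirmed has no integer realization;
  the closest is 495/504 = 98.21%. The generator draws unconfirmed extras
  stochastically around the configured rate rather than forcing a count.
- Blank counts are Poisson and season-independent; real procedural
  contamination may cluster by solution batch.
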