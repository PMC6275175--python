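# Methods

This note documents the models implemented in `plfasip`, the assumptions
they rest on, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that
make runs reproducible. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Isotope arithmetic

All δ¹³C values are per-mil deviations from VPDB. Conversions to atom
fraction use AF = R/(1+R) with R = R_VPDB·(δ/1000 + 1); the standard ratio
defaults to **R_VPDB = 0.0111802**, is configurable on `IsotopeConstants`,
and is echoed into every run-metadata file so results are interpretable
without reading code. δ ≤ −1000 ‰ (atom fraction ≤ 0) is rejected for
measured material; −1000 exactly is accepted as the mathematical limit.

**FAME correction.** GC measurements are made on fatty-acid methyl esters;
the methylation adds one methanol carbon, so
δ_PLFA = ((n+1)·δ_FAME − δ_MeOH)/n with *n* the carbon count of the
underivatized acid. Carbon counts ship in the biomarker catalog and are
cross-checked against a name parser (acyl chain length from the shorthand;
a 10-methyl branch adds one carbon, so 10Me16:0 → 17). The derivatization
methanol δ defaults to −40 ‰ — a typical petrochemical methanol value —
and must be set to the batch value actually used.

**Mixing model.** The litter-derived share is computed in the δ-linear
form, %C_litter = 100·(δ_sample − δ_reference)/(δ_litter − δ_soil), which
is how the two-pool partitioning is conventionally applied. Exact isotope
mass balance is linear in atom fraction, not δ; at these enrichments
(~930 ‰ span) the two forms differ by up to ~0.25 percentage points at
mid-mixing. The atom-fraction variant is available
(`mixing_mode="atom_fraction"`, or
`fraction_litter_derived_atom_fraction`) for sensitivity checks; the
δ-linear form is the default and is what the synthetic generator inverts,
so the zero-noise identity is exact.

Two distinct references exist and are deliberately not conflated: the
**Eq-reference** (time-matched no-litter control of the same field, used as
δ_reference and for excess ¹³C) and the **soil endmember** (bulk soil δ at
experiment start, used in the mixing denominator). For CO₂ the reference is
the no-litter control bottle's evolved δ by default; using the
unlabeled-litter bottle instead is supported through
`RunConfig.reference_treatment` because either reading is defensible when a
protocol does not say which control anchored the partitioning.

Negative excess ¹³C and %litter outside [0, 100] are *flagged and
preserved*. Clipping would bias every group aggregate upward at low
enrichment, so QC flags surface in a dedicated table instead.

## Chamber fluxes

Bottles are closed for ~4.5 h; a 15 mL t₀ sample is withdrawn (before the
N₂ refill, so c₀ measures the undiluted headspace) and replaced by CO₂-free
N₂, diluting every species by (V − v)/V at the start of the interval. Under
linear accumulation the two-point estimator
rate = (c₁ − c₀·(V−v)/V)·V/(Δt·m) is exactly unbiased for constant
production — verified against an independent event-by-event mass-balance
simulation — while ignoring the dilution underestimates any flux with
c₀ > 0. The ¹³C flux applies the same difference to AF·c, and the evolved
δ follows from the flux ratio; for a single constant source it equals the
source δ exactly. No exponential chamber correction or Keeling-plot
partitioning is applied: over 4.5 h at these rates the headspace
accumulation stays far from saturation, and the two-point protocol does not
support multi-point regression.

Headspace volume is an input, not a constant: default 333 mL bottle minus
the volume of 50 g dry soil at a configurable bulk density of 1.4 g cm⁻³
(≈ 297 mL). Concentrations are accepted either as μg C mL⁻¹ or as ppm with
an ideal-gas conversion at the incubation temperature (default 17.5 °C,
1 atm). ¹³C rates are reported on the carbon-mass scale (AF × C mass), i.e.
"μg of carbon that is ¹³C"; generator and estimator share this convention.

## Functional groups

The default catalog holds 24 biomarkers. Thirteen carry the standard group
assignments — fungi (18:2ω6), gram-negative bacteria (16:1ω7, cy17:0,
18:1ω7), gram-positive bacteria (a15:0, a17:0, i15:0, i16:0, i17:0),
actinomycetes (10Me16:0, 10Me17:0, 10Me18:0), micro-fauna (20:4) — and the
remaining eleven are common general biomarkers (14:0, 15:0, 16:0, 17:0,
18:0, 16:1ω5, 16:1ω9, 18:1ω9, 18:1ω5, cy19:0, 20:0) that count toward
total biomass only. The catalog is a plain TSV and fully replaceable, so
any assignment scheme can be reproduced; group biomass always partitions
exactly (assigned + unassigned = total). Micro-fauna is included in the
total PLFA pool. The fungal/bacterial ratio excludes actinomycetes by
default (`include_actinomycetes=True` folds them in), and replicate ratios
are averaged as mean-of-ratios by default (ratio-of-means available).

## Succession

Group excess-¹³C courses are z-scored over the whole incubation with the
**sample** standard deviation (ddof = 1; population sd available), computed
per (group × field) and then averaged across fields — treating fields as
the unit, consistent with the contrast test — with a pooled mode as the
alternative. Constant series raise an explicit degenerate-series error
rather than returning silent zeros; such groups are excluded from the
ordering with a recorded reason. The peak is the earliest day attaining the
maximum (ties flagged); groups order by peak day, and equal peak days are
reported as a "≥" tie broken by the interpolated time to half-maximum —
the group that rose to half its peak sooner accessed the substrate sooner.
This operationalizes the gram-positive vs actinomycete tie: both peak at
day 14, but gram-positives rise faster while actinomycetes plateau.
Because z-scoring is a strictly increasing transform of each series, the
ordering is identical on raw and normalized series.

## The synthetic generator

The generator emulates the statistical structure of a litter-amendment
incubation, not soil biogeochemistry. Design defaults: 3 recent + 3
long-term fields, harvests at days 1, 3, 7, 14, 28, 56; per field × day,
3 labeled bottles, 1 unlabeled-litter control, 1 no-litter control; litter
endmember 904.0 ‰, soil −25.7 ‰; 0.5 g litter (45 % C) on 50 g dry soil.

- **Uptake kinetics.** Each group's litter-derived PLFA pool follows a
  rise-then-decay curve: gamma-shaped rise (t/p)^a·e^{a(1−t/p)} peaking at
  day p, exponential decay e^{−(t−p)/τ} after it. Defaults (p, a, τ, peak
  nmol C g⁻¹): fungi (1, 1.5, 3, 800), G⁻ (3, 2, 8, 240), G⁺ (14, 2, 12,
  100), actinomycetes (14, 3, 60, 22), micro-fauna (28, 2.5, 40, 12),
  unassigned (3, 2, 20, 300). The shapes encode the narrative the analysis
  must recover: a fungal burst that collapses, bacterial build-up to day 14,
  an actinomycete plateau (long τ) with a slower rise than G⁺ (larger a),
  late micro-fauna. Amplitudes make the day-1 fungal pool dominate the
  ~1000 nmol C g⁻¹ litter-derived biomass build-up, with fungal pools ~98 %
  litter-derived at their peak.
- **Baselines.** Stage-level baseline biomass (long-term ≈ 1.35× recent,
  totals ≈ 872 vs 1177 nmol C g⁻¹ split across groups) with a per-field
  lognormal multiplier (CV 10 %) shared by basal respiration — this is what
  gives the stage contrast its field-level replication structure.
- **Deltas.** A biomarker that is fraction f litter-derived gets
  δ = f·δ_litter + (1−f)·δ_soil — the δ-linear model the pipeline inverts,
  so at zero noise recovery is exact to machine precision (the package's
  own zero-noise identity test). The δ is then pushed through the FAME
  forward model δ_FAME = (n·δ_PLFA + δ_MeOH)/(n+1), forcing the analysis to
  undo the derivatization.
- **Respiration.** rate(t) = basal + pulse·e^{−kt} with (basal, pulse, k) =
  (7.2, 115, 0.30) for recent and (8.6, 123, 0.30) for long-term fields and
  55 % of the pulse litter-derived (the remainder is primed native
  mineralization, so day-1 litter-derived CO₂ is ~51 % of the total while
  the total is >10× basal). Chamber observations are built by exact mass
  balance from ambient closure conditions (400 ppm, −8.5 ‰) through the
  withdrawal/refill event and linear accumulation.
- **Noise.** Additive Gaussian noise on δ (sd 10 ‰, both PLFA and gas —
  deliberately coarse for compound-specific IRMS), mean-preserving
  lognormal noise on PLFA amounts (CV 10 %) and on gas concentrations
  (CV 2 %, typical GC precision; two-point differencing makes the flux
  estimate far more sensitive to concentration error than the PLFA side is
  to amount error, so this knob is separate).
- **Randomness.** One seed determines everything; field effects, the PLFA
  table and the gas table draw from independently derived substreams, so
  extending one table never shifts another. Identical configs give
  byte-identical tables.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: no microbial turnover or cross-feeding (each
group's curve is independent, whereas real fungal necromass feeds
bacteria), no isotopic fractionation during biosynthesis or respiration, no
heterogeneous labeling of litter fractions, no day-to-day temperature or
moisture variation, uniform noise across biomarkers regardless of peak
size, and litter-derived PLFA allocated proportionally to baseline weights
within a group. Recovery scores on this generator demonstrate that the
*arithmetic pipeline* is unbiased and adequately precise under realistic
noise, not that the biological assumptions hold in any particular soil.

Litter-C conservation is enforced as an invariant: peak litter-derived
PLFA-C plus cumulative litter-derived CO₂-C stays below the litter C input
(defaults use ~5 % of the 4500 μg C g⁻¹ added — PLFA is a small biomarker
fraction of biomass, so the headroom is intentional).

## Ordination and stage contrast

PCA is a column-centered SVD (covariance scaling on relative abundances by
default; correlation scaling optional and recorded in metadata). Axes are
ordered by decreasing variance, variance shares sum to 100 % over all axes,
and the sign convention (largest-|loading| positive per axis) makes output
deterministic. Missing cells are an error; no silent imputation.

The stage contrast is a two-sided permutation test with the **field** as
the permutation unit — replicate bottles are pseudo-replicates and move
with their field — using p = (1 + #{|Δ_perm| ≥ |Δ_obs|})/(1 + n_perm). With
3 + 3 fields the assignment space is enumerated exhaustively (19
non-identity assignments); since each assignment and its complement share
|Δ|, the attainable p floor is 2/20 = 0.1. This floor is a property of the
design, not the implementation: no test on 6 fields can resolve below it,
which is why calibration checks of p-value uniformity use a larger
synthetic design (5 + 5 fields, sampled permutations). Mixed-effects
modeling, normality/variance testing and type-II ANOVA are deliberately out
of scope; the permutation contrast is the distribution-free stand-in.

## Problem sizes and determinism

The default scenario (4320 PLFA rows, 180 chamber observations) runs the
full pipeline in well under a second, so the succession-recovery study uses
200 seeded replicates and the null calibration 1000 simulations; both
complete in seconds to tens of seconds on one CPU. Hypothesis-based
property tests run derandomized. Tolerances: 1e−9 ‰ for conversion and
correction round trips, 1e−6 for zero-noise recovery identities, 1e−12
relative for conservation sums.

## Known limitations

- The δ-linear mixing default inherits the small (≲0.3 pp) mid-range bias
  relative to exact atom-fraction mass balance; the variant exists to
  quantify it per dataset.
- Linear chamber accumulation ignores back-diffusion and headspace
  equilibration; at much longer closures or higher rates a curvature-aware
  model would be needed.
- The ¹³C flux is carbon-mass-scaled (AF × mass C), not corrected for the
  13/12 mass ratio; consistent internally but a ~8 % scale difference from
  a true isotope-mass reading of "μg ¹³C".
- The catalog's eleven unassigned biomarkers are a documented convention,
  not a claim about any particular study's full biomarker list; swap in
  your own catalog TSV to reproduce a specific assignment scheme.
- Peak location is grid-bound: a group truly peaking between harvests is
  assigned the nearest sampled day that maximizes its series.
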