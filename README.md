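# plfasip

Trace ¹³C-labeled plant litter through the soil microbial food web.

`plfasip` is a tested analysis pipeline for **PLFA stable-isotope-probing
(SIP) incubation experiments**: soils amended with ¹³C-enriched litter are
destructively harvested over weeks, phospholipid fatty acid (PLFA)
biomarkers are quantified and their δ¹³C measured, and closed-bottle
headspace sampling yields CO₂ and δ¹³CO₂. From these measurements the
pipeline quantifies how much of each microbial group's biomass — and of the
respired CO₂ — is litter-derived, and recovers the temporal succession of
decomposer groups (fungi first, then gram-negative bacteria, gram-positive
bacteria and actinomycetes, finally micro-fauna). It is written for soil
ecologists and biogeochemists running litter-amendment SIP experiments, and
ships a synthetic incubation generator with known ground truth so every
stage can be validated end to end without any external data.

## The model

**Derivatization correction.** PLFAs are measured as methyl esters (FAMEs),
which carry one methanol-derived carbon. For a PLFA with *n* carbons,

δ¹³C_PLFA = ((n + 1)·δ¹³C_FAME − δ¹³C_MeOH) / n.

**Excess ¹³C.** With atom fraction AF = R/(1+R), R = R_VPDB·(δ/1000 + 1),
the ¹³C enrichment of a pool of carbon mass *c* above its time-matched
no-litter control is

E = (AF(δ_labeled) − AF(δ_control)) · c.

**Two-pool mixing.** The litter-derived share of any pool (PLFA or evolved
CO₂) follows the δ-linear two-source model

%C_litter = 100 · (δ_sample − δ_reference) / (δ_litter − δ_soil),

with litter and soil endmembers (defaults 904.0 ‰ and −25.7 ‰).

**Chamber fluxes.** Two-point closed-headspace sampling with a withdrawal /
N₂-refill dilution correction: after a t₀ sample of volume *v* is replaced
by N₂, every gas species is diluted by (V − v)/V, so the production rate is
(c₁ − c₀·(V − v)/V)·V / (Δt·m), linear accumulation assumed over the ~4.5 h
closure. The δ¹³C of the evolved CO₂ follows from the ¹³C flux / total flux
ratio.

**Succession.** Each group's excess-¹³C time course is z-scored over the
incubation, z = (x − mean(x))/sd(x), and groups are ordered by peak day;
equal peak days are reported as a tie and broken by the interpolated time to
half-maximum.

## Worked example

```sh
python analysis/01_simulate.py --seed 1   # synthetic incubation + truth
python analysis/02_run_pipeline.py        # full analysis
python analysis/03_parameter_recovery.py --seed 1
```

prints

```
succession: fungi > gram_negative > gram_positive >= actinomycetes > microfauna
day-1 respiration (ug C/g/day): mean 96.3, litter-derived 50.6%
ordination: PC1 96.8%, PC2 1.2% of variance
QC flags: 109 (kept, never clipped); results in .../results/pipeline
%litter recovery: MAE 0.26 pp over 30 group x day cells (worst 0.85 pp)
respiration: mean |rel err| 1.77% of truth, litter-derived CO2 MAE 2.00 pp
```

The succession line is the recovered peak ordering of litter-¹³C
incorporation — fungi peak on day 1, gram-negatives on day 3,
gram-positives and actinomycetes share day 14 (tie broken by the faster
gram-positive rise), micro-fauna on day 28 — matching the order the
generator was configured with. Day-1 respiration is ~13× the no-litter
basal rate and about half litter-derived. The recovery lines score the
estimates against the generator's ground truth: with 10 ‰ δ-noise and 10 %
amount noise, litter-derived fractions are recovered to ~0.3 percentage
points and respiration rates to ~2 %. QC flags count measurements whose
noise pushed excess ¹³C below 0 or %litter outside [0, 100]; they are
reported, never clipped.

The same machinery is available as a library:

```python
from plfasip import simulate, pipeline

ds = simulate.simulate_incubation(simulate.default_scenario(seed=1))
res = pipeline.run_pipeline(ds.measurements, ds.gas, pipeline.RunConfig())
print(res.succession.formatted())
```

## Layout

- `src/plfasip/` — the library: `isotope` (δ/atom-fraction arithmetic, FAME
  correction, mixing model), `gasflux` (chamber rates), `community`
  (biomarker catalog and group aggregation), `succession` (normalization
  and peak ordering), `simulate` (scenario generator + truth), `ordination`,
  `contrast` (field-level permutation test), `pipeline` / `io` / `evaluate`.
- `analysis/` — numbered drivers narrating the full analysis.
- `tests/` — unit, property and acceptance tests.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
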