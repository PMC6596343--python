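# Methods

This note records the models, defaults and numerical choices behind
`capsip`, and what the synthetic-data tests do and do not demonstrate
about real SIP data.

## Detection model

Per OTU and time point the detector consumes the quadruple
(R_a, R_b, R_c, R_d) of percent relative abundances defined in the README
and applies four strict-inequality criteria against a threshold
T = mean + 3·SD of the t₀ per-OTU heavy-fraction differences
(¹³C − ¹²C). Choices that were genuinely open:

* **Signed vs absolute differences.** The baseline moments are computed on
  signed differences by default; an `absolute` mode exists. Published
  baseline means are small and positive, consistent with either reading;
  signed is the default because the criteria themselves are one-sided in
  the same direction.
* **SD estimator.** Sample SD with ddof = 1 (conventional for the small
  OTU panels of a t₀ library pair). The threshold identity
  T = mean + 3·SD is enforced to 1e-9 in the `BaselineStats` type.
* **Ties.** A margin exactly equal to T fails (strict `>` as printed in
  the criteria).
* **Absent OTUs.** An OTU missing from a library has relative abundance 0;
  in particular an OTU undetected at t₀ gets R_d = 0, which is what allows
  a fast responder absent before incubation to be scored labeled.
* **Criterion 4.** R_cs = (3·R_a − R_b − R_c − R_d)/3 is algebraically the
  mean of the three criterion margins, so criteria 1–3 imply criterion 4;
  the `require_c4` flag is therefore verdict-neutral and exists for
  explicitness only. R_cs is still the useful *magnitude* of labeling and
  is what the per-day cumulative scores sum over.
* **Cumulative R_cs** sums the R_cs of OTUs labeled *at that day* (not
  ever-labeled OTUs); negative scores of labeled OTUs would be included
  as-is.
* **Replication.** One threshold per oxygen regime applies to all of that
  regime's days; verdicts are optionally (CLI default: yes) required to
  recur on ≥ 2 distinct days (`replication_filter`), mirroring the
  replication-over-time design in which single gradients per time point
  are not technically replicated.
* **Multiple testing.** None beyond the 3σ threshold itself; the method's
  error control is the threshold's tail bound, and the joint requirement
  of three criteria makes the realized false-positive rate much smaller
  than the per-criterion 0.135% (measured ~0.01% in the operating-
  characteristics test).

## Gradient simulator

The generator emulates the experimental design the detector assumes: two
oxygen regimes, time points {0, 3, 10, 21, 70} d, 10-fraction gradients
spanning 1.75–1.84 g ml⁻¹, pooled heavy (1.81–1.83) and light (1.76–1.77)
libraries for ¹³C and ¹²C treatments.

Model, per time point and isotope treatment:

1. Community composition: a fixed baseline profile (default: lognormal
   rank-abundance, σ = 1.2, summing to 100%). Duplicate-slurry pooling is
   modeled as averaging two community draws (`slurry_sd_percent`, default
   0, i.e. identical duplicates).
2. Density placement: each OTU's RNA mass is spread over the grid as a
   Gaussian centered at `unlabeled_bd_mean + atom_fraction × max_bd_shift`
   with SD `bd_spread_sd`. Defaults: center 1.775 g ml⁻¹, maximum shift
   0.04 g ml⁻¹ at 100 atom % ¹³C (a generic full-labeling RNA buoyant
   density shift; linear in atom fraction as the simplest monotone map),
   spread 0.008 g ml⁻¹. Unlabeled material sits at the natural-abundance
   atom fraction 0.011 (the ¹²C substrate is 1.1 atom % ¹³C).
3. Reads: each fraction library is a multinomial sample of
   `reads_per_library` (default 10 000) reads from the fraction's mass
   composition; fractions in the same window are summed into the pooled
   heavy/light library and converted to percent.
4. Library noise: additive truncated-at-zero Gaussian with SD
   `noise_sd_percent` (defaults 0.19% oxic, 0.39% anoxic — the empirical
   baseline SDs of the two regimes) on each library's percent vector,
   then renormalization.

Randomness derives from one seed via documented `SeedSequence` substreams.
The per-fraction multinomial substream is keyed by (day, fraction) and
shared between the isotope treatments, so the ¹²C gradient behaves as a
perfect technical control: with no labeling signal and zero library noise
the two treatments' tables are identical, and all baseline inter-treatment
noise is carried by the single `noise_sd_percent` dial. This is a
deliberate simplification — in real data, treatment-specific gradient,
amplification and sequencing noise are not shared — but it makes the
baseline-noise model explicit and independently tunable.

What passing tests therefore show: the detector's operating
characteristics (false-positive rate under its own estimated threshold,
sensitivity for heavy-fraction excess ≥ 2T) under Gaussian library noise
plus multinomial counting noise on a lognormal community. What they do not
show: robustness to compositional artifacts of amplification, chimeras,
denoising, copy-number variation, or gradient-to-gradient density drift —
none of which the generator models. Per-fraction RNA-yield profiles are a
free model (not calibrated to any measured quantity-vs-density data).

## Process simulator

First-order mineralization: degraded residues R(t) = R₀(1 − e^(−kt)),
with R₀ = supplied carbon / 8. Defaults: k = 0.037 d⁻¹ oxic (≈54%
degraded by day 21) and 0.0124 d⁻¹ anoxic (≈58% by day 70). Degraded
residues are routed, in proportion to `product_split`, to desk-scale
pathways that each conserve the residue's 8 carbons and 32 electrons
exactly:

| pathway | products per residue |
|---|---|
| respiration (oxic) | 8 CO₂ (electrons to O₂, untracked) |
| iron respiration | 8 CO₂ + 32 Fe(II) |
| acetate fermentation | 4 acetate |
| propionate fermentation | 2 propionate + 2 CO₂ + 2 H₂ |
| (iso)butyrate fermentation | 1 (iso)butyrate + 4 CO₂ + 6 H₂ |
| H₂/CO₂ fermentation | 8 CO₂ + 16 H₂ |
| methanogenesis | 4 CH₄ + 4 CO₂ |

Anoxic phase gating (boundaries default days 14 and 42): iron respiration
runs until the second boundary (ferric pool depletion), fermentations
start at the first, methanogenesis at the second; inactive shares are
redistributed proportionally among active sinks, so carbon and electrons
are conserved exactly whenever measurement noise is zero (the conservation
test asserts 100 ± 1e-4 % recovery on the degraded basis at every day).
An `assimilated_fraction` diverts residues to biomass (never recovered as
products). Measurement noise is multiplicative truncated Gaussian on the
product columns only.

The substrate is treated as uniformly ¹³C-labeled, so the CO₂ column *is*
the ¹³CO₂ curve and no isotopologue mixing is simulated.

## Mass balance

* The 45/44 ion ratio is taken as the ¹³CO₂/¹²CO₂ molar ratio after
  background subtraction (the ¹⁷O contribution to m/z 45 is neglected;
  the conversion `atom_fraction_13c` is a pluggable hook if a correction
  is ever needed). Negative corrected m/z-45 areas clamp to 0 with a
  warning; non-positive corrected m/z-44 areas are errors.
* Degree of reduction: 4·C + H − 2·O − 3·N per mole, CHON only; neutral
  acid formulas for the fermentation products (charge-state independent at
  this precision); Fe(III)→Fe(II) counts 1 e⁻ per mole.
* Electron-recovery denominator defaults to *supplied* residues (the
  complete-degradation assumption used for reported recoveries); the CLI
  exposes a `degraded` basis flag.
* Molarity conversions default to the 0.110 L slurry volume. 5 mmol of
  carbon in 110 ml is strictly 45.5 mM while the conventional figure is
  44 mM; both the mmol and mM paths are exposed rather than reconciled.

## Problem sizes and tolerances

The operating-characteristics suite uses 600-OTU zero-signal communities
over 4 post-t₀ days × 5 seeds (12 000 OTU-day pairs) for the
false-positive bound, and 30-OTU communities with 3 fully labeled OTUs
over 50 seeds (300 eligible OTU-day pairs) for the ≥95% sensitivity bound
— sizes chosen to keep the binomial error on both rates well inside their
margins. Percent columns are validated to sum to 100 within 1e-6; TSV
round-trips are exact at 12 significant digits; the threshold identity and
R_cs identities are asserted at 1e-9.

## Known limitations

* The detector treats libraries as given; no compositional-data
  transformation (e.g. CLR) or depth modeling beyond the multinomial.
* One baseline per oxygen regime assumes t₀ noise is representative of all
  later time points of that regime.
* The phase gating of the process simulator is a caricature of redox
  succession (sharp boundaries, fixed split); it is meant to give the mass
  balance realistic-shaped inputs, not to predict fermentation chemistry.
* No taxonomy handling: OTU ids are opaque strings.
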