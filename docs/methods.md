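# Methods

## The measurement model

A flow-through aquarium at steady state obeys a simple mass balance: the
concentration difference between what flows in and what flows out, times the
flow, is the net rate at which its occupants consume or release a compound.
Normalising by total wet gill mass (the symbiont-bearing tissue) gives the
mass-specific net rate

    rate = (C_exp − C_ref) · F / M_gill      [µM · L h⁻¹ / g = µmol g⁻¹ h⁻¹]

signed so that net uptake is negative and net excretion positive. Two
referencing modes exist: against an empty control aquarium run alongside
(which cancels abiotic losses — "rate experiments") or against the input
water ("variation experiments"). When control effluent equals input water
the two are identical, a property the test suite checks.

Because this is a *net* measurement, simultaneous uptake and release of the
same compound cannot be separated; all downstream language ("oxidation",
"excretion") refers to net fluxes.

### Voltammetric interval processing

The electrode cycles through four channels in 30-min intervals (a 2-h "set":
three experimental effluents, then the reference). Each interval holds two
21-scan bursts (minute 0 and minute 15, ~2 s cadence), i.e. 42 scans. After
a channel switch the flow cell still carries the previous channel's water,
so the first 10 scans (24%) of every interval are discarded; the discard is
applied once per interval to the head of the time-ordered scan sequence, not
per burst. Scans are assigned to intervals by timestamp windows rather than
by count, so cadence jitter is tolerated. Intervals with fewer than 22 scans
per analyte (not enough to leave ≥12 after the discard) are flagged
incomplete.

Censoring: scans below the analyte's detection limit (sulfide and
polysulfides 0.20 µM, thiosulfate 30 µM) enter the interval mean as a
substitution value — 0 by default, configurable to limit/2 or the limit.
Zero is the conservative choice: it biases excretion estimates downward and
never manufactures signal. An interval whose mean falls below the limit is
reported as BDL; summary tables render the literal string "BDL", and the
minimum of an "average (min, max)" cell renders "BDL" when the smallest
interval concentration was censored. Min/max in summaries are over interval
concentrations, not raw scans.

### Temporal gating

Rates use only intervals starting after
`max(min_elapsed_h, min_turnovers · volume/flow)` — default 10 h and 3
turnovers — so the aquarium is near steady state. Each experimental interval
is paired with the single reference interval of its own 2-h set; a linear
time-interpolation of the reference series is available as an alternative
pairing but is off by default, since one reference interval per set is what
the sampling design provides.

### Sustained excretion

A compound is reported as persistently excreted when the effluent is above
detection while the paired reference is below detection in at least two
consecutive gated sets. Rates whose experimental *and* reference intervals
are both BDL are flagged `bdl_pair` and excluded from summaries.

## The carbon-fixation chain

Gill tissue hosts the symbionts and incorporates labelled carbon; foot
tissue of the same individual is symbiont-free and, over a ~1-day
incubation, receives no appreciable translocated carbon, so it serves as
that individual's unlabelled baseline. The fraction of gill carbon newly
fixed is the three-endmember mixing expression

    %¹³C_inc = 100 · (A%_gill − A%_foot) / (A%_water − A%_foot),

converted to grams of ¹³C via dry weight and carbon content, to a dry-mass
molar rate by dividing by MW_¹³C (13.00335 g mol⁻¹, the exact isotope mass),
duration and dry weight, and to a wet-mass basis by the dry:wet ratio. These
algebraic forms are the unique ones dimensionally consistent with the
defined terms and the stated output units (µmol ¹³C g⁻¹ h⁻¹); the package
derives them from the term definitions rather than transcribing a formula
image. Helpers convert δ¹³C (‰ vs VPDB, ratio 0.0111802) to atomic percent
for users whose spectrometer reports per-mil values; the pipeline's native
unit is atomic percent. Carbon content is accepted as a fraction or a
percent with an explicit unit declaration.

Measurement noise can place a gill trivially below its foot baseline; the
resulting small negative rate is clamped to zero with a `clamped` flag by
default (the "no carbon incorporation" reporting convention), or passed
through raw on request.

## Allometry

Gill mass is predicted from body wet mass by per-genus ordinary least
squares, gill = a·body + b, fitted on the animals with directly weighed
gills. A straight line (not log-log) is the default because the gill:body
relation is close to proportional over the ~5–40 g body-mass range these
cohorts span; a log-log option exists. Measured gill masses always override
predictions, non-positive predictions are floored at zero with a warning,
and the per-aquarium sum of completed gill masses is exactly the `M_gill`
the flux stage uses — a consistency the pipeline enforces by construction.

## Sulfur stoichiometry

The molar ratios 6.21 (sulfide) and 6.64 (thiosulfate) mol substrate
oxidised per mol C fixed assume 10% efficiency of energy conservation; the
efficiency is stored for documentation but is already embedded in the
ratios. They convert a fixation rate into a predicted oxidation rate, which
supports attributing the aquarium's measured bulk uptake to its `top_k`
most productive individuals:

    attribution% = 100 · Σ_top_k (C_inc,i · gill_i · s_per_c) / (|rate| · M_gill)

flagged `capped` when predictions exceed the measured total (possible since
the prediction chain and the mass balance are independent measurements).
Excretion fractions are computed on a sulfur-atom basis (sulfide 1,
thiosulfate 2, polysulfide chain length configurable 1–8, default 1 —
per-molecule accounting). An interval-arithmetic mode propagates ±1 sd of
both mean rates into a (lo, hi) band, the natural reading of range-style
statements such as "24–30%". Reference Gibbs free energies for the two
oxidations (−732.6 and −738.7 kJ mol⁻¹) are stored constants, not computed.

## Exact tests

With 3–10 animals per group, p-values are computed by enumeration. The
Mann–Whitney U is computed from mid-ranks; the two-sided p is
2·min(P(U ≤ u), P(U ≥ u)) over all C(n₁+n₂, n₁) labelings, capped at 1 —
the convention under which group sizes 3 and 4 with U = 1 give exactly
4/35 ≈ 0.114. The exact p is exposed as a `Fraction`. The Kruskal–Wallis H
uses the standard tie correction; its null is fully enumerated whenever the
number of distinct labelings is ≤ 300,000 (sizes 5+5+4 give 252,252 and
qualify), with seeded Monte-Carlo permutation and the χ²(k−1) approximation
as alternatives, the method always recorded in the result. No
multiple-testing correction is applied anywhere.

## The synthetic generator

`ventflux.synthetic` emulates the five incubation designs: rate experiments
at 105 µM sulfide, 300 µM thiosulfate and sulfur-free (with an empty control
aquarium as reference), and variation experiments at 350 µM sulfide and
300 µM thiosulfate (input water as reference, larger cohorts). What it
models:

* **Cohorts.** Per-genus body masses (normal, ~24–27 g mean), gill masses
  from a genus allometric line plus noise, stacking positions 1..n. True
  per-animal fixation decays geometrically with position,
  `base · (1 − attenuation)^(pos−1)` (default attenuation 0.3), a
  phenomenological stand-in for substrate depletion along the stacked
  partitions — not a hydrodynamic model. True sulfur uptake is coupled to
  fixation by the substrate's S:C ratio, making attribution closure exact.
* **Chemistry.** Well-mixed steady state: effluent = supplied − Σ(uptake ·
  gill)/flow, floored at zero with a warning; excretion rules (e.g. sulfide
  → thiosulfate at 27% on a sulfur-atom basis) add the excreted analyte to
  the effluent. A linear ramp from the supplied concentration to steady
  state over the first three turnovers gives the gating rule something real
  to exclude. An optional abiotic loss fraction applies equally to control
  and experimental aquaria (as a shared systematic it cancels under control
  differencing).
* **Scans.** The 4-channel cycle with two 21-scan bursts per interval; the
  first `transient_scans` of each interval relax exponentially from the
  previously sampled channel's concentration (carry-over); Gaussian noise
  with standard deviation `noise_sd_uM · signal/100 + 0.05 · detection
  limit` — signal-proportional instrumental noise plus a small baseline
  term, so zero-analyte channels stay convincingly below detection; values
  under the limit are emitted with the censored flag set.
* **Isotopes.** A%_foot at natural abundance (1.11 atom %), A%_gill set by
  the exact algebraic inverse of the fixation chain (so zero-noise recovery
  is an identity to 1e-9 relative), label water at 5 atom % ¹³C, dry:wet
  ratio 0.15, carbon content 0.35 of dry weight — typical values for
  lyophilised gill tissue. Enrichments beyond the label strength raise an
  error as unphysical.

Defaults for quantities the experimental design fixes (input concentrations,
cohort sizes, schedule, detection limits, gating) are those study
conditions; for quantities never printed (flow, volume, noise) the defaults
are 1 L h⁻¹ flow and 2 L volume — consistent with the 10-h/3-turnover gating
arithmetic — and scan noise of 1 µM at a 100 µM signal. Everything is
deterministic under a fixed seed, which is written as a `# seed=N` header
into every output file. Simulated experiments run 24 h (12 sets), which
keeps a full five-scenario suite within seconds while leaving 7 gated sets
per aquarium.

What the generator does **not** emulate — and therefore what passing tests
cannot certify about real data: electrode drift and calibration error,
oxygen dynamics, transient metabolic regulation (uptake rates are constant
in time), inter-individual variance beyond the positional gradient, symbiont
phylotype differences, and label translocation from gill to other tissues.

## Numerical choices

* Discard-percentage rounding is half-up to the nearest integer percent
  (10/42 → 24%).
* Interval means are plain arithmetic means; summary sd is the sample
  (ddof = 1) standard deviation, reported as 0 with `n_sets = 1` for
  singletons.
* All pipeline floats are serialised at 6 significant digits so reruns are
  byte-identical and diffable; the pipeline itself is idempotent and
  seed-deterministic.
* Units are fixed pipeline-wide (µM, L h⁻¹, g wet tissue, hours); any
  conversion happens at the I/O boundary.
* Flow rate is configuration, never inferred from data.

## Known limitations

* Net fluxes only; no separation of gross uptake and release.
* The steady-state generator cannot probe the pipeline's behaviour under
  genuinely transient chemistry (only the ramp-in period is non-steady).
* Attribution inherits the uncertainty of both the stoichiometric ratios
  and the fixation measurements; values above 100% are reported and capped
  rather than hidden.
* The exact Kruskal–Wallis enumeration is exponential in group sizes; above
  the enumeration bound the seeded permutation mode is the honest fallback.
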