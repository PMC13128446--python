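# Methods

This note documents the models implemented in `morpharm`, the defaults
and the reasoning behind the open design choices.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Dose–response and binding kinetics (`morpharm.doseresponse`)

**Model.** Concentration–response data are fitted with the
three-parameter logistic (Hill slope fixed at 1),
`y = bottom + (top − bottom)/(1 + EC50/x)`, by least squares on log10
concentration with pEC50 = −log10(EC50) as the free parameter; this keeps
the optimizer well conditioned across the 10⁻¹²–10⁻⁶ M range.  The
`bottom ≤ top` constraint is enforced by parameterizing the span
(top − bottom ≥ 0), not by clipping.  Starting values come from the
dose-averaged response extremes and the concentration bracketing the
half-span.  Replicates are pooled with equal weights; per-experiment
fits are available by grouping before fitting.  Inputs are assumed
background-subtracted; `subtract_ligand_free` provides the documented
pre-step (mean of zero-concentration wells).

Degenerate inputs (constant responses, unbracketed curves) return a
result with `converged=False` and a message — never a silent fit.
Fewer than four distinct concentrations is a refusal: three parameters
cannot be identified from three doses.

**Kinetics.** Dissociation is `B(t) = B0·exp(−k_off·t)`; association is
`B(t) = Beq·(1 − exp(−k_obs·t))` with `k_off` supplied from the
dissociation fit (mirroring the two-stage protocol in which `k_off` is an
input parameter to the association routine), and
`k_on = (k_obs − k_off)/L`.  `t½ = ln2/k_off` holds exactly for every
emitted `KineticFit` — half-lives printed elsewhere from rounded rate
constants can differ by ~1–2%, which is display rounding, not a model
discrepancy.  A fitted `k_obs < k_off` yields a negative `k_on` and is
flagged non-physical.

**Cheng–Prusoff.** `Ki = IC50/(1 + L/Kd)`; `L = 0` degenerates to
`Ki = IC50`.  Competition curves are fitted in the decreasing
orientation; increasing data are flagged as an orientation error.

## Kinetic BRET bias (`morpharm.bias`)

At each timepoint of a kinetic plate (default grid 2–46 min in 2-min
cycles; arbitrary strictly increasing grids accepted) the raw BRET ratio
is fitted per compound.  Net BRET subtracts the *fitted* curve minimum,
not the smallest observation, so the quantity is invariant to a constant
offset of the raw ratios.  %Emax is the compound's maximal net BRET
(the fitted span) as a percentage of the reference (DAMGO) span at the
same timepoint, which is why supramaximal values above 100% arise.

The proxy transduction index is `TI = log10(%Emax/EC50)` — deliberately
distinct from the operational-model transduction coefficient log(τ/KA),
which is out of scope.  The log base (10) and the molar EC50 convention
are declared and configurable; because bias is a double difference, a
common rescaling of all EC50s cancels, so the unit convention affects
only the reported TI scale, never ΔTI or bias.

TI is computed per independent experiment and then averaged; σ in
`s.e.m. = σ/√n` is the across-experiment standard deviation of TI.
Errors propagate in quadrature:
`SE_assay = √(sem_compound² + sem_DAMGO²)` per pathway and
`SE_final = √(SE_Go² + SE_βarr2²)`.  The reference compound's ΔTI and
bias are identically zero by construction.  Timepoints whose reference
curve is missing or unconverged are skipped with a warning and reported
as gaps — never interpolated.

Open choice: %Emax inside TI uses the fitted-curve maximal net value
(the span), matching the "maximum net BRET ratio" reading rather than
the raw per-experiment maximum; with noiseless data the two coincide.

## APEX spatiotemporal proteomics (`morpharm.apex`)

**Upstream boundary.** Feature-to-protein summarization is a documented,
deliberately simple stage (`summarize_features`: per-protein/sample sum
of feature intensities; proteins with fewer than two features dropped).
Raw spectral processing, library search and transition-level modelling
are out of scope; every statistical stage downstream of the protein
matrix is implemented in full.

**Time-course scoring.** Per protein, log2 intensity is modelled as a
cubic polynomial in the *rank* of the activation timepoint (ranks 1–5
for 0, 1, 5, 10, 30 min — ranks compress the long tail so the rapid
0→1 min changes are fit well) plus an additive batch offset, and
compared with a batch-only null by a nested-model F test:
`F = ((RSS_null − RSS_full)/Δdf)/(RSS_full/df_full)`.  The polynomial
basis is QR-orthogonalized over the rank grid for conditioning; fitted
values are basis-independent and the unit tests pin the F statistic to a
brute-force raw-basis oracle at 1e−10.  The maximum log2 fold change is
the largest-magnitude mean change between rank 1 and any later rank,
computed on observed values with missing cells imputed from the fitted
model (imputation respects each cell's batch).  The signed value is
reported; the interactor threshold (|log2FC| > log2 1.5 AND p ≤ 0.05)
uses the magnitude.  Signedness is configurable because the convention
is not fixed by the procedure itself.

**No multiple-testing correction is applied anywhere in this pipeline.**
The interactor and marker thresholds are raw per-protein thresholds by
design; users performing discovery-style inference on large matrices
should correct downstream.

**Marker selection.** Pairwise compartment contrasts use an
equal-variance t statistic whose pooled variance is the residual
variance of a one-way compartment model across *all* reference samples.
A protein enters the panel if some pair satisfies p < 0.005 and
|mean log2 difference| > 1.0, and its observed intensity exceeds the
global 50th percentile in every replicate of at least one reference.
The percentile universe is all non-missing observations across reference
and receptor samples (the procedure text does not fix the universe; this
choice is recorded).  It is computed on the log2 scale — the pass/fail
outcome is identical on any monotone scale.  Compartments with fewer
than two replicates are refused outright (no variance estimate).

**Deconvolution.** Linear-scale intensities are scaled to [0,1] per
protein (observed/row-max over references and receptor samples jointly;
missing → 0; zero-max rows dropped).  `F` holds per-compartment means of
scaled intensities; `S` restricts `F` to the marker panel.  Each
receptor sample is decomposed by nonnegative least squares over `S`
augmented with three dummy columns drawn i.i.d. uniformly with
replacement from the entries of `S` — the dummies absorb unstructured
background so true-zero coefficients stay at zero.  The randomization
and solve repeat 1,000 times (fresh dummies each repeat) and the
per-compartment median is reported; one child seed stream per sample
makes results independent of processing order.  An exact compartment
member solves with zero residual, so dummies receive nothing and the
0/1 indicator is recovered to solver precision.

## Fibre photometry (`morpharm.photometry`)

The dF/F definition is `(F − F0)/F0`; a literal parse of the commonly
printed one-line formula "(F − F0/F0)" is dimensionally inconsistent and
is not used.

Preprocessing low-passes both channels at 10 Hz (4th-order Butterworth,
forward–backward) and decimates 10×; it requires the input rate to be at
least 20× the cutoff and the cutoff to remain below the post-decimation
Nyquist.  F0 is a polynomial map (default degree 1, configurable) from
the isosbestic channel to the sensor signal, estimated on the declared
baseline window and applied to the whole isosbestic trace.  The
`baseline_als` mode first suppresses residual baseline-window peaks with
an asymmetric-least-squares floor estimate (Whittaker smoother with
asymmetric weights; `p = 0.5` gives the symmetric variant).  "Symmetric
least-squares filtering" has no single standard definition, so the
implemented variants are labelled and configurable; none is claimed to
match any particular lab's in-house code.

The per-animal transient threshold is `median + k·(1.4826·MAD)` of the
baseline dF/F with `k = 2.5` — about k robust standard deviations above
the median for Gaussian noise — set once on a baseline recording (≥60 s
required) and held constant across conditions.  Detection smooths the
trace with a zero-phase 1 Hz low-pass matched to the ~1 s transient
timescale (so sample-level noise does not register as prominent peaks),
then takes local maxima with prominence ≥ threshold.  Amplitude is the
prominence; duration is the full width at half prominence (the procedure
does not define "duration", so this choice is declared); frequency is
events per minute of the analysed trace, reported per bin.

The slow component is a 2nd-order zero-phase Butterworth low-pass at
0.1 Hz (order unstated in the source procedure; 2nd order is the
declared default) with trapezoidal AUC in 5-min bins measured from the
injection time; a trailing partial bin is flagged.  AUC is additive over
adjacent bins and linear in dF/F.

## Synthetic data (`morpharm.synthetic`)

One global integer seed drives a splittable per-family stream
(`SeedSequence(seed, spawn_key=(family_index,))`), so adding a generator
never perturbs another family's output and fixed seeds give
byte-identical tables.  With zero noise every generator satisfies its
generating equation at machine precision, and every dataset carries a
`GroundTruth` echoing the generating parameters verbatim.

Noise models: additive Gaussian on the measurement scale for BRET,
binding and photometry; additive Gaussian on the log2 scale for APEX
intensities (matching the scale on which they are analysed).  No assay's
noise distribution is stated in the source procedures, so these defaults
are declared, not inferred.  APEX mixtures are formed on the linear
intensity scale and then logged, because the deconvolution operates on
scaled linear intensities; missingness is missing-at-random (no
mechanism is stated).  Batch structure is two batches with additive
log2 offsets (0, 0.5).

Default conditions mirror the assay designs: 8–12 half-log agonist
dilutions with 3 replicates and a DAMGO reference plus ligand-free
wells; 23 kinetic timepoints (2–46 min step 2) with G-protein
efficacy trajectories relaxing from 120.8/123.2% toward 111.2/98.4% of
DAMGO; binding kinetics at `k_on = 7e8 /M/min`, `k_off = 0.075 /min`,
`L = 0.3 nM` over 0–120 min; four spatial compartments × 3 reference
replicates with +3 log2 marker enrichment, receptor samples at ranks
1–5 × 4 replicates, fast (surface→endosome) vs slow trafficking
trajectories, and 10 ramping "responder" proteins (+2 log2 by rank 5);
photometry at 250 Hz (no rate is stated for the source recordings;
250 Hz is chosen so the 10 Hz anti-alias + 10× decimation contract
holds with margin) for 600 s with five Gaussian transients of 6–9 a.u.
on a 100 a.u. baseline (amplitude-to-noise ≥ 12) and a shared
bleach/drift component scaled into the isosbestic channel.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: instrument artifacts (ion suppression, photon
shot statistics, detector saturation), heavy-tailed or
intensity-dependent proteomics noise, hemodynamic/motion artifacts that
differ between the 465 and 405 nm channels, inter-animal variability,
and receptor-reserve or kinetic-context effects that make real %Emax
trajectories non-exponential.  Recovery results on these simulations
demonstrate correctness of the estimators under their stated models, not
robustness to every failure mode of the instruments.

## Endpoint calculators (`morpharm.endpoints`)

All calculators are pure functions.  `%MPE = (measure − baseline)/
(max − baseline)·100` with the hot-plate cutoff (45 s in rats) as the
maximum; values above 100% are possible only when a measure exceeds the
stated maximum and are flagged.  ED50 fits dose vs mean %MPE with
asymptotes fixed at 0 and 100 (normalized response), leaving only the
ED50 free; dose units pass through.  For catalepsy scored on the 3–6
scale, `%MPE` uses baseline 3 and maximum 6.  SUV is `C/(dose/BW)` with
the conventional unit bookkeeping (kBq/ml, MBq, kg).

Withdrawal scoring: graded signs — jump attempts 1 point (1–4),
2 (5–10), 3 (>10); paw tremors 2 (1–2), 4 (≥3); wet dog shakes 1 (1–2),
2 (≥3); fecal deposits 1 each — plus fixed-weight checked signs
(salivation 7; posture, irritability, grooming 3; spasms, diarrhea,
ptosis, swallowing, chattering 2) and 1 point per gram of weight loss
(rounded to the nearest gram; fractional handling is unstated upstream).
The bracket boundaries at exactly 3 tremors/shakes and exactly 10 jumps
are unassigned by the verbal scheme; counts of 3 take the higher
bracket and exactly 10 jumps the 2-point bracket (literal ">10" for
3 points).  Per-rater totals are averaged, which by linearity equals
summing per-sign averages.

## Problem sizes and runtime

The statistical acceptance checks run at the sizes their properties are
stated at, chosen to complete in seconds on one CPU: 2,000 simulated
null proteins for the F-test type-I error (target band 3–7% at
α = 0.05); 100 random mixtures × 1,000 NNLS repeats on the
generator-built marker panel (~50 proteins — a reduced panel, as the
simulation has no need of 650 markers) for deconvolution RMSE; 200
seeded plates at 5% CV noise for pEC50 recovery; 50 seeded recordings
for transient sensitivity/precision.

## Known limitations

- Hill slope is fixed at 1; four/five-parameter logistics and
  operational-model (Black–Leff) fitting are out of scope.
- The APEX stage starts from a protein-level matrix; MSstats-style
  feature modelling, normalization and moderated tests are not
  reproduced.
- The exact 650-protein marker panel of the original dataset requires
  the deposited raw data and is not reproduced; panels here come from
  the synthetic references.
- Photometry assumes a single fluorophore per channel and no spectral
  unmixing; behavioural synchronization is out of scope.
- Group-comparison statistics (ANOVA, post-hoc tests) on behavioural
  endpoints are routine and intentionally excluded.
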