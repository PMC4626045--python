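# Methods

This note documents the models, estimators, defaults and numerical choices
behind `solnmr`, and what the synthetic-data generator does and does not
emulate.

## Relaxation fitting

Each residue's peak heights across relaxation delays are modeled as a
mono-exponential decay I(t) = A·exp(−t/T) with additive Gaussian noise.
The fit is unweighted nonlinear least squares (`scipy.optimize.curve_fit`,
bounds A > 0, T > 0). Initial guesses: A₀ = max height; T₀ = the first
delay at which the height falls below A₀/e, falling back to half the delay
span when the decay never crosses that level. Reported uncertainties are
the square roots of the covariance diagonal at the optimum, scaled by the
residual variance — i.e. the noise level is estimated from the fit itself.
A weighted option (`weighted=True`) uses the table's spectral-noise column
as an absolute per-point sigma instead; it is off by default because the
unweighted estimator is the plain reading of "least-squares fitting of peak
heights" and because per-point noise estimates are often unavailable.

A fit is declared failed (result absent, with a warning) rather than
returned when the solver does not converge or when the fitted T exceeds 50×
the sampled delay span — in that regime the experiment simply does not
constrain the decay and the covariance is meaningless. Fewer than three
points or all-equal heights raise typed errors.

Calibration: on synthetic decays at the default delay series with 2%
amplitude noise, the fitted T is unbiased well within 2% and the ±1-sd
interval covers truth at ≈0.65–0.68 over 200 replicates (the slight
undercoverage relative to the Gaussian 0.683 is the expected
estimated-variance effect at 7–9 points); the test suite asserts coverage
in [0.61, 0.75].

## Heteronuclear NOE

NOE = I_sat/I_unsat from one pair of spectra. Uncertainty propagates the
spectral noise of both spectra in first order:
sd = |NOE|·sqrt((n_sat/I_sat)² + (n_unsat/I_unsat)²), implemented in the
algebraically identical form sqrt((n_sat/I_unsat)² + (I_sat·n_unsat/I_unsat²)²)
so a vanishing saturated peak still yields a finite error. Residues with
NOE below `noe_floor` (default 0.65, a conventional rigidity threshold for
backbone amides at high field) are flagged flexible.

## Rotational correlation time and oligomeric state

tau_c = (1/(4π·nu_N))·sqrt(6·(T1/T2) − 7), nu_N = 0.10132912·nu_H. This
parenthesization is the one under which the canonical averages
(T1 = 750 ms, T2 = 70 ms at 600 MHz) give 9.9 ns; the formula is the
large-molecule (omega_N·tau_c ≫ 1) approximation and is undefined for
T1/T2 < 7/6 (a domain error; exactly 7/6 returns 0). Per-residue tau_c
errors propagate the T1/T2 fit sds in first order
(d tau_c/d r = 3·prefactor/sqrt(6r−7), r = T1/T2); the across-residue SD of
tau_c is reported separately and labeled as such, since the two error
notions differ.

The default field is 600 MHz, always overridable — relaxation data are
field-dependent and the acquiring field must be supplied when it differs.
The monomer verdict compares the mean tau_c against a user-supplied (low,
high) window in ns for the protein's mass; no tau_c-vs-mass empirical rule
is hard-coded, because any such rule embeds temperature and shape
assumptions the user is better placed to make. Without a window the
verdict is "not-assessed". Rates R1/R2 = 1/T are trivially available; the
package reports times in ms throughout.

## Chemical-shift perturbation

CSP = sqrt(0.5·(ddH² + (0.2·ddN)²)) ppm; the 0.2 weight maps the wider ¹⁵N
dispersion onto the ¹H scale. States are matched by residue number
(assigned lists), intersected; residues present in only one list are kept
in explicit `unmatched` sets — in slow exchange a disappearing peak is
itself information (exchange broadening), not a zero. Endpoint lists are
the unit of comparison; no fast-exchange trajectory fitting is attempted.

Significance default is the iteratively trimmed mean + 1 SD: the threshold
is recomputed excluding CSPs above the running threshold until the
excluded set stabilizes (≤ 10 rounds). This keeps large perturbations from
inflating the baseline and needs no tuned parameter; a fixed cutoff in ppm
is available instead. A residue is significant when its CSP reaches the
threshold and is nonzero (the nonzero guard makes the degenerate all-null
profile return an empty set rather than everything). Structure mapping
writes CSPs into the B-factor column (2 decimals, range ±999.99), with
−1.0 as the "no data" sentinel so viewers can gray those residues out.

## Ensemble statistics

Superposition is Kabsch: SVD of the cross-covariance of centered point
sets, with the reflection branch corrected by the determinant sign so the
returned rotation is always proper. Degenerate inputs (< 3 points or
collinear sets) are rejected. The mean structure is refined by exactly two
rounds of superposing all models onto the evolving mean (round 1 seeds with
model 1); on test ensembles the mean moves by far less than 1e-3 Å in a
third round, and a fixed count keeps the procedure deterministic.

"Backbone heavy atoms" is resolved as {N, CA, C, O}; the carbonyl O can be
dropped for the 3-atom convention. `all_heavy` excludes hydrogens by atom
name. The rmsd-to-mean statistic superposes each model onto the mean over
the same selection used for the rmsd, and reports mean ± SD (ddof = 1)
across models. The per-residue profile superposes globally under the same
atom policy, then aggregates each residue's squared deviations over models
and atoms; residues with no atoms under the policy are absent from the
profile, never reported as zero. Default command-line selection is the
ordered ranges 2–7, 21–135, 148–195 of the 196-residue default construct;
selections are always explicit configuration, never inferred from the
coordinates. Only the first chain is analyzed.

## Restraint bookkeeping

Separation bins use s = |i−j| (restraints are unordered pairs, so the
absolute value is the only sensible reading): intra s=0, sequential s=1,
medium 1<s≤5, long s>5 by default; the alternative common convention
(medium 2–4, long ≥5) sits behind `convention="narrow_medium"`. Duplicate
identical records are counted as written and logged. Per-residue averages
divide by the full construct length (default 196, always configurable):
total = (distance + phi + psi)/n_residues, long = n_long/n_residues. Note
that (3246 + 220)/196 = 17.68 prints as 17.7 at one decimal; the package
reports what it computes.

## Synthetic data

The generator emulates the acquisition design of a backbone study of a
196-residue, ~23 kDa protein at 600 MHz: nine T1 delays (10, 100, 200,
400, 600, 800, 1000, 1200, 1400 ms), seven T2 delays (10, 30, 50, 70, 90,
110, 150 ms), ground truth T1 = 750 ms, T2 = 70 ms, NOE 0.80 (0.40 inside
the flexible segments 8–20 and 133–153), additive Gaussian height noise of
2% of the amplitude. These defaults are the study conditions, not tuning
knobs. Amide baselines are drawn uniformly from ¹H 7–10 ppm / ¹⁵N 105–130
ppm; the holo list adds the injected perturbations and can drop residues to
emulate exchange-broadened disappearances. Ensembles are a smooth synthetic
backbone curve (N, CA, C, O per residue — plausible scale, not refined
stereochemistry) with per-residue isotropic Gaussian jitter (0.3 Å default,
1.2 Å in flexible segments) and a random rigid motion per conformer so that
downstream statistics must actually superpose. Restraint lists are sampled
with exact per-bin counts.

All randomness derives from one integer seed via independent
`numpy` Philox-family streams seeded `[seed, stream_index]`, one stream per
generator, so adding a generator call never perturbs another's output;
files are written with fixed number formatting, making same-seed outputs
byte-identical.

What the generator does **not** emulate: frequency-domain lineshapes, peak
overlap, chemical-shift prediction from structure, anisotropic diffusion,
exchange contributions to R2, or realistic restraint-network geometry.
Passing tests therefore demonstrate correctness of the estimators and
bookkeeping under the stated noise model — not robustness to spectral
artifacts, nor that a real ensemble's precision statistics would be
reproduced (those depend on the deposited experimental restraints, which
the pipeline reads but does not invent).

## Pipeline

`run_full` validates the flat config (all referenced inputs must exist; the
NOE table is the one tolerated absence, degrading the relaxation section to
T1/T2/tau_c with a warning and a `success-with-warnings` status), runs the
stages it has inputs for, and writes per-stage TSVs, `report.txt` and a
`summary.json` stamped `solnmr-summary/1`. A stage failure aborts with the
stage name and removes partial outputs. Outputs are deterministic given
inputs and seed (floats rounded to 6 decimals in the JSON summary). The
benchmark script uses 200 replicate series per experiment — large enough
for a stable mean (standard error ≈ 0.2%) while keeping the run quick.

## Known limitations

No model-free (Lipari–Szabo) analysis, diffusion-tensor anisotropy, or CPMG
dispersion; tau_c assumes isotropic tumbling. CSP analysis does not
estimate binding constants. Only the PDB coordinate format is read
(mmCIF is out of scope), and NMR-STAR support is limited to the
assigned-chemical-shift loop via a deliberate whitelist tokenizer.
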