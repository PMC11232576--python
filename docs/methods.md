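# Methods

## The modeling problem

A stable-isotope labeling kinetics (SILK) experiment infuses
\(^{13}\mathrm{C}_6\)-leucine intravenously — a 10 min bolus at 2 mg/kg
followed by an 8 h 50 infusion at 2 mg/kg/h, 9 h of label in total — and
collects blood plasma and ventricular CSF roughly every 3 h for 36.2 h
(13 time points). For each peptide the mass spectrometer reports a light
intensity \(I_0\) and a heavy (+6 Da per labeled leucine) intensity
\(I_6\); the observable is the relative isotope abundance

\[ \mathrm{RIA} = \frac{I_6}{I_0 + I_6} \Big/ n_{\mathrm{Leu}}, \]

divided by the peptide's leucine count to compensate for the higher
labeling probability of multi-leucine peptides (multiply-labeled species
are ignored). An *observation* is one peptide in one chromatographic
fraction at one charge state, followed over the 13 time points.

The RIA time course in a fluid reflects synthesis, clearance and
transport between compartments. Because the CNS cannot be sampled in
vivo, its contribution to CSF dynamics is modeled as a hidden compartment.

## Compartment models

All variants are linear first-order systems driven by a normalized
piecewise-constant input \(u(t)\) (bolus level 6, infusion level 1, zero
after 9 h; a single-level 9 h step is available as a simplification).
A tracer-availability compartment low-pass filters the input:

\[ g' = k_g\,(u(t) - g), \qquad g(0)=0 . \]

\(k_g\) represents the kinetics of the precursor pool actually feeding
protein synthesis (intracellular free leucine, aminoacyl-tRNA and
secretory transit). It is a property of the tracer and subject, not of a
protein, so it is a fixed model constant carried by the protocol object
(default **0.15/h**, configurable). The default is chosen so that the
availability tail extends past the label window, which is required for
slow-turnover proteins whose RIA is still rising at 30 h, while fast CSF
dynamics remain representable. Fitting it per protein is not possible:
the variant parameter counts (13 for the full model, 10 for the
simplified one, both including the two per-fluid shifts) leave no free
slot for it.

The variants (states beyond \(g\); all rates first-order, 1/h):

- **single** — one fluid: \(r' = a g - b r\). \(a\) scales the curve,
  \(b\) (clearance) shapes it and sets the half-life.
- **two_bc** — plasma \(p\) and CSF \(f\) with linear transfers
  \(k_{pf}, k_{fp}\) (the classical pharmacokinetic two-compartment
  template; the peripheral compartment has no elimination of its own,
  though a `csf_elimination` field is available and defaults to 0).
- **two_bc_delay** — as two_bc, but the CSF inflow uses
  \(p(t-\tau)\) with zero history; solved by the method of steps.
- **three_bc_full** — plasma, hidden CNS \(c\), CSF; synthesis into
  plasma (\(a_p\)) and CNS (\(a_c\)) from \(g\), eliminations
  \(b_p, b_c, e_f\), and all six pairwise transfers. 13 parameters with
  the two shifts.
- **three_bc_simplified** — sets \(k_{cp} = k_{pc} = e_f = 0\): CNS
  exports to plasma are regarded as already integrated in the plasma
  data, the plasma→CNS→CSF route as negligible, and there is no CSF in
  situ degradation. 10 parameters. The three removed rates are mutually
  redundant with the remaining CSF outflows, which is what makes the
  full model ill-posed (see below).

Observed RIAs carry a small additive per-fluid vertical shift \(s\)
(a consequence of noise and the large \(I_0/I_6\) ratio), estimated
jointly with the rates.

### Numerics

`integrate()` solves each variant with the implicit stiff Runge–Kutta
scheme Radau (SciPy), split at the input breakpoints, with default
tolerances rtol = 1e-8 / atol = 1e-10. Because the systems are linear
with piecewise-constant input, an exact propagator (`method="expm"`,
eigendecomposition with an augmented-matrix-exponential fallback and a
defectiveness check) is also provided; the two routes agree to ~1e-10
over the full parameter bounds and the exact route is used inside
fitting and MCMC loops. The delay variant is integrated by the method of
steps with dense output carrying the history; delays below 1e-3 h are
treated as zero. Rates are bounded to [0, 10]/h and shifts to
[−0.05, 0.05] during fitting (generous for hour-scale kinetics;
configurable).

## Point estimation

The objective is a weighted sum of squared errors,
\(\sum_i w_i\,(r(t_i) - (\mathrm{RIA}_i - s))^2\) with
\(w_i = I_{0,i}/\overline{I_0}\) per fluid (stronger light signals are
more accurate; normalization keeps the objective scale comparable across
observations). Minimization uses bound-constrained quasi-Newton
(L-BFGS-B); joint models are optimized on the log scale of the rates
(effective floor 1e-4/h), which conditions the strongly anisotropic
objective far better, and near-tied multistart results (within 5%) are
resolved in favor of the earliest start so that estimates are
reproducible on flat ridges.

Robustness: a first fit on all points flags as outliers every point
whose shift-corrected distance to the curve exceeds half the curve's
dynamic range, plus every t = 0 point (no tracer incorporated yet, and
t = 0 RIAs are unusable for shift estimation); a second fit excludes
them. Joint (two-fluid) models are seeded from the per-fluid single-fluid
estimates (plasma block from the plasma fit, CNS block from the CSF fit,
transfers swept over a 5-point multistart) and fitted on the points
retained by the per-fluid screens — joint variants never re-flag data,
so competing models are always compared on the same point set.

Confidence intervals come from a percentile bootstrap (default 1,000
replicates) over the retained points, resampled with replacement within
each fluid, each replicate refitted from the point estimate; results are
flagged when more than 20% of refits fail. A simulation study in the
test-suite measures ~89% empirical coverage of the 95% intervals for the
clearance rate at the default design — the usual mild anti-conservatism
of the percentile method at 12 usable points per observation.

Protein-level pooling: shared (non-unique) peptides are dropped; with at
least three observations, per-observation clearance estimates outside the
Tukey fences (quartiles ± 1.5 IQR) are discarded; remaining observations
are aligned by an additive offset (difference of median RIA over shared
time points) onto the observation with the highest median heavy signal;
the pooled data are refitted and bootstrapped.

### Identifiability

The simplified model is *sloppy*: plasma and CSF data identify the
plasma block, the plasma→CSF route and a handful of CSF-outflow and
CNS-block combinations, but not all eight rates individually (the hidden
CNS curve is itself a filtered copy of \(g\) and can trade off against
the direct plasma route). Point estimates therefore wander along
near-flat ridges — the median relative rate error over the default
synthetic design is ~0.6 — which is precisely why the Bayesian
formulation below, with informative priors, is the estimator of record
for the joint models. The model *curves* remain well determined, and the
curve-level checks (model comparison, credibility bands) are stable.

## Bayesian estimation

Likelihood: independent normal errors with per-fluid precision scaled by
the point weight, \( \mathrm{RIA}_i \sim \mathcal N(r(t_i) + s_{\mathrm{fluid}},\,
(\tau_{\mathrm{fluid}} w_i)^{-1}) \). Priors: normal on log-rates
(precision 10), normal on shifts (mean 0, precision 5,000), vague
Gamma(0.001, 0.001) on the error precisions. Prior means for the log
rates come from the per-fluid single-fluid fits — plasma synthesis and
elimination from the plasma fit, CNS synthesis and elimination from the
CSF fit (the CSF curve is the observable shadow of the CNS compartment) —
and transfer rates (and the full-model extras) default to log(0.1),
configurable.

Sampling uses the affine-invariant ensemble sampler (emcee); two
independent ensembles play the role of two chains. `n_iter`/`n_burn`
count total posterior evaluations (defaults 200,000 / 100,000) and are
divided over the walkers internally. Rates start from prior draws,
shifts from the per-fluid quasi-Newton estimates. Convergence is
diagnosed per parameter with split-\(\hat R\) comparing within- and
between-chain variability; results with \(\hat R > 1.1\) are flagged
non-converged (samples still returned). Posterior summaries report
mean, median, CI95 and the relative CI95 (interval range divided by the
estimate).

`posterior_curves` integrates 500 evenly spaced posterior draws to
pointwise 2.5/50/97.5% bands per compartment and compares the
mean-parameter trajectory with the pointwise-median curve: a
mean-parameter curve leaving the interquartile band is the signature of
a multimodal posterior (the parameter mean falls between modes and fits
nothing). `detect_multimodality` evaluates 2-D kernel densities over
pairs of rates and flags more than one local maximum above 10% of the
peak; on faster-CSF synthetic data the full model's redundant trio
(\(e_f, k_{fp}, k_{fc}\)) is flagged multimodal while the simplified
model's remaining pair is unimodal — the in-silico reproduction of the
full-model failure and the rationale for preferring the simplified model.

## QC pipeline

`run_pipeline` reproduces the processing funnel: parse the Skyline
peak-intensity export (configurable column map; light/heavy rows paired
per peptide × fraction × charge × time; a heavy row without a light
partner yields a missing-\(I_0\) point); drop peptides without leucine;
require detection at ≥ 9 of the 13 time points above a configurable
intensity floor (0 = off; no published value exists); screen each
observation with a robust single-fluid fit — rejecting fits with a rate
at the upper bound or a dynamic range below twice the shift, more than
25% outliers (assumed threshold; none is published), Spearman
correlation < 0.75 between retained points and the model, model curves
outside a LOESS (span 0.75) 95% envelope more than 25% of a 0.5 h grid,
or fewer than two retained points before 10 h / after 20 h — then pool
per protein and bootstrap. Two operationalizations differ deliberately
from the obvious reading: only the *upper* rate bound marks an aberrant
fit (a clearance pinned at 0 is the legitimate slow-turnover limit), and
the LOESS band is floored at 10% of the curve's dynamic range so that
the envelope rule targets gross shape violations rather than the LOESS
smoothing bias or the structural gap between the single-fluid screen and
truly multi-compartment dynamics. Every rejection carries a
machine-readable reason; per-stage counts are monotone and fully
accounted. Proteins with ≥ 4 validated observations in each fluid are
joint-model eligible.

## Synthetic data

`SyntheticDesign` defaults encode the study conditions: 13 points every
~3 h over 36.2 h, 4 observations per protein per fluid, leucine counts
drawn from {1, 2, 3} with probabilities (0.5, 0.3, 0.2), \(I_0\)
log-normal (median 1e5, σ = 1), per-fluid shifts (+0.002 plasma, −0.002
CSF) plus a per-observation offset (σ = 0.002, the alignment problem),
heteroscedastic normal RIA noise with precision 2.5e5 scaled by the
point weight (≈ 0.002 RIA at the median intensity, matching the scatter
of the published curves), 5% outlier contamination (spikes 0.5–2 curve
ranges off the curve, guaranteed to trip the half-range rule) and 5%
missing points. Heavy intensities are derived from the target RIA and
the drawn \(I_0\) (\(I_6 = \rho I_0/(1-\rho)\), \(\rho\) the raw heavy
fraction clipped to [0, 0.9]), keeping light/heavy ratios realistic;
infeasible targets are clipped. t = 0 points carry noise only.

Three archetype rate sets reproduce the canonical patterns of
simultaneously observed dynamics: similar dynamics in both fluids;
faster and higher CSF (a TTR-like protein: plasma half-life of days, CSF
peaking high near 14 h through a strong CNS route); and faster plasma
(APOH-like). They were calibrated against those qualitative patterns —
peak RIAs in the observed 0.02–0.14 range, correct ordering of
single-fluid clearance estimates — and then frozen. Cohort generation can
plant labeled QC defects (leucine-free peptides, 8-of-13 coverage,
V-shaped RIA series) whose expected rejection stage is recorded in the
truth table.

What the generator does *not* emulate: correlated noise across time
points or peptides, chromatographic intensity drift, isotope-pattern
interference, shared-peptide ambiguity beyond a boolean flag, or
multiply-labeled species. Passing tests therefore demonstrate
correctness of the algorithms under the stated error model, not
robustness to every artifact of real LC-MS data.

## Problem sizes in the test-suite and acceptance script

The replication experiments use 100 seeded replicates for frequentist
recovery, 50 replicates at 20,000/10,000 MCMC evaluations (a tenth of
the full-scale defaults) for interval calibration, 120 replicates × 300
bootstrap draws for bootstrap coverage, and single seeded datasets for
the model-comparison and multimodality contrasts — sizes chosen so the
full validation story recomputes from scratch in well under half an hour
on one core while keeping Monte-Carlo error small relative to the bands
being checked.

## Known limitations

- Individual rates of the simplified model are not identifiable from
  two observed fluids; only the Bayesian posterior (prior-regularized)
  should be used for rate-level statements, and CNS-related rates remain
  prior-sensitive for proteins whose CSF dynamics need no CNS input.
- The precursor-availability rate \(k_g\) is a fixed constant shared by
  all proteins; misspecifying it biases synthesis-scale estimates
  (amplitude and availability trade off exactly at the curve level).
- The percentile bootstrap is mildly anti-conservative at 12–13 points.
- The LOESS envelope uses a global residual SD with a normal
  approximation, not a local variance estimate.
- Population-level (multi-subject) modeling is out of scope.
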