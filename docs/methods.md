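# Methods

## Structural model

Drug input is a constant-rate intravenous infusion into a central
compartment (volume `V1`, L); drug distributes to a peripheral compartment
(`V2`, L) with inter-compartmental clearance `Q` (L/h) and is eliminated
from the central compartment with total clearance `CL_total` (L/h).
Concentrations are total plasma doripenem; with doses in mg and volumes in
L, mg/L ≡ µg/mL.

The closed-form solution is used everywhere performance matters. With
`k10 = CL/V1`, `k12 = Q/V1`, `k21 = Q/V2`, the macro exponents α > β > 0 are
the roots of `s² − (k10+k12+k21)s + k10·k21`. For one infusion of rate `R`
and duration `T`,

```
C(t) = (R/V1) · [ A·(e^{−α·max(t−T,0)} − e^{−αt})/α
                + B·(e^{−β·max(t−T,0)} − e^{−βt})/β ],
A = (α−k21)/(α−β),  B = (k21−β)/(α−β),
```

and regimens are superposed dose by dose, so overlapping and irregular
infusions need no special casing. A stiff-capable numerical integration of
the compartmental ODEs (with a third state accumulating eliminated mass so
conservation can be audited) is kept solely as an independent oracle; the
two paths agree to better than 1e−6 relative in randomized tests. The
discriminant is clamped at 1e−30 before the square root: it is positive for
all positive parameters, but extreme optimizer trial points can cancel
catastrophically.

## Population model

Fixed effects follow the published final model: body clearance is a power
function of creatinine clearance normalized to the group median, estimated
separately for CRRT and non-CRRT patients, and CRRT patients additionally
clear drug extracorporeally at `fu·Q_E` with the unbound fraction
`fu = 0.919` fixed. The machine clearance carries no random effect and no
covariate (an albumin effect on it was rejected at backward elimination in
the source analysis). Inter-individual variability is exponential
(`parameter = typical · e^η`, η ~ N(0, ω²)); each subject realizes only the
clearance η of their own CRRT group. ω is interpreted as the SD of η, with
"%IIV" reported as 100·ω — the standard pharmacometric convention; the
alternative `ln(1+CV²)` transform differs by <1% at these magnitudes.
Residual error is additive on the natural-log concentration scale
(`ln C_obs = ln C_pred + ε`, ε ~ N(0, σ²)) with σ = 0.365.

The published constants are frozen in `PUBLISHED_FINAL_MODEL`; fitted
models report the same quantities with covariate references re-medianed to
the data at hand (the references used are always recorded in the fit, and
can be pinned explicitly, which recovery experiments do).

## Estimation (FOCE-I)

The marginal likelihood of each subject integrates the Gaussian residual
density over the random effects. It is approximated by a Laplacian
expansion at the conditional mode η̂ (the empirical Bayes estimate) with
the Gauss–Newton Hessian `H = J'J/σ² + Ω⁻¹`, where `J = ∂ln f/∂η`:

```
OFV_i = Σ_j [ r_ij²/σ² + ln 2πσ² ] + η̂'Ω⁻¹η̂ + ln det 2πΩ
      + ln det H_i − d_i ln 2π,            r_ij = ln DV_ij − ln f_ij(η̂).
```

Because the residual model is additive on the log scale with constant σ,
the residual variance does not depend on η and the FOCE "interaction" term
is included trivially. Random-effect dimensions with ω = 0 are excluded
from the integral (as the limit demands), so the all-ω-zero case reduces
exactly to the fixed-effect Gaussian −2 log likelihood.

Numerical choices:

- **Inner problem** (per-subject mode search): damped Newton with the
  Gauss–Newton Hessian, batched across all subjects with numpy; Jacobians
  by central differences (step 1e−4) evaluated in a single stacked kinetics
  call; convergence at max |gradient| < 1e−5, cap 60 iterations; step
  clamped to ±5 with per-subject backtracking, and non-finite trial
  objectives treated as failed steps. Modes are warm-started from the
  previous outer iterate.
- **Outer problem**: L-BFGS-B on log-transformed positive parameters
  (typical values, ωs, σ; covariate exponents untransformed), with
  finite-difference gradients (step 1e−5) and box bounds that keep trial
  points physiologic (typical values in [1e−3, 1e4], ω and σ in
  [1e−3, 3], exponents in [−5, 5]).
- **AIC** = OFV + 2p with p the number of actually estimated parameters
  (fixed quantities such as fu, or anything passed as `fixed=`, excluded).
- Below-LOQ observations are excluded from the likelihood (the package's
  default LOQ policy); the pre-dose sample is structurally zero under the
  model and is likewise excluded.

The independent **quadrature oracle** computes −2 log marginal likelihood
by adaptive Gauss–Hermite quadrature (31 nodes per dimension, tensorized,
centered and scaled at a mode found by a separate BFGS search on the scalar
public model path). It shares no code with the vectorized FOCE-I machinery
and is practical for up to 3 active η dimensions per subject; FOCE-I agrees
with it within 1.0 OFV units on small datasets, the tolerance used in
tests.

Diagnostics follow the standard definitions: PRED (η = 0), IPRED (at the
EBE), iWRES = (ln DV − ln IPRED)/σ, and CWRES from the FOCE linearization,
`V^{−1/2}[ln DV − ln f(η̂) + Jη̂]` with `V = JΩJ' + σ²I`. η-shrinkage is
`100·(1 − SD(EBE)/ω)` per dimension (clearance split by CRRT group) and
ε-shrinkage `100·(1 − SD(iWRES))`; dimensions with ω = 0 report NaN.

## Covariate selection

Candidates are power-form effects `(x/median)^θ` on structural parameters.
Screening keeps candidates whose covariate correlates with the EBE-based
individual parameter (|r| > 0.6, Pearson) and drops the weaker of any
covariate pair correlated above the same cutoff (collinearity). Forward
addition tests each screened candidate one at a time against the base model
with a single shared exponent (one degree of freedom; for body clearance
the covariate is re-medianed per CRRT group), accepting at ΔOFV > 2.71.
All passers are pooled; where several passers target the same parameter the
largest OFV drop takes the slot — this is what the source analysis's full
model implies, since a weaker clearance covariate that passed its marginal
test did not enter. Backward elimination then removes, iteratively, the
least significant effect whose deletion costs ≤ 3.84 OFV. The full
published decision table is shipped as a constant so the rules can be
replayed against the printed ΔOFV values.

The type-I calibration of the forward rule (≈10% at the 2.71 threshold)
is verified on null cohorts of 21 non-CRRT subjects with the structural
parameters pinned at their generating values, so each replicate estimates
only clearance, its variability, residual SD, and the candidate exponent —
a design chosen because the likelihood-ratio null distribution is the same
while 400 replicate fits stay cheap; at much smaller cohorts the χ²(1)
asymptotics are visibly anticonservative.

## Validation

The bootstrap resamples subjects with replacement to the original count,
refits (warm-started from the original estimates, with covariate references
held at the original medians so replicates stay comparable), and summarizes
converged replicates by median and 2.5/97.5 percentiles; replicates that
fail outright are dropped and counted. The VPC simulates replicate datasets
under the model with the original design — same doses, sampling times and
covariates — including both η and ε, bins at the exact nominal times (the
design is fixed, so no smoothing), and overlays observed 5th/50th/95th
percentiles on the 95% band of the same percentiles across replicates;
pooled and CRRT-stratified outputs are both available.

## PTA simulation

Virtual patients are drawn per condition: Ccr uniform within the
renal-function stratum and, when CRRT is on, Q_E uniform on 0.6–1.8 L/h —
the study's stated range; neither within-stratum distribution is published,
so uniform is the assumption and it is recorded in the report metadata.
η draws use the published ωs; residual (assay) error is excluded because
the targets concern true concentrations. Dosing is simulated for 48 h
(≥10 terminal half-lives, t½β ≈ 4.3 h, so steady state is guaranteed) and
targets are evaluated on the 40–48 h window on a 0.05-h grid with
fu = 0.919 and MIC = 2 µg/mL. The three targets are 40% fT>MIC, 100%
fT>MIC, and 100% fT>4×MIC; "100%" requires every grid point above
threshold. Within a (stratum, CRRT) condition the same virtual subjects are
reused across modes and doses — kinetics are linear, so dose scaling is
exact — which makes dose monotonicity, target nesting and mode dominance
hold cell-wise rather than only up to Monte Carlo noise. The default 4000
subjects per condition gives cell-level Monte Carlo noise under 2
percentage points.

## Synthetic cohorts

The generator emulates the study design: 21 subjects (9 CRRT), one 1-h
infusion of 500 mg (one randomly chosen non-CRRT subject receives 250 mg),
sampling pre-dose and at 1, 2, 4, 6, 8 h, LOQ 0.5 µg/mL. Covariates are
truncated normals ([1st, 99th] percentiles, floored at Ccr ≥ 5 mL/min and
BW ≥ 30 kg) with the reported means/SDs; Q_E is uniform on 0.6–1.8 L/h.
Serum albumin was not reported by the study, so its distribution
(2.8 ± 0.6 g/dL, a typical ICU range) is a synthetic stand-in — any
albumin-related result is qualitative only. Observation slots are dropped
uniformly at random (default rate 0.23, making the expected retained count
match the study's 97 samples out of 126 slots), with at least one post-dose
sample always kept per subject. A pure-noise covariate generator (same
location and spread as Ccr, independent of everything) provides the type-I
calibration probe.

What the generator does *not* emulate: within-subject covariate or Q_E
changes, CRRT circuit downtime, informative missingness, assay
heteroscedasticity beyond the log-additive model, and whatever unreported
structure the real albumin distribution has. Passing tests therefore
demonstrate correctness of the machinery under the stated design, not
agreement with the unreleased patient-level data.

## Problem sizes and known limitations

Test and acceptance runs use desk-scale sizes chosen as the package's own
defaults: 4000 virtual subjects per PTA condition, 200 bootstrap and VPC
replicates, 200 type-I replicates, and a 210-subject (design ×10) recovery
experiment.

Two reproduction limits are worth stating plainly. First, under the sparse
study design (≤5 post-dose samples, 36.5% residual CV) the peripheral
parameters V2 and Q are weakly identified: single-dataset maximum-likelihood
estimates of Q scatter with ≈19% SD even at 210 subjects, so a fixed-seed
requirement that *every* fixed effect land within 15% of truth fails for
some parameter on most seeds, and at the original 21-subject size the
likelihood can prefer degenerate large-V2 ridges — the same flatness the
source analysis's own wide bootstrap intervals reflect. Second, several
printed mid-range PTA cells imply a heavier clearance tail than the
published %IIV values produce under the ω-as-SD convention; those cells are
reproducible only approximately, while the saturated (100.0) cells and the
40% fT>MIC ≥ 90% floor reproduce exactly.
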