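# Methods

This package implements the chemometric pipeline used to calibrate
Raman spectra of reconstituted (aqueous) infant formula against
element concentrations measured by an ICP-AES reference method:
baseline correction, PLS1 regression, venetian-blinds
cross-validation, informative-variable selection, the reference
method's own arithmetic, and a synthetic spectrum generator that
emulates the study design so the whole pipeline is exercisable with
known ground truth.

## Baseline correction

Raman spectra of dairy matrices ride on a fluorescence background far
larger than the chemical bands.  Both penalized-least-squares
corrections share a Whittaker smoother core: given weights `w` and a
penalty `lambda`, the baseline `z` minimizes

    sum_i w_i (y_i - z_i)^2 + lambda * sum_i (Delta^2 z)_i^2

solved through the banded normal equations `(W + lambda D'D) z = W y`
(O(n) per solve; `D` is the second-difference operator, order
configurable).  The null space of the penalty is the affine functions,
so as `lambda -> inf` the smooth tends to the weighted straight-line
fit — a property the tests use as an oracle.

* **AsLS** re-weights iteratively: `w_i = p` above the running
  baseline, `1 - p` below, from `w = 1`, until the weight pattern is
  stationary or `max_iter` is reached.  Defaults `lambda = 1e5`,
  `p = 0.01`, `max_iter = 50` are the standard literature values; the
  source study names the method without parameters.
* **airPLS** sets `w_i = 0` at or above the baseline and
  `w_i = exp(t |d_i| / |d^-|)` below it (`t` the iteration index,
  `|d^-|` the L1 norm of negative residuals), stopping when
  `|d^-| < tol * |y|_1`.  Defaults `lambda = 1e5`, `max_iter = 30`,
  `tol = 1e-3`.
* **BOC** (baseline offset correction) subtracts the per-spectrum
  minimum; a reference-window mean is available as a config option
  since the term is not defined more precisely in the field.
* **S.G. first derivative** uses a 7-point window and degree-2
  polynomial, returned per channel index (`delta = 1`): after mean
  centering inside the regression a global axis scale cancels, and the
  nominal spacing of the instrument axis is ambiguous (see *Axis
  handling*).  Edges use the polynomial of the terminal fit window.
  A non-uniform axis (relative spacing deviation above 1e-6) is
  rejected for this method only.

Every baseline method returns `(baseline, corrected)` with
`corrected == input - baseline` bit-exactly; the re-summed
`baseline + corrected` can differ from the input in the last ulp, as
any floating-point split must.

## PLS1 by NIPALS

Predictors are mean-centered only (no unit-variance scaling: all
channels share cps units, and the study describes none).  Per
component: `w = X'y/||X'y||`, `t = Xw`, `p = X't/(t't)`,
`q = y't/(t't)`, then deflation `X <- X - tp'`, `y <- y - qt`.
Regression vectors `B_a = W_a (P_a' W_a)^{-1} q_a` are accumulated for
every component count via the R-basis recursion.  Exactly rank-
deficient inputs truncate the model at the attainable rank rather than
erroring.  Scores are mutually orthogonal to 1e-8 relative; the suite
cross-checks the coefficients against an independent Krylov-space
characterization of PLS1 and against scikit-learn.

**Venetian-blinds cross-validation** assigns sample `i` (dataset
order) to fold `i mod s`, `s = 10` by default (the study does not
state its split count; 10 is the common chemometric choice).  Fold
models recompute centering on their own training rows, so held-out
samples never influence any statistic.  The component count is the
smallest `a` with `RMSECV(a) <= 1.02 * min_a RMSECV` (2% parsimony
tolerance, favouring the small models the study argues for); any `A`
can be forced per model.

Reported metrics mirror the usual table layout: `R2C/RMSEC` on
calibration fits, `R2CV/RMSECV/bias` from out-of-fold predictions,
`R2P/RMSEP/bias` on an external validation set.  `bias` is the mean
signed error; `bias^2 <= RMSE^2` always.

## Variable selection

* **VIP**: `VIP_j = sqrt(J * sum_k ssy_k (w_jk/||w_k||)^2 /
  sum_k ssy_k)` with `ssy_k = q_k^2 t_k't_k`; `mean(VIP^2) = 1` by
  construction, and the default threshold 1.0 keeps channels with
  above-average influence (the study reports selected counts but no
  cutoff).
* **sMC** regresses each centered channel on the fitted response and
  compares `F_j = SS_reg / (SS_res/(n-2))` with the `F(1, n-2)`
  critical value; a channel exactly proportional to the fit (zero
  residual) is capped at a large finite score and flagged.
* **Martens' uncertainty test** refits the regression vector with each
  CV segment left out and forms a per-channel jackknife variance
  `(M-1)/M * sum_m (b_j^(m) - b_j_bar)^2` centered on the segment
  mean; `|b_j|/se_j` is compared with the two-sided Student-t critical
  value at `M-1` degrees of freedom.  Centering on the full-data
  coefficient instead (a common description of the method) adds the
  `(b_bar - b)^2` bias term and makes the test markedly conservative:
  measured type-I rates on pure noise are ~1.4% at alpha = 5%, versus
  ~5.1% for the classical centering used here.  Channels with zero
  jackknife variance are significant iff their coefficient is nonzero.

Both significance tests hold their nominal type-I rate within about a
point on pure-noise simulations (n = 60, J = 200); sMC runs slightly
hot (~6.6%) because each channel participates in building the fitted
response it is tested against.  Selection is one-pass: select once on
the full-variable model, refit and re-cross-validate on the retained
channels; no iterative elimination.

## Calibration/validation split

The "quasi-random" split is implemented as seeded rank-stratified
alternation: samples are ranked by the response, the global minimum
and maximum are forced into calibration (so validation never
extrapolates), and remaining ranks alternate between the sets with
seeded jitter until the sizes are `(n_cal, n - n_cal)`.  Deterministic
given the seed.  Because it is rank-based, the assignment depends on
the response only through its ordering — the leakage tests exploit
this by perturbing validation responses rank-preservingly.

Outlier exclusion is an explicit id list in the pipeline config, never
automatic (the study removed a single anomalous K sample by
inspection).

## Reference-method arithmetic

Standard curves are ordinary least-squares lines through a blank and
multi-element standards (nominally 12.5/25/50 ppm for the abundant
elements, 1.25/2.5/5 ppm for trace elements).  Two acceptance gates
reject a curve: coefficient of determination r^2 <= 0.995, or any
non-blank standard back-predicting more than 10% (relative) from
nominal — the "maximum error" gate is not defined precisely in the
field description, so the maximum relative back-prediction error over
non-blank standards is used and documented.  Quantification is
`dilution_factor * (response - intercept)/slope` (digests of abundant
elements are diluted 1:10 v/v before measurement).  Repeatability is
the pooled within-sample standard deviation of replicates (the ISO
`r = 2.8 * SD` limit is available behind a flag); percent recovery is
`100 * measured / certified` against a certified milk-powder
reference.  Below-detection values (negative concentrations) are
passed through and flagged, never censored.

## Synthetic data generator

The generator emulates the study design: 19 formula powders, 15 of
them reconstituted at 3/5/8/10/13% w/w (75 samples), the remaining
formulas contributing single high-level samples plus one mid-level
sample, for 83 samples total, each scanned twice.  Scans follow

    scan = gain * (C @ S) + baseline + noise

* **Component spectra** `S` are sums of Gaussian/Lorentzian bands at
  the dairy Raman assignments: lactose glycosidic bands
  (355/445/850/877/950/1070/1121 cm^-1), protein bands (phenylalanine
  ring breathing at 1003, amide II/I at 1555/1660, N-H at 3060), lipid
  CH bands (1262/1303/1442/1746/2855/2927/3005), and broad water
  structure (~170 and 3200-3400 cm^-1).  Band amplitudes carry a small
  seeded lognormal jitter.
* **Minerals** never appear as element-specific sharp lines — free
  ions are weak Raman scatterers.  Each element instead modulates
  matrix-like bands concentrated at 170-220 cm^-1 (chelated backbones)
  and 760-1665 cm^-1 (protein-bound structure), with amplitude
  proportional to its concentration.  The visibility preset is
  expressed as peak cps at the element's maximum concentration
  (strong = 300, weak = 12), so elements spanning very different ppm
  scales reach comparable spectral visibility when their complexes
  scatter comparably; Cu uses the weak preset and is by design the
  hard case, mirroring its poor calibration in practice.  Mn is
  generated as detection-limit noise around zero and excluded from
  modeling, leaving 7 usable elements.
* **Concentrations** are exactly proportional to powder level within a
  formula (`ppm = formula density x level`).  Per-formula densities
  are drawn stratified-uniform over the range implied by the reference
  measurements (minimum at 3% w/w to maximum at 13% w/w), so every
  seed spans the full printed concentration range.  The reference
  table carries these true values; per-element repeatability figures
  are attached as metadata.
* **Nuisance structure**: a fluorescence baseline
  `amp * exp(-(shift-lo)/decay) + tilt` with amplitude (lognormal,
  CV 0.4), decay (CV 0.3) and tilt drawn per scan; a per-scan
  multiplicative gain (SD 3%); and Gaussian noise whose SD (4 cps at
  the base) inflates linearly up to 4-fold between 1800 cm^-1 and the
  end of the axis, mimicking the detector's high-shift noise growth.
* **Axis handling**: the default axis is 50-3398 cm^-1 with 3473
  channels (~0.964 cm^-1 spacing), consistent with the largest
  spectral-variable counts the study tables report; the instrument
  section instead quotes 2 cm^-1 increments, so the package treats the
  axis as data everywhere and never assumes a spacing (spacing is
  configurable, and coarser axes are used in the cheaper tests).

Chloride-salt control spectra (the eight 1 M solutions) are water
background plus salt-specific low-frequency bands in 50-465 cm^-1 with
the same high-shift noise inflation; pairwise differences concentrate
below 465 cm^-1 as in the laboratory control experiment.

What the generator does **not** emulate: cosmic spikes (removed by
vendor software upstream), instrument drift between sessions,
nonlinear detector response, water-band temperature shifts, and any
mineral-matrix interaction beyond linear modulation.  Passing
recovery tests therefore demonstrate that the pipeline is correct and
well-calibrated on bilinear-plus-nuisance data of realistic scale —
not that laboratory spectra of this matrix are themselves bilinear.

## Problem sizes and numerics

The recovery experiments use the full 83-sample, 3473-channel design
with up to 6 latent variables and 10 venetian blinds — the study's
own scale, which runs in seconds.  Type-I calibrations use n = 60,
J = 200 over 50 seeds.  Banded Cholesky solves back the Whittaker
smoother (gram matrices cached per length/order); zero-penalty or
all-zero-weight systems are rejected explicitly.  Ties in the
best-model marking break toward fewer latent variables.  All
randomness flows through `numpy.random.default_rng` seeds; same seed,
same bytes.

## Known limitations

* The sMC test's mild anti-conservatism is inherent to testing
  channels against a fitted response built from them; at J >> n it is
  small but visible.
* The AsLS envelope sits slightly below true baselines under dense
  peaks (asymmetry bias ~1% of range with the defaults).
* `chosen_A` by the 2% parsimony rule can differ from what a human
  would pick off an RMSECV elbow; force `A` per model to reproduce a
  specific table row.
* The CLI serializes spectra as CSV only; vendor formats (OMNIC, SPC,
  JCAMP-DX) are out of scope.
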