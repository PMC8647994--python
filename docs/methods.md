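# Methods

## Patlak graphical analysis

For an irreversible two-tissue tracer the tissue concentration obeys
`C_T(t) = Ki·∫₀ᵗC_p + V_D·C_p(t)` once the free compartment has
equilibrated, so plotting `y = C_T/C_p` against the "stretched time"
`x = ∫₀ᵗC_p / C_p` yields a line with slope Ki (min⁻¹) and intercept
V_D. The fit is unweighted ordinary least squares; `r2` is the
squared Pearson correlation of the Patlak points (identical to OLS R²
for a simple regression). Assumptions: decay-corrected activities
(curves flagged otherwise are refused), negligible dephosphorylation
over the hour, and equilibration fast relative to the first selected
frame. Negative tissue frame values (reconstruction noise) are
clamped to 0 with a warning before the transform.

Each frame is stamped at its mid-time. This is the standard
convention for frame-averaged TACs; the alternative (frame end-times)
would shift x by half a frame and was not adopted. The short
protocol's early tissue point is the 5–10-min frame (mid-time
7.5 min), i.e. the last frame of the early acquisition.

## Input functions

* **IDIF** — the full measured aorta TAC. Between frame mid-times the
  curve is piecewise-linear; before the first mid-time it rises
  linearly from 0 at t = 0 (no activity pre-injection).
* **Population tail (pIDIF)** — per-patient least-squares fits of
  `a + b·e^(−ct)` over the frames with mid-times in 10–60 min,
  averaged arithmetically coefficient-by-coefficient across the
  training cohort. Fit initialisation: `a₀` = last value,
  `b₀` = first tail value − a₀, `c₀` = ln2 / (half the tail span),
  with bounded restarts from perturbed guesses; flat curves return a
  degenerate fit (`b = 0`, `c` at its 1e-6 min⁻¹ floor).
* **Hybrid curve** — measured 0–10-min segment continued by the
  population tail on 10–60 min.

Every curve is anchored to the venous sample: one scale factor
`s = plasma(45 min) / curve(45 min)` multiplies the **entire** curve
(early segment and tail alike). Uniform scaling keeps the operation
idempotent and mirrors the standard-IDIF treatment; scaling the tail
only would introduce a step at 10 min whose size depends on the
sample, which we considered and rejected. The residual mismatch
between the measured value and the analytic tail at 10 min is exposed
as a diagnostic (`tail_discontinuity`), not silently removed.

The curve integral is exact-trapezoidal over the measured knots plus
the closed form `a(T−t₁) + (b/c)(e^(−ct₁) − e^(−cT))` for the
analytic tail; it agrees with 0.001-min quadrature to better than
0.1%.

**LOOCV.** For each held-out patient the population coefficients are
refitted on the rest, the patient's hybrid curve is rebuilt from their
own 0–10-min data and blood sample, and the mean square percentage
error `MSEP = (100/n)·Σ((ref−fit)/ref)²` is evaluated against their
blood-anchored measured IDIF at the tail frame mid-times only — the
early segments are identical by construction and would dilute the
error. The MSEP definition is the plain squared-relative-error form;
a root-mean-square variant (RMSPE) would be the square root of it.

## Method-comparison statistics

Passing–Bablok regression uses the original 1983 Part I estimator:
all pairwise slopes (vertical pairs as ±∞, slopes of exactly −1
discarded), slope = median shifted by K = #{slopes < −1}, intercept =
median(y − slope·x), confidence bounds from the rank indices
`M1 = (N−w)/2`, `M2 = N−M1+1` with
`w = z·sqrt(n(n−1)(2n+5)/18)`, offset by K. No bootstrap, no CUSUM
linearity test. Spearman ρ uses average ranks for ties; R² is squared
Pearson. Reported roundings follow the bundled tables' precision
(ρ to 3 decimals, R² to 4, slope to 3, intercept to 4).

Recomputing the summary statistics from the bundled per-patient
tables reproduces almost all published values to within two units of
the last printed digit — the scale at which the tables' own rounding
propagates. Two caveats, both visible in `report-tables` output: the
shifted-median slope evaluates to 0.994 against a printed 0.992
(plausibly a software-convention difference in the original
analysis), and the Spearman correlation between SUV and Ki,s
evaluates to 0.917 from the printed tables against a printed 0.923
under every standard tie convention — that value was presumably
computed from unrounded source data and is not recoverable from the
tables; the corresponding acceptance check is left failing rather
than loosened.

## Simulator

The generator reproduces the study conditions, not scanner physics.

* **Plasma input** `Cp(t) = A·(t/tp)^α·e^{α(1−t/tp)} +
  (1−e^{−t/τ})·(a+b·e^{−ct})`: a gamma-variate bolus (peak exactly A
  at tp) blended into the population tail. Defaults A = 60 kBq/ml
  (typical aortic peak for a few hundred MBq), tp = 0.6 min, α = 3,
  τ = 0.4 min; beyond 10 min the curve is the pure tail to <1%.
* **Tissue** from `dC1/dt = K1·Cp − (k2+k3)·C1`, `dC2/dt = k3·C1`,
  `CT = (1−Vb)(C1+C2) + Vb·Cp`. C1 is advanced with the exact
  exponential-update for piecewise-linear Cp on the fine grid, C2 by
  trapezoid; an independent `solve_ivp` integration agrees to <0.1%.
* **Fine grid** 0.5-s step over 0–60 min (7201 points), chosen so
  every 5-s frame boundary lies exactly on the grid; frame averaging
  is trapezoidal and conserves the fine-grid integral per frame.
* **Noise** ε ~ N(0, scale·sqrt(value/Δt)): Gaussian with variance
  proportional to activity over frame duration, the usual surrogate
  for reconstructed count statistics. Sinogram-level Poisson noise,
  attenuation, scatter and motion are out of scope, so passing tests
  show algorithmic correctness under the stated noise model, not
  robustness to full scanner physics.
* **Cohorts** draw Ki uniformly over 0.01–0.13 min⁻¹ (the clinical
  NSCLC span), k2 over 0.2–0.6, k3 over 0.03–0.09 min⁻¹, and derive
  K1 = Ki(k2+k3)/k3 so the cohort covers the Ki range exactly. The
  blood sample is the true Cp(45). Default cohorts are noiseless with
  all tails equal to the population model — the idealised condition
  under which short-protocol equivalence is provable; `tail_jitter`
  adds between-patient tail variability for LOOCV experiments.
* **Phantoms**: aortic cylinder + spherical tumor on a 32×32×16 grid
  of 3.18×3.18×3-mm voxels, uniform background, optional Gaussian
  blur. Noise-free, blur-free phantoms round-trip exactly through VOI
  extraction.

Numerical notes: worst-case noiseless Patlak bias over the cohort
parameter box is ≈4.9% (slow-equilibration corner k2 = 0.2,
k3 = 0.03 min⁻¹, rate 0.23 min⁻¹) — the residual equilibration
transient inherent to the graphical method, independent of Ki itself.

## VOI rule

The reference image (0–45-s summed frames for the aorta, last frame
for the tumor) is searched inside a region mask; the slice holding
the global maximum and its two neighbours (shifted inward at region
boundaries) form three consecutive slices, and the five hottest
voxels per slice are kept (15 voxels). The alternative reading — five
voxels total over the three slices — is available as `mode="total"`.
Ties resolve deterministically by ascending (z, y, x) index.

## Known limitations

No arterial sampling, metabolite, partial-volume, dispersion or
motion correction; regional (not voxel-wise) Patlak only; reversible
(generalised) Patlak not implemented; DICOM ingestion not supported
(NIfTI + JSON sidecar only). The Patlak transient bias noted above
means slow-equilibrating lesions are mildly underestimated by both
protocols equally.
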