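# Methods

## Unfolding model and melting point

The fraction of natively folded protein surviving heating to temperature
`T` is modeled as

    f(T) = (1 − p) / (1 + exp(−a·(T − b))) + p

with slope `a` (°C⁻¹), inflection `b` (°C) and plateau `p` (dimensionless).
As printed, the logistic increases with `T` for `a > 0`; a melting curve
must decrease, so `a` is constrained negative throughout (bounds
`a ∈ [−10, −10⁻³] °C⁻¹`). The upper asymptote is fixed at 1 by the
reference normalization; the model has exactly three free constants.

The melting point is defined as the absolute `f = 0.5` crossing — the
temperature at which half the protein is denatured — not the midpoint
between plateaus:

    Tm = b − ln(0.5 / (0.5 − p)) / a ,  defined only for p < 0.5.

For `p = 0` this reduces to `Tm = b` exactly. The closed form agrees with
numeric root-finding of `f(T) = 0.5` to below 10⁻⁹ °C (property-tested on
10³ random parameter sets).

## Normalization and fitting

Each replicate's intensities are divided by that replicate's intensity at
the lowest observed temperature (the non-denaturing reference); replicates
with a zero or missing reference are excluded with reason `no_reference`.
Normalization is idempotent.

Because the observed series is therefore `f(T)/f(T_ref)` rather than
`f(T)`, the fit minimizes residuals of the *self-normalized* model
`f(T; a,b,p) / f(T_ref; a,b,p)`. This matters: for proteins already
melting slightly at the reference temperature, fitting plain `f` against
reference-anchored data biases `b` upward; the self-normalized form
recovers the generating parameters exactly on noise-free data (to 10⁻⁶ in
the parameters, 10⁻⁴ °C in Tm, verified on the six-point 43–60 °C grid).

Fitting is bounded trust-region nonlinear least squares with an analytic
Jacobian, pooling all replicate points of one protein/condition
(replicate-wise fits are run separately only for the replicate-mode
significance test). Start values: `p₀ = clip(min y, 0, 0.3)`, `b₀` = the
temperature whose mean abundance is nearest `(1+p₀)/2`, `a₀` from the
two-point slope around `b₀` via `df/dT = a(1−p)/4`. If the primary start
fails, a 3×3 grid of perturbed `(a₀·{0.5,1,2}, b₀+{−3,0,+3})` starts is
retried; only if all fail is the fit reported non-converged. A minimum of
5 distinct temperatures is required (`insufficient_points` otherwise);
flat series are rejected as `no_melting_signal` since r² is undefined
without variance.

Goodness of fit (r²) is computed against the per-temperature replicate-mean
profile rather than the pooled points: replicate scatter is irreducible
measurement noise, and a pooled-point r² would penalize exactly the curves
— late-melting, small dynamic range — where noise dominates total variance
regardless of model adequacy. RMSE is still reported on the pooled
residuals.

## Quality control

A control/treated fit pair enters shift calling only if both fits
converged, both reach r² ≥ 0.8, both plateaus are < 0.4, and both melting
points are defined and lie within the assayed window ± 5 °C. Every failed
check appends a named reason code (`low_r2_treated`, `no_tm_control`, …)
and the protein is classed `qc_failed`, retained in the output without a
rank. All thresholds are exposed in the run configuration and logged.

## Shift statistics

ΔTm = Tm(treated) − Tm(control); positive means ligand-stabilized. Two
significance modes:

* **proteome_null** (default; needs no replicate structure): the bulk
  proteome is assumed unshifted, so each ΔTm is standardized as
  `z = (ΔTm − median) / (1.4826·MAD)` over QC-passing proteins, with a
  two-sided normal p-value. A MAD floor of 10⁻⁶ °C guards the degenerate
  all-identical null (then all z = 0). At least 3 QC-passing proteins are
  required.
* **replicate**: replicate-r control and treated curves are fitted
  separately, paired by replicate index, and the per-protein ΔTm values are
  tested against zero with a one-sample two-sided t-test (≥ 2 pairs).

Both modes are followed by Benjamini–Hochberg adjustment across proteins
(statsmodels). A protein is **stabilized** if ΔTm ≥ +2 °C with q ≤ 0.05,
**destabilized** if ΔTm ≤ −2 °C with q ≤ 0.05, else unchanged; both knobs
are configurable and recorded in output metadata. Ranks run 1..n over
QC-passing proteins by descending |ΔTm|, ties broken by ascending q then
protein id, making the ranking fully deterministic. Swapping condition
labels negates every ΔTm and exchanges the stabilized/destabilized counts.

## Differential expression

The two-fold rule operates on the lowest-temperature (non-denaturing)
abundances — the closest stand-in for an unheated comparative-proteomics
experiment within the data the pipeline holds. Per protein: log2 fold
change of replicate means (treated/vehicle), Welch's t-test on log
intensities, BH adjustment; **up** requires fold change ≥ 2 (inclusive)
with q below the cutoff, **down** requires ≤ 0.5. Zero control means and
insufficient replication are flagged, not silently dropped.

## CETSA

Densitometry series (≥ 4 strictly increasing temperatures) are normalized
by the lowest-temperature band. Tm50 is obtained either by fitting the
unfolding model (preferred with ≥ 5 points) or by linear interpolation at
the first adjacent pair bracketing 0.5 — the first-bracket rule makes
multi-crossing noisy series deterministic. The fit method falls back to
interpolation when the model cannot be fitted. Interpolated Tm50 is
invariant to uniform rescaling of the raw bands. With replicate curve
pairs (≥ 3) the replicate Tm50 differences are tested with a paired
two-sided Student's t-test. With ~5 % band noise, a single curve pair
carries roughly ±0.4 °C of Tm50 uncertainty (the noisy reference band
rescales the whole series), so the ±0.5 °C recovery property is stated —
and tested — for the triplicate assay.

## Synthetic data generator

The simulator emulates a temperature-range TPP screen: per protein, control
parameters drawn uniformly from `a ∈ (−1.5, −0.5) °C⁻¹`,
`b ∈ (47, 53) °C`, `p ∈ (0, 0.3)`; a base intensity log-uniform over
10⁶–10⁹ (typical label-free dynamic range); treated curves share `(a, p)`
and shift only `b` by the spiked ΔTm, isolating the melting-point shift as
the single causal difference. Spiked stabilized/destabilized counts are
`round(fraction·n)`; effect magnitudes default to uniform 2–8 °C, spanning
the 1.3–8 °C shifts reported for real targets of this assay class.
Defaults: six temperatures 43.0–60.0 °C in steps of 3.4 °C, three
replicates per condition, 10 % quantification noise, 5 % missingness.

The control melting-point range (47–53 °C) sits inside the heating gradient
with headroom at the top: a curve whose treated melting point leaves the
measured window cannot be fitted — a genuine identifiability limit of the
assay, not of the software — so the generator emulates the quantifiable
proteome, consistent with gradients being designed around the proteome
melting-point distribution (median near 50 °C).

Noise is multiplicative log-normal with median 1: `σ_log = √ln(1+CV²)` so
the linear-scale coefficient of variation equals `noise_cv` and log-noise
factors average to zero (the mean factor is then `exp(σ²/2)`, ≈ 1.005 at
CV 0.1 — negligible and condition-symmetric). Missingness is completely at
random. Identical configurations (including seed) produce bit-identical
tables and truth lists.

What the generator does **not** emulate: peptide-level roll-up, correlated
(protein- or run-level) noise, intensity-dependent variance and
missingness, co-aggregation effects, or ratio compression. Passing tests
therefore demonstrate correctness of the analysis machinery under a clean
generative model, not performance on real LC-MS/MS data.

## Problem sizes and numerical choices

The acceptance properties are computed at: 10³ random parameter sets for
the analytic-oracle check; 25 proteins for noise-free identifiability;
1000 proteins with 50 spike-ins at +6.4 °C (3 replicates, CV 0.1) for
recovery; 10 × 1000 zero-effect proteins for null calibration — sizes at
which the measured quantities are stable to well within their stated
bounds. Optimizer tolerances are 10⁻¹² (xtol/ftol/gtol); shift-table
floats are serialized at 6 significant digits, giving byte-identical
reruns; ties in ranking are broken deterministically as described above.

## Known limitations

* Per-condition curves are fitted, not treated/control abundance ratios;
  with only ratio data the normalization stage does not apply.
* The proteome-null mode assumes most proteins are unshifted; compounds
  with massive proteome-wide effects would inflate the null MAD and cost
  power.
* Tm is undefined for `p ≥ 0.5` by construction; strongly heat-resistant
  proteins are QC-failed rather than extrapolated.
* No isothermal dose-response (concentration-range) analysis, no Kelvin
  or thermodynamic (ΔG) parameterization, and no vendor-format parsing.
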