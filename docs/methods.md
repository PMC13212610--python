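# Methods

## Scope and intent

`perifem` couples a reduced-order (1-D) hemodynamic model of a stenosed
femoropopliteal segment to the statistics used to validate noninvasive
pressure predictions against invasive wire measurements. The reduced-order
solver is a deliberate stand-in for full 3-D computational fluid dynamics:
it preserves the entire pipeline interface (geometry + inflow in, axial
pressure profile out) and every clinically defined quantity, while being
fast and fully deterministic at desk scale. Image segmentation, 3-D
meshing, wall compliance, pulsatility and collateral networks are out of
scope.

## Pressure model

The lumen is a sampled radius profile `r(x)` (mm, proximal inlet at
`x = 0`). At steady flow `Q` the pressure drop has two parts:

1. **Distributed viscous loss.** The local Poiseuille gradient
   `8 μ Q / (π r⁴)` is integrated trapezoidally over the sampled axis.
   With `r` in mm, `Q` in mL/s and `μ` in mPa·s the integrand is directly
   in Pa/mm; the result is converted once to mmHg (1 mmHg = 133.322 Pa).
2. **Post-stenotic expansion loss.** Flow separation distal to each lesion
   dissipates kinetic energy that the viscous integral cannot capture. Per
   annotated lesion an empirical Young–Tsai-type turbulent term
   `Kt (ρ/2) (A_ref/A_min − 1)² V_ref |V_ref|` is applied as a localized
   pressure step at the lesion end, with `V_ref = Q/A_ref` and `Kt = 1.52`
   (dimensionless, configurable). This quadratic-in-Q term is what makes
   the vessel's pressure–flow relation nonlinear and severity-dominant for
   high-grade lesions.

Steady (cycle-averaged) flow is used throughout: the validated endpoints —
mean resting gradient and FFR — are time-averaged quantities, so waveform
shape enters only through the time-averaged DUS velocity.

Blood is Newtonian with density 1.06 g/cm³ and viscosity from the
hematocrit fraction η via `μ = 1.2 (1 + 2.5 η + 6.2 η²)` mPa·s. The
polynomial is interpreted with a 1.2 mPa·s plasma baseline, the only
physically sensible unit reading; it is valid for η ≤ 0.7 and gives
4.06 mPa·s at the typical η = 0.45.

A flow/geometry combination whose distal pressure falls to or below the
venous level is returned with a warning status rather than rejected: at an
imposed flow a high-grade stenosis can demand a supra-physiologic driving
pressure, and flagging keeps such cases visible instead of silently
clipped.

## Boundary conditions

* **CFDm** — population-average resting inflow, 1.26 mL/s for every
  patient. Cheap (no patient measurement) but blind to individual flow
  state.
* **CFDi** — individualized inflow from a popliteal DUS tracing:
  `Q = f · v̄_p · A`, where `v̄_p` is the trapezoidal time-average of the
  peak-velocity envelope over the largest whole number of cardiac cycles in
  the trace, `A` the circular lumen area at the sampling site, and
  `f = 0.5` the peak-to-mean factor of a parabolic velocity profile
  (configurable, since a larger sampling volume would change it). A
  machine-dependent fractional peak-velocity correction of 0, −10 % or
  −20 % is supported; −10 % is the default, reflecting the systematic
  overestimation reported for the scanner family involved.

**Hyperemia.** The peripheral (runoff) resistance is calibrated from the
resting solution as `R = (Pd,rest − Pv)/Q_rest` (venous pressure `Pv`
defaults to 0 mmHg, the conventional simplification in FFR work). A
vasodilator is modelled as `R → R/3`, and the hyperemic flow `Q*` solves

    Pa = vessel_drop(Q*) + (R/3) Q* + Pv

at a fixed resting inlet pressure. Both terms increase monotonically with
`Q`, so the root is unique and bracketed by `[Q_rest, 3 Q_rest]`; it is
found by scipy's bracketed root-finder to |ΔQ| < 1e−9 mL/s. With zero
vessel resistance `Q* = 3 Q_rest` exactly; any vessel resistance pulls it
lower. The simulated FFR is `Pd(Q*)/Pa`.

## Lesion detection and per-lesion attribution

Diffuse multi-segmental disease has no healthy reference segment, so the
reference diameter is estimated robustly: lesions are maximal contiguous
spans where the local diameter falls below `(1 − s/100)` times the
reference, with the reference taken as the median radius in two passes
(global first, then recomputed excluding candidate spans). The detection
threshold `s` defaults to 50 % diameter stenosis.

Individual-lesion FFR comes from a (virtual or measured) pullback: each
lesion's pressure jump is read between a 5 mm margin proximal of its start
and 5 mm distal of its end (margins shrink to the midpoint between adjacent
lesions so no span is counted twice), and its FFR is `(Pa − Δp)/Pa` with
`Pa` the most-proximal trace pressure. Normalizing by the segment-inlet
pressure (rather than each lesion's immediately-proximal pressure) makes
the per-lesion values reduce exactly to the full-segment FFR for a single
lesion spanning the vessel.

## Validation statistics

Differences are simulated minus measured. Bland–Altman bias is their mean,
SD uses the n−1 denominator, limits of agreement are `bias ± 1.96 SD`, and
the bias is tested with a two-sided one-sample t-test at α = 0.05.
Significance classification is strict on both thresholds: resting gradient
`> 10 mmHg`, FFR `< 0.8` (a gradient of exactly 10.0 or an FFR of exactly
0.80 is non-significant). Sensitivity, specificity and accuracy carry exact
Clopper–Pearson 95 % intervals (beta quantiles); a proportion whose
denominator is 0 or 1 is flagged degenerate, since its interval then rests
on at most one observation. Percentages are reported with halves rounded
away from zero.

## Synthetic cohorts

The generator emulates the statistical structure of the study population so
every pipeline stage is testable without patient data:

| parameter | default | rationale |
|---|---|---|
| lesions per limb | mean 3, spread 1.5, clipped 1–5 | matches the reported stenosis count per limb |
| diameter stenosis | uniform 50–90 % | study enrolled multi-segmental disease > 50 % |
| segment length / radius | 300 mm, 2.5 ± 0.3 mm | femoropopliteal dimensions |
| hematocrit | 0.42 ± 0.04, truncated [0.25, 0.55] | physiologic range |
| inlet pressure | 95 ± 10 mmHg | mean aortic pressure |
| resting flow | log-normal, median 2.0 mL/s, log-SD 0.35 | spans the ~0.9–4.3 mL/s range observed by DUS |
| distal-pressure noise | 2.0 mmHg SD, Gaussian | wire-measurement repeatability scale |

Vessels are a mildly tapered baseline (≤ 10 % over the length) with
non-overlapping cosine-bell narrowings sampled at 1 mm. Velocity traces are
a triphasic template (systolic lobe, early-diastolic reversal,
late-diastolic forward bump) scaled so the flow estimator recovers the
target flow exactly at zero noise; envelope noise is a per-trace
multiplicative gain (plus small jitter), so a 20 % setting reproduces the
~20 % interobserver variability reported for DUS flow. All randomness
derives from one root seed through per-case child streams, so any case is
reproducible independently of cohort size.

**Ground truth and the recovery experiment.** Each case's true distal
pressures come from a reference evaluation of the same physics. By default
the truth is evaluated on the same 1 mm grid as the analysis pipeline
(matched physics), so the parameter-recovery experiment isolates the
measurement noise: the pipeline's Bland–Altman SD should reproduce the
injected 2 mmHg and its bias should be statistically indistinguishable from
zero. Model mismatch can be switched on explicitly, either by evaluating
the truth at 10× finer axial resolution (`truth_refinement=10`; the 1 mm
trapezoid then systematically overestimates severe-lesion drops, biasing
recovery by ~2 mmHg at these severities — a deliberate probe of
discretization sensitivity, not the default) or by perturbing the truth's
expansion-loss coefficient (`truth_kt_perturbation`).

**What the generator does not emulate.** Flow is imposed, not solved from a
systemic circulation, so a high-grade lesion at median flow can demand a
non-physical driving pressure; such cases are flagged (`physical=False`),
excluded from hyperemic truth, and at the default severity range make up
roughly 40 % of a cohort. Real anatomies also have non-circular lumens,
measured areas with their own error, pulsatile pressure, and collateral
pathways that cap trans-lesion flow. Passing recovery tests therefore
demonstrate internal consistency of the pipeline under its own model
family — not accuracy against 3-D flow or in vivo measurements, which is
what the packaged study tables address.

## Numerical choices

* mmHg ↔ Pa fixed at 133.322; density 1.06 g/cm³; all unit handling
  verified by an SI round-trip test.
* Trapezoidal integration on the profile as sampled — no implicit
  resampling or smoothing; smoothness is the generator's responsibility.
* Root-finding: scipy `brentq` on the analytic bracket, xtol 1e−9 mL/s,
  deterministic.
* Lesion expansion steps are applied at the lesion end position (the
  physical site of the separation loss).
* A single-sample lesion span is widened by half a grid step per side so
  its annotation has positive length.
* The packaged study tables are verified against embedded SHA-256
  checksums at every load.

## Known limitations

* The reduced-order model omits lesion-lesion interaction beyond series
  addition; closely spaced stenoses whose jets interact are treated as
  independent losses.
* The parabolic-profile factor 0.5 is an assumption of the DUS flow
  estimate; skewed or blunted profiles change it.
* Hyperemic inlet pressure is held at its resting value; systemic pressure
  responses to vasodilators are not modelled.
* The per-lesion FFR normalizes by the segment-inlet pressure; an
  alternative convention (each lesion's local proximal pressure) yields
  slightly higher values for distal lesions.
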