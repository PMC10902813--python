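# Methods

This note documents the measurement model implemented in `sulfid`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Measurement model

### Ratio formation and masking

The raw trace carries ³²S and ³⁴S intensities (counts/s) on a common
time base; the two isotopes are scanned quasi-simultaneously by a
sector-field instrument, so no inter-channel time alignment is
performed. The per-point ratio is r = i32/i34. Points whose ³⁴S
intensity falls at or below a configurable floor are masked (excluded)
rather than set to infinity; the default floor is 0 because the
post-column spike guarantees a large ³⁴S signal everywhere. A ratio of
exactly zero (no ³²S counts in a dwell interval) is *not* masked — it is
a legitimate baseline observation that the mass-flow step clips to zero.

### Mass-bias correction

"Mass bias" is implemented as Russell's exponential law,
R_true = R_meas·(m32/m34)^β. The exponent is calibrated from one or
more measurements of an unspiked natural-abundance standard whose
³²S/³⁴S amount ratio is certified (default 22.555), each measured by the
peak-area integration method (ratio of the integrated ³²S and ³⁴S
areas). Per-repetition exponents are averaged. A purely multiplicative
("linear") correction factor K = mean(R_ref/R_meas) is available as an
option (`law: linear`); for sulfur the two differ negligibly at typical
bias levels, and the exponential form is the default because it is the
standard in ICP-MS isotope-ratio metrology. Correcting an
already-corrected ratio trace is a contract violation and raises, so the
correction cannot be applied twice.

### Isotope-dilution conversion

With spike amount fractions x_sp32, x_sp34, sample amount fractions
x_s32, x_s34, and the total spike sulfur molar flow
n_sp = (w_spike·f_spike)/(m34·x_sp34) (mol/min), the analyte sulfur mass
flow is

    MF = AW_sample · n_sp · (r·x_sp34 − x_sp32) / (x_s32 − r·x_s34)

converted to ng/min. w_spike is interpreted strictly as the mass
fraction of the ³⁴S *isotope* in the sheath liquid (not of total spike
sulfur); with a 99.8 % enriched spike the distinction is a 0.2 % effect
and is handled explicitly through x_sp34. AW_sample is computed from the
configured 4-isotope sample composition (CIAAW representative natural
abundances by default, user-overridable), never hard-coded.

The admissible ratio interval is open: (x_sp32/x_sp34, x_s32/x_s34).
At the lower bound the signal is pure spike (MF = 0); at the upper bound
the denominator vanishes (sample-dominated signal). The scalar
`mass_flow_point` raises a range error naming the violated bound; the
vectorised trace path instead clips out-of-range points to MF = 0 and
logs their count, because baseline counting noise at near-zero ³²S
legitimately produces ratios at or below the spike ratio. Clipping (not
erroring) on the high side is harmless in practice since the spike keeps
peak-top ratios far from the natural ratio at the flows considered.

### Blank subtraction

MF_blank is the median raw mass flow over user-declared blank time
regions and is subtracted globally; the median resists residual peak
contamination and, because more than half of the clean-baseline points
clip to exactly zero under counting noise, it estimates a zero blank
without bias. Negative blanks are floored at zero. No local per-window
baseline is re-estimated during integration — blank correction is a
single global step.

### Peak integration

Peak areas use the trapezoidal rule on MF (ng/min) against time, with
the single s→min conversion performed inside the integrator so areas are
ng of sulfur. The trapezoidal rule equals the Σ MF·Δt sum at uniform
sampling and remains correct at non-uniform sampling. Auto-detection
(optional; configured windows take precedence) thresholds the trace at a
minimum height and width and extends each core to the flanking local
minima, mimicking manual region placement. Overlapping-peak
deconvolution is deliberately out of scope. Negative point values inside
a window (blank-subtracted noise) are integrated as-is so the estimate
stays unbiased; only the final reported area is floored at zero.

### Quantification

sulfur concentration = area / V_inj; compound concentration =
sulfur concentration · M_compound/(n_S·AW_S). The sulfur molar mass per
mole of compound is n_S·AW_S with AW_S = 32.06 g/mol (conventional
CIAAW standard atomic weight), which reproduces the benchmark mass
fractions (sulfate 33.4 %, cystine 26.7 %, methionine 21.5 %, BSA
1.85 %, HSA 1.94 %) to three significant figures. V_inj is determined
operationally by injecting a sulfate standard of known sulfur
concentration and dividing the integrated mass by that concentration; a
warning is logged if the result leaves the plausible hydrodynamic range
(10–50 nL).

### Calibration figures of merit

Calibration is unweighted ordinary least squares of response on nominal
sulfur concentration (a 1/x-weighted option exists but is off by
default, as no weighting is assumed in the reference procedure);
residual_se = sqrt(SSR/(n−2)); LOD = 3·residual_se/|slope| and
LOQ = 10·residual_se/|slope| in mg/L of sulfur, so LOQ/LOD = 10/3
identically. The absolute-mass form (pg) is LOD·V_inj, exposed as
`CalibrationResult.lod_absolute_pg`.

### Uncertainty

First-order GUM propagation treats the composed measurement function
(ratio → mass flow → concentration) as a black box: sensitivities are
central differences with step max(1e-6·|x|, 1e-12), u² = Σ(cᵢuᵢ)², and
per-input shares (cᵢuᵢ)²/u². Input correlations are taken as zero (no
covariances are available). The single-measurement model used by
`concentration_model` represents the peak by its average corrected ratio
sustained over a fixed effective duration (default 0.5 min) — the same
reduction a budget tool applies when a transient peak must be expressed
as one ratio quantity. Replicates are combined as

    u_c = sqrt(mean(u_i)² + s²/n),   U = k·u_c (k = 2 default),

with s the replicate standard deviation. The root-sum-square form is a
documented choice (the alternative `max(mean(u_i), s/√n)` is selectable
via `mode="max"`); it is conservative, reduces to mean(u) when scatter
vanishes and to s/√n when the per-run budget vanishes. Monte-Carlo
propagation is used only as an independent test oracle, not as a
primary mode.

## Constants

Isotope masses and the representative natural amount fractions
(x32 = 0.9499, x33 = 0.0075, x34 = 0.0425, x36 = 0.0001; AW ≈ 32.065)
follow CIAAW; the version is recorded in `constants.CIAAW_VERSION` and
every value is overridable through the run configuration, since the
exact "organic sulfur of animal origin" composition a laboratory adopts
may differ slightly. The spike composition defaults to 99.8 % ³⁴S /
0.2 % ³²S, the spike level to 0.5 mg/kg ³⁴S delivered at 10 mg/min, and
the certified calibrant ratio to 22.555.

## The simulator

`simulate` runs the measurement model forward. Analyte sulfur elutes as
Gaussian peaks (σ in seconds; an exponentially modified Gaussian tail
with time constant τ is available to mimic electrophoretic tailing),
each normalised to its true sulfur mass; an optional constant analyte
blank can be added. Spike and sample isotope molar flows follow from
their compositions; ideal intensities are proportional to isotope molar
flow with a single detector constant shared by both isotopes, so the
unbiased intensity ratio equals the amount ratio. That constant is
specified as counts·s⁻¹ per ng·min⁻¹ of ³²S mass flow (the unit users
reason in) and converted internally via m32. Mass bias is applied as the
exact inverse of the Russell-law correction with a configurable true
exponent; mass-dependent transmission differences are represented
entirely by that exponent. Poisson noise acts on counts per dwell
interval (counts = cps·dwell, default dwell 0.002 s) and is converted
back to cps; all randomness is seeded.

Default study conditions: 10 Hz sampling, 120 s runs, the spike
parameters above, peak σ ≈ 2.5–5 s, and a sensitivity of
2×10⁵ cps/(ng·min⁻¹), which puts the spike-dominated ³⁴S channel near
10⁶ cps — the upper end of realistic count rates for a sector-field
instrument after dead-time correction. At these settings single-run peak
areas carry ≈ 0.3 % relative counting scatter. A serum-like preset
(`simulate_serum_profile`) places a cluster of partially overlapping
early protein peaks ahead of a baseline-resolved albumin peak sized from
a target albumin concentration (default 28.1 g/L at 21.6 nL injected).

What the simulator does **not** emulate: electromigration physics
(migration times are inputs, not predictions), drift of the sheath flow
or of the mass bias within a run, detector dead time (assumed corrected
upstream), ³³S/³⁶S spectral interferences, and correlated baseline
wander. Passing closed-loop tests therefore demonstrates the
correctness of the data processing — not the absence of these
instrumental effects in real data. Consequently the instrument-dependent
figures (recoveries, LODs, serum concentrations) obtained on synthetic
data characterise the pipeline, not any physical measurement.

## Numerical and scale choices

Problem sizes in tests and in the acceptance script — 120–240 s traces
at 10 Hz, 50 noise replicates, 10⁵ Monte-Carlo draws — were chosen so
each statistical check has comfortable resolving power while the whole
suite runs in seconds. Time is stored in seconds, mass flow in ng/min,
areas in ng, concentrations in mg/L (sulfur) and g/L (compound); each
unit conversion happens in exactly one place. Ties and degenerate
inputs: traces need ≥ 2 points and strictly increasing time; windows
need ≥ 3 points to integrate; calibrations need ≥ 3 distinct levels;
replicate combination needs n ≥ 2; an all-masked trace raises instead of
returning an empty ratio trace.

## Known limitations

- Overlapping peaks are integrated as drawn windows; no deconvolution.
- The uncertainty model reduces a transient peak to one average-ratio
  quantity; point-wise propagation along the transient is not attempted.
- The LOD/LOQ definitions are calibration-curve based; blank-based
  (3σ_blank) definitions are not implemented.
- Mass bias is assumed constant between the bracketing standard
  measurements; no within-sequence drift correction.
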