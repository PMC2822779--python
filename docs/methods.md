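# Methods

This note documents the models, estimators and numerical choices behind
`tailbeat`, and what the synthetic benchmarks do and do not establish.

## The half-center simulator

Two units (left *i* = L, right *i* = R; *j* the other side) follow a
Matsuoka-style half-center with rectified activations
y_i = max(0, u_i):

    tau_act  · du_i/dt' = −u_i + 1 + (w_exc − w_inh)·y_j − b_adapt·v_i + ξ_i
    tau_adapt· dv_i/dt' = −v_i + y_i

with adaptation v_i, OU drive noise ξ_i (correlation time 50 ms, stationary
SD `noise_sd`), and a side-specific clock dt' = d_i·dt where the *effective
drive* d_i = drive·(1 ± asym)/(1 + gaba_tone) sets the network tempo.  The
output per side is y_i passed through a first-order 20 ms low-pass (muscle
and optical smoothing).  Integration is fixed-step Euler–Maruyama at
10 × the output rate (default 500 samples/s), decimated; a 2 s lead-in is
simulated and discarded so traces start in the stationary regime.

Design rationale:

- **Drive as tempo.**  Swimming frequency in the reduced preparation scales
  with bath glutamate concentration (≈12 Hz at 10 µM, ≈24 Hz at 100 µM).  A
  plain Matsuoka oscillator has an input-robust frequency, so tonic drive is
  implemented as a time rescaling of the unit dynamics: frequency is
  proportional to effective drive (verified to ~2% over the calibrated
  range), amplitude is drive-independent, and the "more drive never slows
  the rhythm" invariant holds by construction.
- **GABA tone as a drive divisor.**  `gaba_tone` (default 0.15) divides the
  effective drive; setting it to 0 (picrotoxin) raises frequency ~15%
  without touching the crossed inhibition, so alternation is preserved.
- **Rhythm without coupling.**  A single adapting unit has a stable damped
  focus, not a limit cycle; with crossed inhibition removed (strychnine,
  antisense knockdown) rhythmicity is sustained by the drive noise exciting
  that weakly damped mode (quasi-cycles).  The time constants and adaptation
  gain (tau_act 59 ms, tau_adapt 74 ms, b_adapt 30, w_inh 2.0) were chosen
  so the uncoupled quasi-cycle frequency matches the coupled limit-cycle
  frequency within a few percent — the strychnine phenotype keeps the intact
  frequency while the left/right phase diffuses freely.
- **Phase 0.54, not 0.50.**  A small left/right drive imbalance
  (`asym` = −0.045, right side slightly stronger) detunes the two half
  centers so the locked phase settles near 0.54 rather than exact antiphase.
- **Noise level.**  `noise_sd` = 0.05 (≈5% of the unit drive) gives
  cycle-to-cycle locked-phase circular SD ≈ 0.04 cycles (below the 0.05
  locking tolerance) while still decorrelating uncoupled sides within a few
  seconds; episode gating (`episode_on`) is off by default and, when on,
  lengthens swimming bouts as GABA tone decreases — a qualitative feature
  only.
- Weak crossed excitation `w_exc` defaults to 0 (its biological presence is
  uncertain); partial inhibition block is expressible by intermediate
  `w_inh` but is not calibrated to any benchmark.

Preset drives are derived from target frequencies through the measured base
frequency (12.17 Hz at unit effective drive).  The morpholino presets reuse
the intact drive level: the antisense preset removes crossed inhibition
(strychnine-like), the 5-mismatch control is the intact parameterization, so
their frequency difference is only sampling noise and the unpaired t test on
frequency is non-significant, as in the knockdown experiment.

## Rhythm estimators

- **Autocorrelation / cross-correlation**: biased (divide by N),
  mean-subtracted, normalized to correlation coefficients.  The biased form
  tapers smoothly at long lags, which stabilizes peak picking on short
  traces.  Detrending is mean subtraction only.
- **Period**: first positive-lag local maximum of the left autocorrelation,
  required to lie after the first local minimum (never the zero-lag
  shoulder) and to exceed a white-noise band Bonferroni-corrected over the
  searched lags (z_{1−0.025/M}/√N).  The pointwise 1.96/√N band would flag a
  "period" on nearly every pure-noise trace.  Peaks are refined by 3-point
  parabolic interpolation; ties break toward the smaller lag.
- **Phase**: the cross-correlation peak is searched in (0, T] (half a sample
  of slack at the T edge so a peak at exactly one period survives
  rounding), giving a single-valued φ in [0, 1).  The statistic is always
  computed; whether it is *reported* is decided by 199 circular-shift
  surrogates of the right channel (max |C| in the same window, two-sided
  95th percentile).  Circular shifting preserves each side's rhythmicity
  and destroys genuine coupling, so the test controls false positives on
  independent same-frequency rhythms (measured ≈3% at the 5% level).  For
  noiseless periodic signals every surrogate ties with the observed peak —
  locking is then undecidable from one trace and the phase is flagged
  undefined even though the statistic itself is exact; summaries report the
  phase only when defined.
- **Bursts**: half-wave rectified envelope relative to a local baseline
  (moving average over two periods), causal 10 ms boxcar smoothing; burst
  peaks are envelope maxima above 10% of its 95th percentile separated by at
  least 0.6 T, and each onset walks back from its peak to the height
  threshold.  Peak-anchored detection was chosen over plain
  threshold-crossing (mean + 1 SD) because the rhythm's amplitude
  fluctuates: the fixed threshold dropped 15–30% of genuine cycles, which
  broke both the burst-count/cycle-count agreement and strict-alternation
  scoring.  The alternation index is the fraction of consecutive L/R events
  that switch sides; L/R/L/R/L/R → 1.0, L/L/L/R/R/R → 0.2 (one switching
  pair of five), random sides → 0.5.
- **Degenerate inputs**: constant signals raise a degenerate-signal error;
  non-rhythmic traces raise a not-rhythmic error from `locomotor_period`,
  while `analyze_trace` never raises on them — it returns a summary with
  the corresponding `*_defined` flags false and the reason in `notes`.

## Acquisition emulation

Frames are 240×150 8-bit grayscale; the tail is an anti-aliased polyline
from a pivot near the top, lateral offset growing as s^1.2 along the tail,
with tip deflection proportional to the difference of per-side-normalized
activations raised to the 5th power, smoothed 4 ms (supralinear muscle
recruitment plus tail inertia).  The exponent matters: with a strictly
linear difference the two ROI signals become near-antisymmetric functions of
one scalar and their cross-correlation collapses toward φ = 0.5, erasing
the 0.54 asymmetry; a supralinear map keeps each side's burst timing
distinct in the single tail trajectory.  ROIs span the outer excursion band
per side (from 12% of peak excursion outward, lower half of the tail),
mirroring "maximum excursion" placement.  Densitometry is the plain spatial
mean per frame (no modelled PMT gain or filtering); optional Gaussian pixel
noise supports robustness tests.  With these defaults the
simulate → render → measure → analyze round trip agrees with direct analysis
to ≤2% in period and ≤0.01 cycles in phase over seeded repeats.

## Cohort statistics

Frequency uses arithmetic mean ± SEM (SD/√n; a single animal reports SEM 0
and is flagged).  Phase uses the circular (resultant-vector) mean and
circular SD/√n over animals with defined phase, reported only when at least
half the group qualifies; with tightly clustered phases this reduces to the
linear statistics.  The unpaired t test is the classical pooled-variance
Student form (Welch behind a flag); no multiple-testing correction is
applied and raw p-values are recorded.  The experiment runner seeds each
condition block deterministically from one base seed.

## Oocyte analyses

The Hill fit uses least squares (`scipy.optimize.curve_fit`) with r_max
initialized at the maximum response, EC₅₀ at the dose nearest half-max,
n = 1, and n bounded to [0.3, 6]; it requires ≥4 distinct doses spanning
≥1.5 log units.  The synthetic generator produces occupancy-plus-noise
tables over the tested range 30 µM–3 mM (default EC₅₀ 7.5×10⁻⁴ M, n = 1.5);
noise-free refits recover EC₅₀ to optimizer precision and the median
absolute EC₅₀ error at 2% response noise is ≈3.5% over 500 replicates.

Reversal potentials come from linear interpolation of the zero crossing of
the leak-subtracted I–V (straight-line fit to the pre-agonist ramp); with
several crossings the one nearest the Cl⁻ Nernst prediction is taken and
flagged.  Nernst potentials use E = (RT/zF)·ln([out]/[in]) at the bath
temperature (default 20 °C; recording temperature was not specified).
Internal concentrations default to typical oocyte values (Cl⁻ 40 mM,
Na⁺ 10 mM, K⁺ 110 mM) — the internal Cl⁻ is an assumption, configurable per
call.  The ND96 bath is 96 NaCl, 2 KCl, 2 CaCl₂, 1.8 MgCl₂ (total Cl⁻
105.6 mM ⇒ E_Cl ≈ −24.5 mV).  The low-Cl⁻ (methanesulphonate for chloride)
and low-Na⁺/K⁺ (NMDG for the cations, small residual Na⁺/K⁺ so Nernst
predictions stay finite) recipes are plausible reconstructions, not
published compositions.  The substitution classifier scores each candidate
ion by the summed squared difference between measured and Nernst-predicted
reversal shifts across solutions and picks the minimum; on synthetic
Cl⁻-selective channels with 1% current noise it is correct in 100/100
seeded runs.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds; per-component child seeds
are derived by SHA-256 from (seed, component, index) and kept below 2³¹.
CSV/JSON writers emit shortest round-trip float representations with LF
endings, so re-runs are byte-identical.  Default problem sizes — 20 s traces
at 500 samples/s, cohorts of 5–11 animals, 199 surrogates, 10 s renders for
the video round trip, 100–500 replicate fits — keep the full test suite and
the acceptance script at a few minutes on one core while leaving every
statistic comfortably inside its tolerance.

## What the synthetic benchmarks show — and what they do not

The generator reproduces the statistical structure the analysis assumes:
near-antiphase locking at 10–25 Hz, drive-scaled frequency, noise-sustained
unilateral rhythms under inhibition block, amplitude fluctuation, slow drive
wander.  It does not emulate episode structure quantitatively, traveling
tail waves or hydrodynamics, camera artifacts beyond additive pixel noise,
real video segmentation, or biophysically detailed neurons.  Passing tests
therefore validate the estimators and the pipeline's internal consistency at
realistic signal statistics — not the biological model itself, and not
performance on raw experimental video.

Known limitations: the locked-phase asymmetry (0.54) enters through a
static drive imbalance, one of several mechanisms consistent with the
measurement; the surrogate test is intentionally powerless on perfectly
periodic signals (see above); burst detection assumes a roughly stationary
rhythm within a trace and a detectable period for its refractory scaling;
and the ion-substitution classifier only considers single-ion selectivity
hypotheses.
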