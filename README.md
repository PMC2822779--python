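# tailbeat

Quantitative analysis of bilateral locomotor rhythms — built around the
swimming of the ascidian (*Ciona intestinalis*) larva, whose tail beats
left/right at 10–25 Hz under the control of a minimal spinal-like central
pattern generator (CPG).  The package is for physiologists and modellers who
record paired left/right activity traces (video densitometry,
photomultiplier pairs, EMG envelopes) and want the standard rhythm
statistics, plus a calibrated synthetic-data generator to validate the whole
measurement chain.

## What it computes

Given a bilateral trace (left(t), right(t) at a fixed sampling rate):

- **Locomotor period** *T*: the lag of the first significant positive-lag
  maximum of the left-side autocorrelation (biased, mean-subtracted
  estimator; 3-point parabolic peak interpolation; white-noise significance
  band).  Frequency *f* = 1/*T*.
- **Contralateral phase** φ: with τₓ the peak of the normalized left/right
  cross-correlation *C*(τ) inside (0, *T*] (convention: *C*(τ) correlates
  left(t) with right(t+τ)),

      φ = ((T − τₓ) / T) mod 1

  so perfect antiphase gives φ = 0.5.  A circular-shift surrogate ensemble
  (199 shifts of the right channel, 95th percentile of the windowed maximum)
  decides whether the phase is *defined* — uncoupled but same-frequency
  rhythms fail the test, reproducing the "no cross-correlated peak"
  phenotype of glycinergic block.
- **Burst alternation**: envelope-based burst onsets per side, merged into an
  L/R event sequence; the alternation index is the fraction of consecutive
  events that switch sides (1.0 = strict L/R/L/R).
- **Cohort statistics**: per-condition mean ± SEM frequency, circular
  mean ± SEM phase, proportion of animals with defined phase, Student's
  paired/unpaired t tests.
- **Oocyte analyses** for receptor characterization: Hill fits
  (r = r_max·c^n/(c^n + EC₅₀^n)) of dose-response tables, leak-subtracted
  reversal potentials from voltage ramps, Nernst predictions
  E = (RT/zF)·ln([out]/[in]), and an ion-substitution classifier that
  identifies the permeant ion (Cl⁻ vs Na⁺ vs K⁺) from reversal shifts.

The synthetic-data generator (`tailbeat.synth`) is a Matsuoka-style
half-center oscillator: two rectified leaky units with slow adaptation and
crossed (glycinergic) inhibition, driven by tonic excitation under OU noise.
Named presets map pharmacological/genetic conditions onto parameters —
`intact`, `headless_glut_100uM`, `headless_glut_10uM`, `strychnine`
(crossed inhibition removed), `picrotoxin` (tonic GABAergic modulation
removed), `mo_antisense`, `mo_mismatch` — each calibrated so the full
pipeline reproduces the corresponding swimming phenotype.  A rendering
module turns traces into schematic tail-swing TIFF stacks and recovers them
through rectangular-ROI densitometry, emulating the dual-photomultiplier
recording geometry.

## Worked example

```python
from tailbeat import preset, simulate_cpg, analyze_trace

for name in ("intact", "strychnine", "picrotoxin"):
    params = preset(name).params.replace(seed=1)
    trace = simulate_cpg(params)          # 20 s at 500 samples/s
    s = analyze_trace(trace, seed=1)
    phase = f"{s.phase:.3f}" if s.phase_defined else "undefined"
    print(f"{name:12s} f = {s.frequency_hz:5.2f} Hz   phase = {phase:9s} "
          f"alternation = {s.alternation_index:.2f}")
```

prints

```
intact       f = 12.22 Hz   phase = 0.542     alternation = 1.00
strychnine   f = 12.04 Hz   phase = undefined alternation = 0.83
picrotoxin   f = 14.08 Hz   phase = 0.541     alternation = 1.00
```

i.e. the intact network swims near 12 Hz locked just past antiphase
(φ ≈ 0.54); blocking crossed inhibition (strychnine) leaves each side
rhythmic at an unchanged frequency but destroys the phase relation and
degrades strict alternation; removing GABAergic modulation (picrotoxin)
raises the frequency ~15% without touching alternation.

The same pipeline is scriptable from the shell:

```sh
tailbeat simulate --preset intact --seed 1 --out run/
tailbeat analyze --trace run/trace_intact_seed1.csv --seed 1 --out run/analysis/
tailbeat experiment --config experiment.yaml --out results/
tailbeat oocyte fit-hill --doses doses.csv --out hill.json
```

Every run writes a `manifest.json` (config echo, seed, artifact checksums);
identical seeds give byte-identical outputs.

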