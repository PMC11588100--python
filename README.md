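# noiseschema

Hearing a brief sound against ongoing background noise — a phone ring in
rain, a bark over a crowd — requires knowing what the noise itself sounds
like. `noiseschema` implements a signal-computable observer model of this
ability, the synthetic stimuli to probe it, and the psychophysical
analyses used to characterize it. It is aimed at auditory researchers who
want a workable reference implementation of outlier-based foreground
detection and of the elbow-curve analysis stack that goes with it.

## The model

A waveform is converted to a cochleagram (ERB-spaced bandpass filters,
compressed Hilbert envelopes) and then to time-varying activations of
spectrotemporal features. For each filter *i*, the model fits a Gaussian
N(μᵢ, σᵢ²) to the activations in a sliding **past** window (1,000 ms) and
scores the adjacent **present** window (500 ms) by its average surprisal

  Sᵢ(t) = ⟨ −ln N(xᵢ; μᵢ, σᵢ²) ⟩_present = ½ln(2πσᵢ²) + ⟨(xᵢ−μᵢ)²⟩/(2σᵢ²),

pools S(t) = meanᵢ Sᵢ(t), and reports a foreground when S(t) exceeds an
empirically calibrated, time-varying threshold for a sustained run of
evaluations. Because the background statistics are estimated from finite
data, detection sensitivity (d′) rises as the foreground's onset is
delayed and the past window fills — a rise-then-plateau ("elbow")
dependence on onset time, with the plateau reached on the timescale of
the past window. The analysis stack quantifies such curves with
piecewise-linear elbow fits, participant bootstrap CIs, delay-benefit
statistics, permutation tests and asymptote matching.

## Worked example

```python
import numpy as np
from noiseschema import (TextureSpec, ForegroundSpec, WindowConfig,
                         gen_texture_background, gen_foreground, mix_at_snr,
                         calibrate_threshold, detect)
from noiseschema.experiments import DESK_FRONTEND

# 1. background-only calibration set -> decision threshold (1% FA target)
cal = [DESK_FRONTEND.features(gen_texture_background(TextureSpec(seed=s)))
       for s in range(100)]
thr = calibrate_threshold(cal, WindowConfig(), q=0.99)

# 2. a texture with a 0 dB foreground starting 1.5 s in
bg = gen_texture_background(TextureSpec(seed=777))
fg = gen_foreground(ForegroundSpec(seed=7, band=(600.0, 1700.0)))
mix = mix_at_snr(fg, bg, snr_db=0.0, onset_ms=1500)

d = detect(mix, thr, WindowConfig(), DESK_FRONTEND)
print(d.present, round(d.peak_time, 2))   # True 2.0
```

The decision is `True` with the pooled-surprisal peak at 2.0 s — inside
the foreground's 1.5–2.0 s extent. (At the studied −2/−6 dB SNRs,
single-trial detection is probabilistic; the experiment drivers estimate
hit rates over many trials.)

The numbered drivers under `analysis/` run the full studies and write
tables under `results/`. `python analysis/02_observer_model.py` prints,
for a 40-background onset × SNR experiment pooled over 8 stimulus sets:

```
pooled false-alarm rate: 0.019 (design target 0.01)
model d' rises from 0.22 at 250 ms to 1.17 at late onsets (rho = 0.65)
elbow of the onset curve: 1250 ms (past window 1000 ms); delay benefit 0.96 d'
```

i.e. the model is near its false-alarm design target, detection improves
several-fold as onset is delayed, and the improvement plateaus on the
timescale of the past window. `python analysis/03_behavioral_analyses.py`
runs the behavioral stack on synthetic cohorts generated at published
curve parameters (elbow 912 ms; delay-benefit gap 0.15 d′ between
repeated and nonrepeated backgrounds):

```
detection cohort: elbow 900 ms (95% CI [855, 965] ms; generating value 912 ms)
delay benefit: nonrepeated 0.99, repeated 0.85 d' (difference 0.14, injected 0.15); permutation p = 0.0460
```

A `noiseschema` command-line interface exposes the same stages
(`synth`, `calibrate`, `detect`, `analyze`, `metrics`, `run`); see
`noiseschema --help`.

## Layout

```
src/noiseschema/   frontend, detector, stimuli, psychophysics, metrics,
                   experiments, io, config, pipeline, cli
analysis/          numbered narrative drivers (01 stimuli, 02 model,
                   03 behavior)
tests/             unit, property and acceptance tests
docs/methods.md    model, generators, analyses, design choices, limits
```
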