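# Methods

This package implements an observer model of foreground detection in
background noise, the synthetic stimuli it is evaluated on, and the
psychophysical analysis stack (d′ curves, elbow fits, bootstrap and
permutation inference) used to characterize both model and simulated
behavioral data.

## The observer model

The model treats a foreground sound as a statistical outlier under a
continuously estimated model of the ongoing background.

**Front end.** A waveform is decomposed by a bank of bandpass filters with
half-cosine magnitude responses equally spaced on the ERB-rate axis
(defaults: 30 channels, 20 Hz–10 kHz, 20 kHz sampling). Subband envelopes
(magnitude of the analytic signal) are compressed with exponent 0.3 and
downsampled to a 200 Hz frame rate, yielding a cochleagram. A set of 2D
Gabor-like spectrotemporal kernels — parameterized by temporal rate (Hz),
spectral scale (cycles/octave) and up/down direction, each forced to zero
temporal mean and unit L2 norm — is convolved with the cochleagram
("same" in time; reflection-padded along frequency so activations exist at
every channel), and the outputs are magnitude-rectified. Temporal Gaussian
envelopes use σ = 0.4/rate, truncated at min(2σ, 200 ms) so low-rate
kernels remain usable on few-second stimuli; frames within half a kernel
support of the signal edges are flagged and excluded from all statistics.

The feature set passed to the detector additionally includes the
cochleagram channels themselves as "level" features — the lowpass corner
of the modulation-filter plane. This is a deliberate design choice: a
purely zero-temporal-mean kernel set is blind to local envelope level,
which is the dominant cue for a sustained foreground in an ongoing
texture, and a detector limited to such kernels is insensitive at
realistic SNRs.

**Sliding-window surprisal.** For each evaluation position, a univariate
Gaussian (sample mean and variance, variance floored at 10⁻⁶ of the
global activation variance) is fit per filter to the activations in a
"past" window (default 1,000 ms) that immediately precedes a disjoint
"present" window (default 500 ms). The per-filter surprisal is the mean
over present-window frames of −ln N(x; μ, σ²); the pooled trace is the
mean over filters. Evaluations advance in 25 ms hops and are timestamped
by the end of the present window. Before the past window has filled, it
grows from a 100 ms minimum, so the model operates — with noisier
estimates — from the earliest foreground onsets; this is what produces
the smooth rise of performance with onset time. The whole trace is
computed with cumulative sums (O(frames × filters)).

**Decision.** A stimulus is judged to contain a foreground when the
pooled surprisal exceeds a time-varying threshold for at least `k_consec`
consecutive evaluations (default 6, i.e. 150 ms of sustained evidence —
brief excursions of modulated textures are thereby discounted while
500 ms foregrounds pass easily). The threshold is calibrated empirically
on background-only stimuli. Two modes are provided:

- `pointwise`: the per-timepoint q-quantile of pooled surprisal across
  calibration traces (q = 0.99 by default; higher early, where past
  windows are short);
- `trial` (default): the pointwise-quantile curve shifted by a constant
  chosen so the fraction of *calibration trials* flagged equals 1 − q.
  This mode pins the per-trial false-alarm rate at the design target,
  which the pointwise construction alone does not (with ~100 correlated
  evaluations per trial, pointwise exceedances compound).

**Model experiments.** Experiment-scale runs use a desk-scale front end:
all 30 level channels plus rate-2 Hz up/down kernels at one channel
position. The full kernel inventory (rates 1–32 Hz × scales 0.25–2
cyc/oct × 2 directions at every 2nd channel) remains the module default
and is exercised by the frontend tests; the reduced inventory keeps a
full onset × SNR experiment (thousands of 3.25 s stimuli) within minutes
on one CPU while preserving the model's qualitative behavior. Model d′
uses a single false-alarm rate pooled over background-only trials and a
hit rate per (onset, SNR) condition, with the 1/(2N) extreme-rate
correction.

## Synthetic stimuli

**Texture backgrounds** (3.25 s) are sums over 14 ERB-spaced bands of
narrowband Gaussian carriers, each multiplied by a seeded unit-mean
lognormal envelope (log-SD 0.7) bandlimited to 0.5–8 Hz. The modulation
depth interpolates between stationary spectrally-shaped noise (0) and
fully modulated texture (1); experiment designs draw each background's
depth from U(0.4, 0.8), emulating the heterogeneous stationarity of a
diverse natural-texture set. Band gains default to a gentle pink tilt
with random smooth spectral bumps per exemplar. An optional event
generator adds sparse amplitude pulses for event-like textures; it is off
by default because sparse loud bursts read as foregrounds rather than
background texture. **Spectrally matched noise** transplants a source's
magnitude spectrum onto random phases at equal RMS, raising stationarity.

**Foregrounds** (0.5 s, raised-cosine 20 ms ramps) come in three kinds:
bandlimited noise bursts, logarithmic chirps, and harmonic complexes
(1/k partial rolloff). Burst and chirp kinds carry 4–16 Hz amplitude
modulation at depth 0.6; in trial sets, bursts occupy a random
~1.5-octave band (center log-uniform 300–4000 Hz). Both choices emulate
recorded natural sound excerpts, which are spectrally compact and
amplitude-modulated; a foreground with the background's own broadband
spectrum and flat envelope is nearly information-free at the studied
SNRs and would misrepresent the task. **Mixtures** scale the foreground
so that SNR is defined against the background RMS over the foreground's
temporal extent (meaningful for nonstationary noise); samples outside the
extent are bit-identical to the background. **Interrupters** replace the
middle 500 or 1,500 ms of a background with silence or RMS-matched white
noise.

**Trial sets** reproduce the experimental designs at configurable scale:
balanced assignment of backgrounds to the onset × SNR (× interrupter)
grid, one background-only trial per background, and repeated-background
block designs in which repetitions share the texture parameters but never
the waveform (fresh seed per repetition). The default grid is onsets
{250, …, 2500} ms × SNRs {−2, −6} dB.

**Synthetic behavior.** Trial tables are generated from an equal-variance
signal-detection model: condition sensitivity follows the elbow law
d′(t) = a + b·min(t, t_e), participants receive Gaussian offsets
(SD 0.3 by default), and a shared criterion (z = 1) fixes the false-alarm
rate; responses are Bernoulli. A vectorized variant
(`simulate_cohort_dprime`) returns participant × onset d′ matrices
directly for recovery and coverage studies over hundreds of cohorts.

## Analyses

d′ is z(hit) − z(false alarm) with extreme rates replaced by 1/(2N)
(log-linear correction available). Participant-level curves use one
false-alarm rate per participant. The elbow function — a rising segment
followed by an exactly flat plateau — is fit by grid search over the
breakpoint (default 5 ms step over the probed onset range) with (a, b)
solved in closed form per candidate; ties go to the earliest breakpoint,
and an all-flat curve therefore reports the earliest onset. The delay
benefit is the plateau minus the fitted value at the earliest probed
onset (250 ms; the designs never probe earlier). Bootstrap CIs for the
elbow resample participants with replacement (percentile intervals; the
SD of replicates is also reported). Group differences in elbow or delay
benefit are tested by shuffling participant-to-group labels, with
two-sided p = (k + 1)/(n_perm + 1). Asymptote matching greedily drops,
from the better group, the participant most extreme in the direction of
that group's advantage until late-onset (1,500–2,500 ms) means agree
within tolerance.

## Acoustic metrics

**Texture statistics** per cochlear channel: normalized envelope mean,
coefficient of variation, skewness, neighbor-channel correlations, and
modulation power in four octave rate bands (1–16 Hz) normalized by
channel variance; all entries are scale-free, so the derived stationarity
measure is gain-invariant. **Nonstationarity** is the SD of each
statistic across sliding windows (1,000 ms, 50% overlap), divided by that
statistic's reference dispersion — the median SD across a seeded corpus
of 50 generated textures spanning modulation depths 0 to 1 (a documented
stand-in for a natural-corpus normalization) — and averaged.
**Periodicity** is the frame-averaged maximum of the normalized waveform
autocorrelation over lags spanning 80–400 Hz, clipped to [0, 1]; silence
scores 0 by convention. **Spectrotemporal similarity** is the mean of the
cosine similarities of two standardized feature blocks — the excitation
pattern and the excitation-weighted modulation power per (channel, rate
band) — computed per sound; excitation weighting prevents silent channels
from aligning spuriously.

## Numerical and design notes

- Every stochastic stage takes an explicit seed; a master seed fans out
  to stage seeds via CRC32(stage name) through a `SeedSequence`, folded
  below 2³¹.
- Window lengths in frames are rounded from ms at the frame rate; sample
  variance uses ddof = 1; the variance floor guards silent or constant
  channels (the silence path is exercised in tests).
- Threshold calibration requires at least 20 background-only traces;
  study-scale runs use 300–500.
- Analysis problem sizes (40 backgrounds per replicate set, 6–20
  replicate sets, 300–500 calibration traces, 200 simulated cohorts,
  500 null simulations) are the package's desk-scale choices; they keep
  every scripted analysis within minutes on one CPU.

## What the synthetic data do and do not show

The generators reproduce the *structure* of the studied conditions —
texture-like backgrounds with controllable stationarity, brief compact
foregrounds of controllable harmonicity, onset × SNR designs with
balanced assignment, behavioral data following a rise-then-plateau law —
but not the acoustics of any particular natural texture or sound class:
band envelopes are independent lognormals, cross-band correlations and
higher-order texture statistics are not imposed, and foreground classes
are stylized. Passing tests therefore demonstrate that the model and the
analysis stack behave correctly under the stated statistical conditions,
not that the model attains human (or the original model's) absolute
performance on natural recordings. Model d′ at the studied SNRs is below
typical human performance, and with ~40 trials per condition the
per-condition d′ estimates carry sampling noise of roughly 0.2 d′, which
dominates the run-to-run scatter of rank correlations and fitted elbow
locations at that scale.

## Known limitations

- The Gaussian noise model is univariate per filter: cross-filter
  correlations and temporal dependencies beyond the kernel width are
  ignored, and no noise prior is carried across trials, so
  repeated-background enhancement is outside the model's scope (the
  behavioral analyses cover it via the synthetic-behavior generator).
- The threshold is global across backgrounds; heterogeneous background
  stationarity therefore compresses attainable hit rates at a fixed
  false-alarm rate.
- Foreground property estimation (separating the foreground from the
  mixture) is not attempted; the model only detects.
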