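"""Synthetic stimulus generation: texture backgrounds, foregrounds, mixtures.

Backgrounds are texture-like noises built as a sum of ERB-spaced narrowband
noise carriers, each amplitude-modulated by a seeded lognormal envelope.
The modulation depth and (optional) discrete amplitude events control how
stationary the texture is; the per-band gains control its long-term
spectrum.  Spectrally matched noise shares a source's magnitude spectrum
with randomized phase.  Foregrounds are brief (0.5 s) bursts, chirps or
harmonic complexes.  Trial-set builders reproduce the block designs of the
behavioral experiments (onset x SNR grids, interrupters, repeated
backgrounds) at configurable scale, and a synthetic-behavior generator
produces trial tables whose sensitivity follows a rise-then-plateau
(elbow) law with participant-level variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt
from scipy.stats import norm

from .frontend import Waveform, design_filterbank

DEFAULT_SR = 20_000.0
DEFAULT_BG_DUR = 3.25
DEFAULT_FG_DUR = 0.5
_TARGET_RMS = 0.05


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class TextureSpec:
    """Parameters of one texture-like background exemplar."""

    seed: int
    duration: float = DEFAULT_BG_DUR
    sample_rate: float = DEFAULT_SR
    band_gains: np.ndarray = None      # per-band spectrum shape; None -> pink-ish
    mod_depth: float = 0.5             # 0 = stationary noise, 1 = fully modulated
    mod_sigma: float = 0.7             # log-SD of the lognormal modulation envelope
    mod_rate_range: tuple = (0.5, 8.0)  # Hz band of the modulation envelopes
    event_density: float = 0.0         # discrete amplitude events per second
    n_bands: int = 14
    f_lo: float = 50.0
    f_hi: float = 8000.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (0.0 <= self.mod_depth <= 1.0):
            raise ValueError("mod_depth must lie in [0, 1]")


@dataclass
class ForegroundSpec:
    """Parameters of one 0.5-s foreground event."""

    seed: int
    duration: float = DEFAULT_FG_DUR
    sample_rate: float = DEFAULT_SR
    kind: str = "noise_burst"          # noise_burst | chirp | harmonic
    f0: float = 200.0                  # fundamental (harmonic kind)
    n_harmonics: int = 10
    band: tuple = (200.0, 6000.0)      # passband of noise bursts
    ramp_ms: float = 20.0
    am_depth: float = 0.6              # amplitude modulation of burst/chirp kinds
    am_rate_range: tuple = (4.0, 16.0)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.kind == "harmonic" and self.f0 <= 0:
            raise ValueError("harmonic foreground requires f0 > 0")
        if self.kind not in ("noise_burst", "chirp", "harmonic"):
            raise ValueError(f"unknown foreground kind: {self.kind}")


@dataclass
class TrialSpec:
    """Condition labels of one trial."""

    onset_ms: float = None             # None on background-only trials
    snr_db: float = None
    interrupter: str = "none"          # none | silence | white_noise
    interrupter_ms: float = 0.0
    background_id: int = 0
    foreground_id: int = None          # None on background-only trials
    block: int = None
    repeat: bool = False

    def __post_init__(self) -> None:
        if self.foreground_id is not None and (
            self.onset_ms is None or self.onset_ms < 250
        ):
            raise ValueError("foreground onset must be >= 250 ms")
        if self.interrupter not in ("none", "silence", "white_noise"):
            raise ValueError(f"unknown interrupter: {self.interrupter}")


# ---------------------------------------------------------------------------
# waveform generators
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _band_noise(rng, n, resp_row) -> np.ndarray:
    """Gaussian noise shaped by one band's magnitude response, synthesized
    in the frequency domain (random complex spectrum x response)."""
    nf = len(resp_row)
    a = rng.standard_normal(nf) + 1j * rng.standard_normal(nf)
    a[0] = a[0].real
    if n % 2 == 0:
        a[-1] = a[-1].real
    return np.fft.irfft(a * resp_row * np.sqrt(n / 2), n=n)


def _mod_envelope(rng, n, sr, rate_range, depth, sigma=1.0) -> np.ndarray:
    """Seeded lognormal modulation envelope with unit mean.

    Synthesized at a low control rate (modulation rates are a few Hz) and
    linearly interpolated to the audio rate.
    """
    lo, hi = rate_range
    ctrl_sr = max(50.0, 8 * hi)
    m = int(np.ceil(n / sr * ctrl_sr)) + 2
    z = rng.standard_normal(m)
    nyq = ctrl_sr / 2
    sos = butter(2, [max(lo, 1e-3) / nyq, min(hi, nyq * 0.99) / nyq],
                 btype="band", output="sos")
    z = sosfiltfilt(sos, z)
    s = z.std()
    if s > 0:
        z = z / s
    raw = np.exp(sigma * z - sigma**2 / 2)  # unit-mean lognormal
    env = np.interp(np.arange(n) / sr, np.arange(m) / ctrl_sr, raw)
    return (1.0 - depth) + depth * env


def gen_texture_background(spec: TextureSpec) -> Waveform:
    """Generate one texture exemplar: modulated narrowband noise in ERB bands."""
    rng = _rng(spec.seed)
    sr = spec.sample_rate
    n = int(round(spec.duration * sr))
    fb = design_filterbank(spec.n_bands, spec.f_lo, spec.f_hi, sr)
    freqs = np.fft.rfftfreq(n, d=1.0 / sr)
    resp = fb.response(freqs)
    gains = spec.band_gains
    if gains is None:
        gains = fb.center_freqs ** -0.25  # gentle pink tilt
    gains = np.asarray(gains, dtype=float)
    if len(gains) != spec.n_bands:
        raise ValueError("band_gains length must equal n_bands")

    t = np.arange(n) / sr
    x = np.zeros(n)
    for b in range(spec.n_bands):
        carrier = _band_noise(rng, n, resp[b])
        env = _mod_envelope(rng, n, sr, spec.mod_rate_range, spec.mod_depth,
                            sigma=spec.mod_sigma)
        if spec.event_density > 0:
            n_ev = rng.poisson(spec.event_density * spec.duration)
            for _ in range(n_ev):
                t0 = rng.uniform(0, spec.duration)
                w = rng.uniform(0.02, 0.08)
                amp = rng.uniform(2.0, 5.0)
                env = env + amp * np.exp(-((t - t0) ** 2) / (2 * w**2))
        x += gains[b] * carrier * env
    r = np.sqrt(np.mean(x**2))
    if r > 0:
        x *= _TARGET_RMS / r
    return Waveform(x, sr)


def gen_spectrally_matched_noise(source: Waveform, seed: int) -> Waveform:
    """Noise with the source's magnitude spectrum and randomized phase."""
    if len(source.samples) == 0:
        raise ValueError("empty source waveform")
    rng = _rng(seed)
    n = len(source.samples)
    mag = np.abs(np.fft.rfft(source.samples))
    phase = rng.uniform(0, 2 * np.pi, len(mag))
    phase[0] = 0.0
    if n % 2 == 0:
        phase[-1] = 0.0
    y = np.fft.irfft(mag * np.exp(1j * phase), n=n)
    r = np.sqrt(np.mean(y**2))
    if r > 0:
        y *= source.rms / r
    return Waveform(y, source.sample_rate)


def _ramp(n_samples: int, ramp_n: int) -> np.ndarray:
    env = np.ones(n_samples)
    ramp_n = min(ramp_n, n_samples // 2)
    if ramp_n > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        env[:ramp_n] = r
        env[-ramp_n:] = r[::-1]
    return env


def gen_foreground(spec: ForegroundSpec) -> Waveform:
    """Generate one foreground event with raised-cosine onset/offset ramps."""
    rng = _rng(spec.seed)
    sr = spec.sample_rate
    n = int(round(spec.duration * sr))
    t = np.arange(n) / sr
    if spec.kind == "noise_burst":
        x = rng.standard_normal(n)
        freqs = np.fft.rfftfreq(n, d=1.0 / sr)
        lo, hi = spec.band
        # smooth-edged brickwall passband
        edge = (hi - lo) * 0.1
        mask = np.clip((freqs - lo) / edge, 0, 1) * np.clip((hi - freqs) / edge, 0, 1)
        x = np.fft.irfft(np.fft.rfft(x) * mask, n=n)
    elif spec.kind == "chirp":
        f_start = rng.uniform(300, 600)
        f_end = f_start * 4
        phi = 2 * np.pi * f_start * (spec.duration / np.log(f_end / f_start)) * (
            np.exp(t / spec.duration * np.log(f_end / f_start)) - 1
        )
        x = np.sin(phi + rng.uniform(0, 2 * np.pi))
    else:  # harmonic complex, 1/k amplitude rolloff
        x = np.zeros(n)
        for k in range(1, spec.n_harmonics + 1):
            fk = k * spec.f0
            if fk >= sr / 2:
                break
            x += np.cos(2 * np.pi * fk * t + rng.uniform(0, 2 * np.pi)) / k
    if spec.kind != "harmonic" and spec.am_depth > 0:
        # natural 0.5-s events are amplitude-modulated; steady tones are not
        rate = rng.uniform(*spec.am_rate_range)
        x = x * (1 + spec.am_depth * np.sin(2 * np.pi * rate * t
                                            + rng.uniform(0, 2 * np.pi)))
    x = x * _ramp(n, int(round(spec.ramp_ms / 1000 * sr)))
    r = np.sqrt(np.mean(x**2))
    if r > 0:
        x *= _TARGET_RMS / r
    return Waveform(x, sr)


def mix_at_snr(fg: Waveform, bg: Waveform, snr_db: float, onset_ms: float) -> Waveform:
    """Add the foreground to the background at the stated SNR and onset.

    SNR is defined against the background RMS measured over the
    foreground's temporal extent (meaningful for nonstationary noise).
    Samples outside the foreground extent are returned unchanged.
    """
    if fg.sample_rate != bg.sample_rate:
        raise ValueError("sample rates differ")
    if onset_ms < 250:
        raise ValueError("foreground onset must be >= 250 ms")
    sr = bg.sample_rate
    i0 = int(round(onset_ms / 1000 * sr))
    i1 = i0 + len(fg.samples)
    if i1 > len(bg.samples):
        raise ValueError("foreground overruns the background")
    rms_bg = np.sqrt(np.mean(bg.samples[i0:i1] ** 2))
    rms_fg = np.sqrt(np.mean(fg.samples**2))
    if rms_fg == 0:
        raise ValueError("silent foreground")
    scale = rms_bg * 10 ** (snr_db / 20) / rms_fg
    out = bg.samples.copy()
    out[i0:i1] += scale * fg.samples
    return Waveform(out, sr)


def insert_interrupter(
    bg: Waveform, kind: str, dur_ms: float, position: str = "middle", seed: int = 0
) -> Waveform:
    """Replace a middle segment of the background with silence or white noise.

    The white-noise interrupter is RMS-matched to the background; total
    duration is unchanged.
    """
    n = len(bg.samples)
    m = int(round(dur_ms / 1000 * bg.sample_rate))
    if m >= n:
        raise ValueError("interrupter as long as the background")
    if m == 0:
        return Waveform(bg.samples.copy(), bg.sample_rate)
    if position != "middle":
        raise ValueError("only middle placement is supported")
    i0 = (n - m) // 2
    out = bg.samples.copy()
    if kind == "silence":
        out[i0 : i0 + m] = 0.0
    elif kind == "white_noise":
        w = _rng(seed).standard_normal(m)
        out[i0 : i0 + m] = w / np.sqrt(np.mean(w**2)) * bg.rms
    else:
        raise ValueError(f"unknown interrupter kind: {kind}")
    return Waveform(out, bg.sample_rate)


# ---------------------------------------------------------------------------
# experiment designs and trial sets
# ---------------------------------------------------------------------------

@dataclass
class ExperimentDesign:
    """Descriptor of one experiment's stimulus design."""

    name: str
    n_backgrounds: int = 160
    onsets_ms: tuple = tuple(range(250, 2501, 250))
    snrs_db: tuple = (-2.0, -6.0)
    background: str = "texture"        # texture | matched
    foreground_kind: str = "noise_burst"
    interrupters: tuple = ("none",)    # conditions crossed with onset x snr
    interrupter_ms: float = 0.0
    repeat: str = "none"               # none | every_trial | every_other
    block_size: int = 40
    duration: float = DEFAULT_BG_DUR
    sample_rate: float = DEFAULT_SR
    # per-background modulation depth range: exemplars span moderately
    # stationary to strongly modulated, like a diverse natural texture set
    mod_depth: tuple = (0.4, 0.8)
    event_density: float = 0.0


_PRESETS = {
    "exp1": {},
    "exp5a": {"interrupters": ("silence", "white_noise"), "interrupter_ms": 500.0},
    "exp5b": {"interrupters": ("silence", "white_noise"), "interrupter_ms": 1500.0},
    "exp6": {"repeat": "every_trial", "snrs_db": (-6.0,)},
    "exp7": {"snrs_db": (-6.0,)},
    "exp8": {"repeat": "every_other", "snrs_db": (-6.0,)},
    "exp9": {"background": "matched", "snrs_db": (-4.0, -8.0)},
    "exp10": {"foreground_kind": "harmonic", "snrs_db": (-6.0,)},
}


def experiment_design(name: str, **overrides) -> ExperimentDesign:
    """Build a named experiment descriptor (exp1, exp5a/b, exp6-10)."""
    if name not in _PRESETS:
        raise ValueError(f"unknown experiment {name!r}; choose from {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[name])
    kwargs.update(overrides)
    return ExperimentDesign(name=name, **kwargs)


def _foreground_spec(design: ExperimentDesign, rng: np.random.Generator) -> ForegroundSpec:
    """Draw one foreground spec.  Generated events are spectrally compact
    (a random ~1.5-octave band or a harmonic complex), like the natural
    sound excerpts they emulate; a texture-spectrum-wide noise foreground
    would carry almost no information beyond overall level."""
    fc = float(np.exp(rng.uniform(np.log(300.0), np.log(4000.0))))
    return ForegroundSpec(
        seed=int(rng.integers(2**31)),
        sample_rate=design.sample_rate,
        kind=design.foreground_kind,
        f0=float(rng.uniform(120, 320)),
        band=(fc / 2**0.75, fc * 2**0.75),
    )


def _background_spec(design: ExperimentDesign, rng: np.random.Generator) -> TextureSpec:
    """Draw one background TextureSpec (random smooth spectrum per exemplar)."""
    fb = design_filterbank(14, 50.0, 8000.0, design.sample_rate)
    tilt = fb.center_freqs ** rng.uniform(-0.4, -0.1)
    bumps = np.exp(0.5 * rng.standard_normal(3))
    centers = rng.uniform(0, 13, 3)
    shape = tilt * (
        1 + sum(b * np.exp(-((np.arange(14) - c) ** 2) / 8) for b, c in zip(bumps, centers))
    )
    depth = design.mod_depth
    if isinstance(depth, tuple):
        depth = float(rng.uniform(*depth))
    return TextureSpec(
        seed=int(rng.integers(2**31)),
        duration=design.duration,
        sample_rate=design.sample_rate,
        band_gains=shape / shape.max(),
        mod_depth=depth,
        event_density=design.event_density,
    )


def _render_background(
    spec: TextureSpec, design: ExperimentDesign, rng: np.random.Generator
) -> Waveform:
    bg = gen_texture_background(spec)
    if design.background == "matched":
        bg = gen_spectrally_matched_noise(bg, seed=int(rng.integers(2**31)))
    return bg


def build_trial_set(design: ExperimentDesign, master_seed: int) -> list:
    """Build the (Waveform, TrialSpec) list for one experiment run.

    Foreground-bearing trials are balanced across the condition grid
    (onset x SNR x interrupter); every background also occurs once without
    a foreground.  Repeat designs reuse the background TextureSpec within
    a block but draw a fresh exemplar (new seed) on every repetition, so
    repeated trials share statistics but never waveform samples.
    """
    rng = _rng(master_seed)
    conditions = [
        (o, s, it)
        for it in design.interrupters
        for s in design.snrs_db
        for o in design.onsets_ms
    ]
    n_cond = len(conditions)
    if design.n_backgrounds % n_cond != 0:
        raise ValueError(
            f"n_backgrounds={design.n_backgrounds} not divisible by "
            f"{n_cond} conditions"
        )
    if design.repeat == "none":
        specs = [_background_spec(design, rng) for _ in range(design.n_backgrounds)]
        assignment = np.repeat(np.arange(n_cond), design.n_backgrounds // n_cond)
        rng.shuffle(assignment)
        trials = []
        for bg_id, (spec, ci) in enumerate(zip(specs, assignment)):
            onset, snr, interrupter = conditions[ci]
            bg = _render_background(spec, design, rng)
            if interrupter != "none":
                bg = insert_interrupter(
                    bg, interrupter, design.interrupter_ms, seed=int(rng.integers(2**31))
                )
            fg = gen_foreground(_foreground_spec(design, rng))
            mix = mix_at_snr(fg, bg, snr, onset)
            trials.append(
                (mix, TrialSpec(onset, snr, interrupter, design.interrupter_ms,
                                bg_id, foreground_id=bg_id))
            )
            # the same background once more, without a foreground
            bg2 = _render_background(replace(spec, seed=int(rng.integers(2**31))),
                                     design, rng)
            if interrupter != "none":
                bg2 = insert_interrupter(
                    bg2, interrupter, design.interrupter_ms,
                    seed=int(rng.integers(2**31)),
                )
            trials.append((bg2, TrialSpec(background_id=bg_id,
                                          interrupter=interrupter,
                                          interrupter_ms=design.interrupter_ms)))
        return trials

    # repeated-background block designs (exp6: every trial; exp8: every other)
    n_blocks = max(design.n_backgrounds // design.block_size, 1)
    trials = []
    fg_count = 0
    for block in range(n_blocks):
        block_spec = _background_spec(design, rng)
        order = [conditions[i % n_cond] for i in range(design.block_size)]
        rng.shuffle(order)
        for k, (onset, snr, interrupter) in enumerate(order):
            repeating = design.repeat == "every_trial" or (
                design.repeat == "every_other" and k % 2 == 0
            )
            spec = (
                replace(block_spec, seed=int(rng.integers(2**31)))
                if repeating
                else _background_spec(design, rng)
            )
            bg = _render_background(spec, design, rng)
            is_fg = rng.uniform() > 0.25  # ~25% background-only catch trials
            if is_fg:
                fg = gen_foreground(_foreground_spec(design, rng))
                mix = mix_at_snr(fg, bg, snr, onset)
                trials.append(
                    (mix, TrialSpec(onset, snr, interrupter, design.interrupter_ms,
                                    block * design.block_size + k,
                                    foreground_id=fg_count, block=block,
                                    repeat=repeating))
                )
                fg_count += 1
            else:
                trials.append(
                    (bg, TrialSpec(background_id=block * design.block_size + k,
                                   block=block, repeat=repeating))
                )
    return trials


# ---------------------------------------------------------------------------
# synthetic behavior
# ---------------------------------------------------------------------------

def elbow_curve(onsets_ms, a: float, b: float, t_e: float) -> np.ndarray:
    """Rise-then-plateau sensitivity law: d'(t) = a + b * min(t, t_e)."""
    t = np.asarray(onsets_ms, dtype=float)
    return a + b * np.minimum(t, t_e)


def gen_synthetic_behavior(
    curve_params: dict,
    n_participants: int,
    trials_per_condition: int,
    n_noise_trials: int,
    seed: int,
    criterion: float = 1.0,
    participant_sd: float = 0.3,
    onsets_ms: tuple = tuple(range(250, 2501, 250)),
    background_type: str = "texture",
) -> pd.DataFrame:
    """Simulate a behavioral trial table under an equal-variance SDT model.

    ``curve_params`` maps a condition label (e.g. SNR in dB) to elbow
    parameters (a, b, t_e) in d' units (b per ms).  Each participant gets a
    Gaussian random offset (SD ``participant_sd``) added to every condition
    d'; hit P = Phi(d' - c), false-alarm P = Phi(-c) with shared criterion
    c.  Responses are Bernoulli per trial; the output schema matches real
    trial tables (one row per trial).
    """
    rng = _rng(seed)
    rows = []
    for p in range(n_participants):
        u = rng.normal(0, participant_sd)
        fa_p = norm.cdf(-criterion)
        for label, (a, b, t_e) in curve_params.items():
            for onset in onsets_ms:
                d = a + b * min(onset, t_e) + u
                ph = norm.cdf(d - criterion)
                resp = rng.uniform(size=trials_per_condition) < ph
                for r in resp:
                    rows.append((p, onset, label, background_type, True, bool(r)))
        resp = rng.uniform(size=n_noise_trials) < fa_p
        for r in resp:
            rows.append((p, np.nan, np.nan, background_type, False, bool(r)))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "onset_ms", "snr_db", "background_type",
                 "foreground_present", "response"],
    )


def simulate_cohort_dprime(
    curve_params: dict,
    n_participants: int,
    trials_per_condition: int,
    n_noise_trials: int,
    seed: int,
    criterion: float = 1.0,
    participant_sd: float = 0.3,
    onsets_ms: tuple = tuple(range(250, 2501, 250)),
    correction: str = "half",
):
    """Vectorized cohort simulator returning the participants x onsets d'
    matrix directly (d' averaged over the condition labels in
    ``curve_params``), under the same SDT model as gen_synthetic_behavior.

    Used for recovery/coverage studies where materializing trial-level
    tables for hundreds of cohorts would dominate the runtime.
    """
    from scipy.stats import norm as _norm

    rng = _rng(seed)
    onsets = np.asarray(onsets_ms, dtype=float)
    u = rng.normal(0, participant_sd, size=n_participants)
    fa_k = rng.binomial(n_noise_trials, _norm.cdf(-criterion), size=n_participants)
    fa_rate = np.clip(fa_k / n_noise_trials, 1 / (2 * n_noise_trials),
                      1 - 1 / (2 * n_noise_trials))
    n = trials_per_condition
    d_mats = []
    for a, b, t_e in curve_params.values():
        d = a + b * np.minimum(onsets, t_e)[None, :] + u[:, None]
        hits = rng.binomial(n, _norm.cdf(d - criterion))
        if correction == "half":
            h = np.clip(hits / n, 1 / (2 * n), 1 - 1 / (2 * n))
        else:
            h = (hits + 0.5) / (n + 1)
        d_mats.append(_norm.ppf(h) - _norm.ppf(fa_rate)[:, None])
    return onsets, np.mean(d_mats, axis=0)
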