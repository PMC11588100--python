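"""Auditory front end: cochleagram and spectrotemporal feature extraction.

A waveform is decomposed by a bank of cochlea-like bandpass filters
(half-cosine magnitude responses on an ERB-rate axis), the subband
envelopes are extracted (magnitude of the analytic signal), compressed
with a power-law nonlinearity and downsampled to a frame rate suitable
for texture statistics, yielding a cochleagram.  A second stage convolves
the cochleagram with 2D Gabor-like spectrotemporal kernels (parameterised
by temporal rate in Hz, spectral scale in cycles/octave and direction),
yielding time-varying feature activations on which background-noise
statistics are estimated downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, resample_poly


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Waveform:
    """A mono pressure signal with its sample rate in Hz."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2))) if len(self.samples) else 0.0


@dataclass
class Filterbank:
    """Bandpass filterbank with half-cosine magnitude responses on the ERB-rate axis.

    ``response(freqs)`` evaluates the n_channels x len(freqs) magnitude
    transfer functions.  The lowest and highest channels carry flat
    shoulders toward DC and Nyquist respectively, so the summed squared
    response is 1 across the design band [f_lo, f_hi].
    """

    n_channels: int
    f_lo: float
    f_hi: float
    sample_rate: float
    center_freqs: np.ndarray = field(init=False)
    _erb_centers: np.ndarray = field(init=False, repr=False)
    _erb_spacing: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi <= self.sample_rate / 2):
            raise ValueError(
                f"require 0 < f_lo < f_hi <= nyquist; got f_lo={self.f_lo}, "
                f"f_hi={self.f_hi}, sample_rate={self.sample_rate}"
            )
        if self.n_channels < 4:
            raise ValueError("n_channels must be >= 4")
        e_lo, e_hi = erb_rate(self.f_lo), erb_rate(self.f_hi)
        pts = np.linspace(e_lo, e_hi, self.n_channels + 2)
        self._erb_centers = pts[1:-1]
        self._erb_spacing = pts[1] - pts[0]
        self.center_freqs = inverse_erb_rate(self._erb_centers)

    def response(self, freqs: np.ndarray) -> np.ndarray:
        """Magnitude response of every channel at the given frequencies (Hz)."""
        e = erb_rate(np.maximum(np.asarray(freqs, dtype=np.float64), 0.0))
        d = (e[None, :] - self._erb_centers[:, None]) / self._erb_spacing
        resp = np.where(np.abs(d) <= 1.0, np.cos(np.pi / 2 * d), 0.0)
        # flat shoulders: lowest channel passes everything below its center,
        # highest everything above, keeping sum-of-squares flat on [f_lo, f_hi]
        resp[0] = np.where(d[0] < 0, 1.0, resp[0])
        resp[-1] = np.where(d[-1] > 0, 1.0, resp[-1])
        return resp


@dataclass
class Cochleagram:
    """Time x channel array of compressed subband envelopes."""

    env: np.ndarray  # (n_frames, n_channels), nonnegative
    frame_rate: float
    center_freqs: np.ndarray

    def __post_init__(self) -> None:
        self.env = np.asarray(self.env, dtype=np.float64)
        if self.env.ndim != 2:
            raise ValueError("cochleagram env must be 2D (time x channel)")

    @property
    def n_frames(self) -> int:
        return self.env.shape[0]

    @property
    def n_channels(self) -> int:
        return self.env.shape[1]

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 0.5) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class ModFilterSet:
    """Set of 2D spectrotemporal kernels indexed by (rate Hz, scale cyc/oct, direction)."""

    kernels: list[np.ndarray]         # each (n_t, n_f), zero temporal mean
    params: list[tuple[float, float, str]]
    frame_rate: float
    octaves_per_channel: float

    @property
    def max_half_support(self) -> int:
        """Largest temporal half-width (frames) over kernels; edge-exclusion radius."""
        return max(k.shape[0] // 2 for k in self.kernels)


@dataclass
class FeatureActivations:
    """Time x filter activations sharing the source cochleagram's frame rate.

    ``valid`` marks frames further than half a kernel support from the
    signal edges; only those frames enter downstream statistics.
    """

    act: np.ndarray  # (n_frames, n_filters)
    frame_rate: float
    filter_index: list[tuple]
    valid: np.ndarray = None  # boolean (n_frames,)

    def __post_init__(self) -> None:
        self.act = np.asarray(self.act, dtype=np.float64)
        if self.valid is None:
            self.valid = np.ones(self.act.shape[0], dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.act.shape[0]

    @property
    def n_filters(self) -> int:
        return self.act.shape[1]

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 0.5) / self.frame_rate


# ---------------------------------------------------------------------------
# ERB scale
# ---------------------------------------------------------------------------

def erb_rate(f_hz):
    """Frequency (Hz) -> ERB-rate (Glasberg & Moore)."""
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f_hz, dtype=np.float64))


def inverse_erb_rate(e):
    """ERB-rate -> frequency (Hz)."""
    return (10.0 ** (np.asarray(e, dtype=np.float64) / 21.4) - 1.0) / 0.00437


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

@dataclass
class FrontendConfig:
    """Bundled front-end parameters with cached filter designs.

    ``features(w)`` runs waveform -> cochleagram -> activations in one call;
    the filterbank and kernel set are built once per config instance.
    """

    n_channels: int = 30
    f_lo: float = 20.0
    f_hi: float = 10_000.0
    sample_rate: float = 20_000.0
    compression_exponent: float = 0.3
    frame_rate: float = 200.0
    rates: tuple = (1, 2, 4, 8, 16, 32)
    scales: tuple = (0.25, 0.5, 1, 2)
    directions: tuple = ("up", "down")
    channel_stride: int = 2
    rectify: bool = True
    include_level: bool = True
    level_stride: int = 1

    def __post_init__(self) -> None:
        self._fb = None
        self._mods = None

    @property
    def filterbank(self) -> "Filterbank":
        if self._fb is None:
            self._fb = design_filterbank(
                self.n_channels, self.f_lo, self.f_hi, self.sample_rate
            )
        return self._fb

    @property
    def mod_filters(self) -> "ModFilterSet":
        if self._mods is None:
            self._mods = design_mod_filters(
                self.rates, self.scales, self.directions,
                frame_rate=self.frame_rate, n_channels=self.n_channels,
                f_lo=self.f_lo, f_hi=self.f_hi,
            )
        return self._mods

    def cochleagram(self, w: Waveform) -> "Cochleagram":
        return compute_cochleagram(
            w, self.filterbank, self.compression_exponent, self.frame_rate
        )

    def features(self, w: Waveform) -> "FeatureActivations":
        """Feature activations: spectrotemporal-filter outputs, optionally
        augmented with the cochleagram channels themselves ("level"
        features - the lowpass corner of the modulation filter plane),
        which carry the local envelope level that zero-mean bandpass
        kernels discard."""
        c = self.cochleagram(w)
        act = apply_mod_filters(c, self.mod_filters, self.rectify,
                                self.channel_stride)
        if not self.include_level:
            return act
        keep = np.arange(0, c.n_channels, self.level_stride)
        level_idx = [("level", 0.0, "none", int(i)) for i in keep]
        return FeatureActivations(
            np.concatenate([c.env[:, keep], act.act], axis=1),
            act.frame_rate, level_idx + act.filter_index, act.valid,
        )


def design_filterbank(
    n_channels: int = 30,
    f_lo: float = 20.0,
    f_hi: float = 10_000.0,
    sample_rate: float = 20_000.0,
) -> Filterbank:
    """Design an ERB-spaced half-cosine filterbank covering [f_lo, f_hi]."""
    return Filterbank(n_channels, f_lo, f_hi, sample_rate)


def _subband_envelopes(w: Waveform, fb: Filterbank) -> np.ndarray:
    """Hilbert envelopes of each subband, (n_samples, n_channels).

    The analytic subbands are formed in one pass: the signal's FFT is
    weighted by the filter responses and the Hilbert one-sided weights
    (2 on positive frequencies, 1 at DC/Nyquist, 0 on negatives), then
    inverse-transformed per channel.
    """
    n = len(w.samples)
    cache = getattr(fb, "_resp_cache", None)
    if cache is None:
        cache = fb._resp_cache = {}
    key = (n, w.sample_rate)
    if key not in cache:
        freqs = np.abs(np.fft.fftfreq(n, d=1.0 / w.sample_rate))
        resp = fb.response(freqs)  # (C, n)
        weights = np.zeros(n)
        half = n // 2
        weights[0] = 1.0
        if n % 2 == 0:
            weights[1:half] = 2.0
            weights[half] = 1.0
        else:
            weights[1 : half + 1] = 2.0
        cache[key] = resp * weights
    spec = np.fft.fft(w.samples)
    analytic = np.fft.ifft(spec[None, :] * cache[key], axis=1)  # (C, n)
    return np.abs(analytic).T


def compute_cochleagram(
    w: Waveform,
    fb: Filterbank,
    compression_exponent: float = 0.3,
    frame_rate: float = 200.0,
) -> Cochleagram:
    """Cochleagram: compressed subband envelopes downsampled to frame_rate."""
    if len(w.samples) == 0:
        raise ValueError("cannot compute cochleagram of an empty waveform")
    if w.sample_rate > fb.sample_rate:
        raise ValueError("waveform sample rate exceeds filterbank design rate")
    env = _subband_envelopes(w, fb) ** compression_exponent
    decim = w.sample_rate / frame_rate
    if abs(decim - round(decim)) > 1e-9:
        raise ValueError("sample_rate must be an integer multiple of frame_rate")
    env = resample_poly(env, up=1, down=int(round(decim)), axis=0)
    return Cochleagram(np.maximum(env, 0.0), frame_rate, fb.center_freqs)


def excitation_pattern(c: Cochleagram) -> np.ndarray:
    """Per-channel time average of the cochleagram."""
    if c.n_frames == 0:
        raise ValueError("empty cochleagram")
    return c.env.mean(axis=0)


def design_mod_filters(
    rates: list[float] = (1, 2, 4, 8, 16, 32),
    scales: list[float] = (0.25, 0.5, 1, 2),
    directions: tuple[str, ...] = ("up", "down"),
    frame_rate: float = 200.0,
    octaves_per_channel: float = None,
    n_channels: int = 30,
    f_lo: float = 20.0,
    f_hi: float = 10_000.0,
    max_half_support_s: float = 0.2,
) -> ModFilterSet:
    """Build Gabor-like spectrotemporal kernels, one per (rate, scale, direction).

    The temporal Gaussian envelope has sigma = 0.4 / rate, truncated at
    min(2 sigma, max_half_support_s) so low-rate kernels stay usable on
    few-second stimuli.  Scales in cycles/octave are mapped to cycles per
    cochlear channel through the mean channel spacing in octaves.  Kernels
    are forced to zero temporal mean per spectral slice and unit L2 norm.
    """
    rates, scales = list(rates), list(scales)
    if not rates or not scales:
        raise ValueError("rates and scales must be nonempty")
    if any(r <= 0 for r in rates) or any(s <= 0 for s in scales):
        raise ValueError("rates and scales must be positive")
    if octaves_per_channel is None:
        octaves_per_channel = np.log2(f_hi / f_lo) / n_channels
    kernels, params = [], []
    for rate in rates:
        sigma_t = 0.4 / rate
        half_t = min(2 * sigma_t, max_half_support_s)
        nt = max(int(round(half_t * frame_rate)), 2)
        t = np.arange(-nt, nt + 1) / frame_rate
        for scale in scales:
            cyc_per_chan = scale * octaves_per_channel
            sigma_x = 0.5 / cyc_per_chan
            nx = max(int(np.ceil(2 * sigma_x)), 1)
            x = np.arange(-nx, nx + 1)
            for direction in directions:
                sgn = 1.0 if direction == "up" else -1.0
                carrier = np.cos(
                    2 * np.pi * (rate * t[:, None] + sgn * cyc_per_chan * x[None, :])
                )
                envelope = np.exp(-(t[:, None] ** 2) / (2 * sigma_t**2)) * np.exp(
                    -(x[None, :] ** 2) / (2 * sigma_x**2)
                )
                k = carrier * envelope
                k = k - k.mean(axis=0, keepdims=True)  # zero temporal mean
                k /= np.linalg.norm(k)
                kernels.append(k)
                params.append((float(rate), float(scale), direction))
    return ModFilterSet(kernels, params, frame_rate, octaves_per_channel)


def apply_mod_filters(
    c: Cochleagram,
    m: ModFilterSet,
    rectify: bool = True,
    channel_stride: int = 2,
) -> FeatureActivations:
    """Convolve the cochleagram with each spectrotemporal kernel.

    Convolution is 'same' in time; along frequency the cochleagram is
    reflection-padded by each kernel's half-width so activations exist at
    all channels, then subsampled to every ``channel_stride``-th channel.
    Frames within half a kernel support of the edges are flagged invalid.
    """
    if abs(c.frame_rate - m.frame_rate) > 1e-9:
        raise ValueError("cochleagram and kernel frame rates differ")
    if any(k.shape[0] > c.n_frames for k in m.kernels):
        raise ValueError("cochleagram shorter than a kernel's temporal support")
    keep = np.arange(0, c.n_channels, channel_stride)
    cols, index = [], []
    for k, p in zip(m.kernels, m.params):
        nx = k.shape[1] // 2
        padded = np.pad(c.env, ((0, 0), (nx, nx)), mode="reflect")
        out = fftconvolve(padded, k, mode="same")[:, nx : nx + c.n_channels]
        out = out[:, keep]
        if rectify:
            out = np.abs(out)
        cols.append(out)
        index.extend([(p[0], p[1], p[2], int(ch)) for ch in keep])
    act = np.concatenate(cols, axis=1)
    valid = np.zeros(c.n_frames, dtype=bool)
    h = m.max_half_support
    if c.n_frames > 2 * h:
        valid[h : c.n_frames - h] = True
    return FeatureActivations(act, c.frame_rate, index, valid)
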