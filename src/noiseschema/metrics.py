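"""Acoustic measures: texture statistics, stationarity, periodicity, similarity.

Stationarity is quantified as the SD of windowed texture statistics over
time, each statistic normalized by its typical dispersion across a seeded
reference corpus of generated textures (so statistics with intrinsically
different variability contribute comparably), then averaged.  Periodicity
is the frame-averaged maximum of the normalized waveform autocorrelation
over candidate pitch lags.  Spectrotemporal similarity is the cosine
between standardized excitation-pattern + modulation-power feature
vectors of two sounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import skew

from .frontend import (
    Cochleagram,
    Waveform,
    compute_cochleagram,
    design_filterbank,
    excitation_pattern,
)

# octave bands of modulation rate (Hz) for the modulation-power statistics
MOD_BANDS = ((1.0, 2.0), (2.0, 4.0), (4.0, 8.0), (8.0, 16.0))

_METRICS_FRONTEND = dict(n_channels=30, f_lo=20.0, f_hi=10_000.0,
                         compression=0.3, frame_rate=200.0)


@dataclass
class TextureStatVector:
    """Flat vector of texture statistics with a documented layout.

    Layout (C channels): normalized envelope means (C), coefficients of
    variation (C), skewness (C), neighbor-channel correlations (C-1),
    modulation power per channel per octave rate band (C x 4, normalized
    by channel variance).  ``degenerate`` flags entries that were set to 0
    because they were undefined (constant envelopes).
    """

    values: np.ndarray
    names: list
    degenerate: np.ndarray


def _cochleagram(w: Waveform, sample_rate: float = None) -> Cochleagram:
    sr = sample_rate or w.sample_rate
    fb = design_filterbank(
        _METRICS_FRONTEND["n_channels"], _METRICS_FRONTEND["f_lo"],
        min(_METRICS_FRONTEND["f_hi"], sr / 2 * 0.999), sr,
    )
    return compute_cochleagram(w, fb, _METRICS_FRONTEND["compression"],
                               _METRICS_FRONTEND["frame_rate"])


def texture_statistics(c: Cochleagram, window: tuple = None) -> TextureStatVector:
    """Texture statistics of a cochleagram window (>= 250 ms)."""
    if window is not None:
        i0 = int(round(window[0] * c.frame_rate))
        i1 = int(round(window[1] * c.frame_rate))
        if i0 < 0 or i1 > c.n_frames:
            raise ValueError("window outside cochleagram")
        env = c.env[i0:i1]
    else:
        env = c.env
    if env.shape[0] < 0.25 * c.frame_rate:
        raise ValueError("window shorter than 250 ms")
    C = env.shape[1]
    mean = env.mean(axis=0)
    std = env.std(axis=0)
    grand = mean.sum()
    norm_mean = mean / grand if grand > 0 else np.zeros(C)
    flags = []

    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, std / np.maximum(mean, 1e-300), 0.0)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        sk = skew(env, axis=0)
    sk_bad = ~np.isfinite(sk) | (std == 0)
    sk = np.where(sk_bad, 0.0, sk)

    centered = env - mean
    num = (centered[:, :-1] * centered[:, 1:]).mean(axis=0)
    den = std[:-1] * std[1:]
    corr_bad = den == 0
    corr = np.where(corr_bad, 0.0, num / np.where(corr_bad, 1.0, den))

    # modulation power: fraction of envelope variance in each rate band
    T = env.shape[0]
    spec = np.abs(np.fft.rfft(centered, axis=0)) ** 2
    freqs = np.fft.rfftfreq(T, d=1.0 / c.frame_rate)
    total = spec[1:].sum(axis=0)
    mp = []
    for lo, hi in MOD_BANDS:
        sel = (freqs >= lo) & (freqs < hi)
        band = spec[sel].sum(axis=0)
        mp.append(np.where(total > 0, band / np.maximum(total, 1e-300), 0.0))
    mp = np.concatenate(mp)

    values = np.concatenate([norm_mean, cv, sk, corr, mp])
    names = (
        [f"mean[{i}]" for i in range(C)]
        + [f"cv[{i}]" for i in range(C)]
        + [f"skew[{i}]" for i in range(C)]
        + [f"corr[{i},{i+1}]" for i in range(C - 1)]
        + [f"modpow[{lo}-{hi}Hz,{i}]" for (lo, hi) in MOD_BANDS for i in range(C)]
    )
    degenerate = np.concatenate([
        np.zeros(C, bool), mean == 0, sk_bad, corr_bad,
        np.tile(total == 0, len(MOD_BANDS)),
    ])
    return TextureStatVector(values, names, degenerate)


@lru_cache(maxsize=4)
def reference_dispersions(
    n_textures: int = 50, seed: int = 20_240_501, win_ms: float = 1000.0,
    hop_ms: float = 500.0, sample_rate: float = 20_000.0,
    duration: float = 3.25,
) -> np.ndarray:
    """Per-statistic reference dispersions: the median, across a seeded
    corpus of generated textures spanning mod_depth in [0, 1], of each
    statistic's SD over sliding windows.  Cached per parameter set."""
    from .stimuli import TextureSpec, gen_texture_background

    rng = np.random.default_rng(seed)
    depths = np.linspace(0.0, 1.0, n_textures)
    sds = []
    for d in depths:
        spec = TextureSpec(seed=int(rng.integers(2**31)), duration=duration,
                           sample_rate=sample_rate, mod_depth=float(d),
                           event_density=float(rng.uniform(0, 2)))
        w = gen_texture_background(spec)
        sds.append(_windowed_stat_sds(w, win_ms, hop_ms))
    med = np.median(np.vstack(sds), axis=0)
    return np.maximum(med, 1e-9)


def _windowed_stat_sds(w: Waveform, win_ms: float, hop_ms: float) -> np.ndarray:
    c = _cochleagram(w)
    win = win_ms / 1000.0
    hop = hop_ms / 1000.0
    starts = np.arange(0.0, c.duration - win + 1e-9, hop)
    if len(starts) < 2:
        raise ValueError("signal shorter than two analysis windows")
    stats = np.vstack(
        [texture_statistics(c, (t0, t0 + win)).values for t0 in starts]
    )
    return stats.std(axis=0)


@dataclass
class NonstationarityIndex:
    """Mean normalized SD of texture statistics over time (lower = more
    stationary)."""

    value: float
    per_statistic: np.ndarray


def nonstationarity(
    w: Waveform, win_ms: float = 1000.0, hop_ms: float = 500.0,
    normalizer: np.ndarray = None, n_reference: int = 50,
) -> NonstationarityIndex:
    """Stationarity measure of a waveform (SD of texture statistics across
    sliding windows, normalized per statistic, averaged)."""
    sds = _windowed_stat_sds(w, win_ms, hop_ms)
    if normalizer is None:
        normalizer = reference_dispersions(
            n_reference, win_ms=win_ms, hop_ms=hop_ms, sample_rate=w.sample_rate
        )
    z = sds / normalizer
    return NonstationarityIndex(float(z.mean()), z)


def periodicity(
    w: Waveform, f0_range: tuple = (80.0, 400.0),
    frame_ms: float = 50.0, hop_ms: float = 25.0,
) -> float:
    """Waveform periodicity in [0, 1]: frame-averaged maximum normalized
    autocorrelation over lags spanning the candidate f0 range.  Silence
    scores 0 by convention."""
    sr = w.sample_rate
    f0_lo, f0_hi = f0_range
    lag_min = max(int(np.floor(sr / f0_hi)), 1)
    lag_max = int(np.ceil(sr / f0_lo))
    if len(w.samples) < 2 * lag_max:
        raise ValueError("waveform shorter than two periods of the lowest f0")
    frame_n = max(int(round(frame_ms / 1000 * sr)), 2 * lag_max)
    hop_n = max(int(round(hop_ms / 1000 * sr)), 1)
    scores = []
    for i0 in range(0, len(w.samples) - frame_n + 1, hop_n):
        x = w.samples[i0 : i0 + frame_n]
        x = x - x.mean()
        e = np.sum(x * x)
        if e == 0:
            scores.append(0.0)
            continue
        # autocorrelation via FFT
        nfft = int(2 ** np.ceil(np.log2(2 * frame_n)))
        X = np.fft.rfft(x, nfft)
        ac = np.fft.irfft(X * np.conj(X), nfft)[: lag_max + 1]
        csum = np.concatenate([[0.0], np.cumsum(x * x)])
        lags = np.arange(lag_min, lag_max + 1)
        e_head = csum[frame_n - lags] - csum[0]
        e_tail = csum[frame_n] - csum[lags]
        den = np.sqrt(e_head * e_tail)
        r = np.where(den > 0, ac[lag_min:] / np.maximum(den, 1e-300), 0.0)
        scores.append(float(np.clip(r.max(), 0.0, 1.0)))
    if not scores:
        return 0.0
    return float(np.mean(scores))


def _z(v: np.ndarray) -> np.ndarray:
    s = v.std()
    if s == 0:
        raise ValueError("degenerate feature vector")
    return (v - v.mean()) / s


def _feature_blocks(w: Waveform):
    """Standardized excitation-pattern and modulation-power feature blocks.

    Modulation power per (channel, rate band) is weighted by the channel's
    excitation share so that silent channels contribute nothing (their
    raw entries would otherwise align spuriously between any two sounds).
    """
    c = _cochleagram(w)
    if not np.any(c.env > 0):
        raise ValueError("silent input: similarity undefined")
    ep = excitation_pattern(c)
    stats = texture_statistics(c)
    C = c.n_channels
    mp = stats.values[-4 * C:].reshape(len(MOD_BANDS), C)
    mp = (mp * (ep / ep.sum())[None, :]).ravel()
    return _z(ep), _z(mp)


def spectrotemporal_similarity(fg: Waveform, bg: Waveform) -> float:
    """Cosine similarity in [-1, 1] between the standardized
    spectrotemporal features of two sounds, averaging the excitation-
    pattern and modulation-power blocks with equal weight."""
    blocks_a = _feature_blocks(fg)
    blocks_b = _feature_blocks(bg)
    cosines = [
        float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        for u, v in zip(blocks_a, blocks_b)
    ]
    return float(np.mean(cosines))
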