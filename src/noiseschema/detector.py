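"""Observer model: sliding-window Gaussian surprisal over feature activations.

The model treats a foreground sound as a statistical outlier under a
continuously estimated model of the background.  For each spectrotemporal
filter, a univariate Gaussian is fit to the activations in a "past"
window; the samples in the adjacent "present" window are scored by their
average negative log-likelihood (surprisal) under that Gaussian.  The
per-filter surprisals are averaged and compared to an empirically
calibrated, time-varying decision threshold.  Performance improves as the
past window fills, reproducing the rise-then-plateau dependence of human
foreground detection on foreground onset time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frontend import FeatureActivations, FrontendConfig, Waveform

_LOG_2PI = float(np.log(2 * np.pi))
_VAR_ABS_FLOOR = 1e-12


@dataclass
class WindowConfig:
    """Past/present window layout of the observer model (all durations in ms).

    past_ms:     width of the background-estimation window (default 1,000 ms)
    present_ms:  width of the evaluation window (default 500 ms)
    hop_ms:      step between successive evaluations
    min_past_ms: minimum past data required before the model will evaluate;
                 below past_ms the window grows from this minimum so the
                 model can operate at early foreground onsets
    k_consec:    consecutive supra-threshold evaluations required for a
                 "foreground present" decision; the default (6 hops =
                 150 ms) demands sustained evidence, suppressing the brief
                 excursions that modulated backgrounds produce while
                 passing the 500-ms foregrounds
    """

    past_ms: float = 1000.0
    present_ms: float = 500.0
    hop_ms: float = 25.0
    min_past_ms: float = 100.0
    k_consec: int = 6
    var_floor_frac: float = 1e-6

    def __post_init__(self) -> None:
        if not (self.past_ms >= self.min_past_ms > 0):
            raise ValueError("require past_ms >= min_past_ms > 0")
        if self.present_ms <= 0 or self.hop_ms <= 0:
            raise ValueError("present_ms and hop_ms must be positive")

    def frames(self, frame_rate: float) -> tuple[int, int, int, int]:
        ms = frame_rate / 1000.0
        return (
            max(int(round(self.past_ms * ms)), 1),
            max(int(round(self.present_ms * ms)), 1),
            max(int(round(self.hop_ms * ms)), 1),
            max(int(round(self.min_past_ms * ms)), 2),
        )


@dataclass
class GaussianParams:
    """Per-filter mean and (floored) variance of background activations."""

    mu: np.ndarray
    var: np.ndarray


@dataclass
class SurprisalTrace:
    """Surprisal of the present window as a function of evaluation time.

    Evaluation times mark the END of each present window.  ``pooled`` is
    the mean of ``per_filter`` across filters.
    """

    t: np.ndarray                 # (n_eval,) seconds
    per_filter: np.ndarray        # (n_eval, n_filters)
    pooled: np.ndarray            # (n_eval,)
    threshold: np.ndarray = None  # optional aligned threshold values


@dataclass
class ThresholdCurve:
    """Time-varying decision threshold calibrated on background-only stimuli."""

    t: np.ndarray
    values: np.ndarray
    q: float
    mode: str
    k_consec: int


@dataclass
class Decision:
    present: bool
    peak_surprisal: float
    peak_time: float


def _var_floor(act: np.ndarray, frac: float) -> float:
    """Variance floor: frac x pooled global activation variance, with an
    absolute floor guarding all-silent input."""
    g = float(np.var(act))
    return max(frac * g, _VAR_ABS_FLOOR)


def fit_window_gaussians(
    act: FeatureActivations, t_end: float, cfg: WindowConfig
) -> GaussianParams:
    """Fit per-filter Gaussians to the past window ending at ``t_end`` (s).

    The window spans min(past_ms, available past) before t_end; at least
    min_past_ms of valid frames must be available.
    """
    fr = act.frame_rate
    past_f, _, _, min_past_f = cfg.frames(fr)
    v = np.flatnonzero(act.valid)
    if len(v) == 0:
        raise ValueError("no valid frames")
    v0 = v[0]
    j = int(round(t_end * fr))
    j = min(j, v[-1] + 1)
    if j - v0 < min_past_f:
        raise ValueError(
            f"insufficient past: {1000*(j - v0)/fr:.0f} ms available, "
            f"{cfg.min_past_ms:.0f} ms required"
        )
    i = max(v0, j - past_f)
    x = act.act[i:j]
    mu = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    floor = _var_floor(act.act[act.valid], cfg.var_floor_frac)
    return GaussianParams(mu, np.maximum(var, floor))


def gaussian_surprisal(x: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Elementwise -ln N(x; mu, var) = 0.5 ln(2 pi var) + (x-mu)^2/(2 var)."""
    return 0.5 * (_LOG_2PI + np.log(var)) + (x - mu) ** 2 / (2 * var)


def window_surprisal(
    act: FeatureActivations,
    params: GaussianParams,
    t_start: float,
    cfg: WindowConfig,
) -> np.ndarray:
    """Mean per-filter surprisal over the present window starting at t_start (s)."""
    fr = act.frame_rate
    _, present_f, _, _ = cfg.frames(fr)
    i = int(round(t_start * fr))
    if i < 0 or i + present_f > act.n_frames:
        raise ValueError("present window outside activations")
    x = act.act[i : i + present_f]
    return gaussian_surprisal(x, params.mu, params.var).mean(axis=0)


def sliding_surprisal(act: FeatureActivations, cfg: WindowConfig) -> SurprisalTrace:
    """Surprisal trace over all evaluation positions.

    Present windows of present_ms advance by hop_ms; each is scored under
    Gaussians fit to the window of up to past_ms of valid frames
    immediately preceding it (growing from min_past_ms at the start).
    Implemented with cumulative sums, O(frames x filters) total.
    """
    fr = act.frame_rate
    past_f, present_f, hop_f, min_past_f = cfg.frames(fr)
    v = np.flatnonzero(act.valid)
    if len(v) == 0:
        raise ValueError("no valid frames")
    v0, v1 = v[0], v[-1] + 1
    starts = np.arange(v0 + min_past_f, v1 - present_f + 1, hop_f)
    if len(starts) == 0:
        raise ValueError(
            "activations too short for min_past + present at this frame rate"
        )
    a = act.act
    c1 = np.concatenate([np.zeros((1, a.shape[1])), np.cumsum(a, axis=0)])
    c2 = np.concatenate([np.zeros((1, a.shape[1])), np.cumsum(a * a, axis=0)])
    floor = _var_floor(a[act.valid], cfg.var_floor_frac)

    p0 = np.maximum(v0, starts - past_f)          # past-window start per eval
    n_past = (starts - p0).astype(float)[:, None]
    s1 = c1[starts] - c1[p0]
    s2 = c2[starts] - c2[p0]
    mu = s1 / n_past
    var = (s2 - n_past * mu**2) / (n_past - 1)
    var = np.maximum(var, floor)

    e1 = c1[starts + present_f] - c1[starts]
    e2 = c2[starts + present_f] - c2[starts]
    m1 = e1 / present_f
    m2 = e2 / present_f
    # mean over present frames of 0.5 ln(2 pi var) + (x - mu)^2 / (2 var)
    per_filter = 0.5 * (_LOG_2PI + np.log(var)) + (
        m2 - 2 * mu * m1 + mu**2
    ) / (2 * var)
    pooled = per_filter.mean(axis=1)
    t = (starts + present_f) / fr
    return SurprisalTrace(t, per_filter, pooled)


def _flag_runs(above: np.ndarray, k: int) -> bool:
    """True if ``above`` contains >= k consecutive True values."""
    if k <= 1:
        return bool(above.any())
    run = 0
    for b in above:
        run = run + 1 if b else 0
        if run >= k:
            return True
    return False


def _run_stat(margin: np.ndarray, k: int) -> float:
    """Max over positions of the min margin across k consecutive evaluations.

    The trial is flagged at additive offset d iff this statistic > d.
    """
    if len(margin) < k:
        return -np.inf
    if k == 1:
        return float(margin.max())
    sw = np.lib.stride_tricks.sliding_window_view(margin, k)
    return float(sw.min(axis=1).max())


def calibrate_threshold(
    background_only: list[FeatureActivations],
    cfg: WindowConfig,
    q: float = 0.99,
    mode: str = "trial",
    min_traces: int = 20,
) -> ThresholdCurve:
    """Calibrate the time-varying decision threshold on background-only stimuli.

    mode="pointwise": the pointwise q-quantile of pooled surprisal across
    calibration traces (higher early, where past windows are short).

    mode="trial" (default): the pointwise-quantile curve is shifted by a
    constant chosen so the fraction of calibration trials with k_consec
    consecutive supra-threshold evaluations equals 1 - q, giving a
    per-trial false-alarm rate at the design target.
    """
    if len(background_only) == 0:
        raise ValueError("empty calibration set")
    if len(background_only) < min_traces:
        raise ValueError(
            f"calibration set too small: {len(background_only)} < {min_traces}"
        )
    traces = [sliding_surprisal(a, cfg) for a in background_only]
    n_eval = min(len(tr.t) for tr in traces)
    t = traces[0].t[:n_eval]
    pooled = np.stack([tr.pooled[:n_eval] for tr in traces])
    shape = np.quantile(pooled, q, axis=0)
    if mode == "pointwise":
        return ThresholdCurve(t, shape, q, mode, cfg.k_consec)
    if mode != "trial":
        raise ValueError(f"unknown threshold mode: {mode}")
    stats = np.array([_run_stat(p - shape, cfg.k_consec) for p in pooled])
    delta = float(np.quantile(stats, q, method="higher"))
    return ThresholdCurve(t, shape + delta, q, mode, cfg.k_consec)


def decide(trace: SurprisalTrace, threshold: ThresholdCurve) -> Decision:
    """Compare a pooled surprisal trace to the calibrated threshold."""
    n = min(len(trace.t), len(threshold.t))
    if not np.allclose(trace.t[:n], threshold.t[:n], atol=1e-9):
        raise ValueError("trace and threshold evaluation grids differ")
    pooled = trace.pooled[:n]
    above = pooled > threshold.values[:n]
    present = _flag_runs(above, threshold.k_consec)
    i = int(np.argmax(pooled))
    return Decision(present, float(pooled[i]), float(trace.t[i]))


def detect(
    stimulus: Waveform,
    threshold: ThresholdCurve,
    cfg: WindowConfig,
    frontend: FrontendConfig,
) -> Decision:
    """Full observer-model decision for one stimulus waveform."""
    act = frontend.features(stimulus)
    trace = sliding_surprisal(act, cfg)
    if len(trace.t) != len(threshold.t):
        raise ValueError(
            "stimulus duration does not match calibration duration "
            f"({len(trace.t)} vs {len(threshold.t)} evaluations)"
        )
    return decide(trace, threshold)


def run_model_experiment(
    trials: list,
    threshold: ThresholdCurve,
    cfg: WindowConfig,
    frontend: FrontendConfig,
) -> pd.DataFrame:
    """Run the observer model over a trial set; one decision per trial.

    ``trials`` is a list of (Waveform, TrialSpec) as built by
    stimuli.build_trial_set; background-only trials must be included (they
    provide the single pooled false-alarm rate downstream).  Returns a
    trial table with model decisions; condition d' is computed from it by
    psychophysics.model_dprime_table.
    """
    rows = []
    for i, (w, spec) in enumerate(trials):
        d = detect(w, threshold, cfg, frontend)
        rows.append(
            {
                "trial_id": i,
                "onset_ms": spec.onset_ms,
                "snr_db": spec.snr_db,
                "background_id": spec.background_id,
                "foreground_present": spec.foreground_id is not None,
                "decision": d.present,
                "peak_surprisal": d.peak_surprisal,
                "peak_time_s": d.peak_time,
            }
        )
    table = pd.DataFrame(rows)
    if not (~table["foreground_present"]).any():
        raise ValueError("trial set contains no background-only trials")
    return table
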