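"""Observer-model experiment runners at desk scale.

These helpers wire stimulus synthesis, threshold calibration and the
detector into complete simulated experiments.  The desk-scale front end
(``DESK_FRONTEND``) uses a reduced spectrotemporal filter inventory so a
full onset x SNR experiment runs in minutes on one CPU; the filterbank
and window parameters match the model defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import stage_seed
from .detector import ThresholdCurve, WindowConfig, calibrate_threshold, decide, sliding_surprisal
from .frontend import FrontendConfig
from .stimuli import ExperimentDesign, _background_spec, _render_background, build_trial_set

DESK_FRONTEND = FrontendConfig(rates=(2,), scales=(1.0,), channel_stride=30)


def background_features(
    design: ExperimentDesign, frontend: FrontendConfig, n: int, seed: int
) -> list:
    """Feature activations of n background-only draws from the design's
    background distribution (used for threshold calibration and held-out
    false-alarm measurement)."""
    rng = np.random.default_rng(seed)
    acts = []
    for _ in range(n):
        spec = _background_spec(design, rng)
        bg = _render_background(spec, design, rng)
        acts.append(frontend.features(bg))
    return acts


def calibrated_threshold(
    design: ExperimentDesign,
    frontend: FrontendConfig,
    window: WindowConfig,
    n_calibration: int,
    seed: int,
    q: float = 0.99,
    mode: str = "trial",
) -> ThresholdCurve:
    acts = background_features(design, frontend, n_calibration, seed)
    return calibrate_threshold(acts, window, q, mode)


def run_trials(
    trials: list,
    threshold: ThresholdCurve,
    window: WindowConfig,
    frontend: FrontendConfig,
) -> pd.DataFrame:
    """Model decisions for a prebuilt (Waveform, TrialSpec) list."""
    rows = []
    for i, (w, spec) in enumerate(trials):
        trace = sliding_surprisal(frontend.features(w), window)
        d = decide(trace, threshold)
        rows.append(
            {
                "trial_id": i,
                "onset_ms": np.nan if spec.onset_ms is None else spec.onset_ms,
                "snr_db": np.nan if spec.snr_db is None else spec.snr_db,
                "background_id": spec.background_id,
                "foreground_present": spec.foreground_id is not None,
                "decision": d.present,
                "peak_surprisal": d.peak_surprisal,
                "peak_time_s": d.peak_time,
            }
        )
    return pd.DataFrame(rows)


def pooled_model_experiment(
    design: ExperimentDesign,
    frontend: FrontendConfig = None,
    window: WindowConfig = None,
    n_calibration: int = 60,
    n_seeds: int = 5,
    master_seed: int = 0,
    q: float = 0.99,
    mode: str = "trial",
    threshold: ThresholdCurve = None,
) -> pd.DataFrame:
    """Run the observer model over ``n_seeds`` replicate stimulus sets and
    pool decisions into one trial table.

    Pooling across replicates raises the per-condition trial count (each
    replicate contributes n_backgrounds / n_conditions foreground trials
    per condition) so condition hit rates are estimated stably.
    """
    frontend = frontend or DESK_FRONTEND
    window = window or WindowConfig()
    thr = threshold
    if thr is None:
        thr = calibrated_threshold(
            design, frontend, window, n_calibration,
            stage_seed(master_seed, "calibration"), q, mode,
        )
    tables = []
    for s in range(n_seeds):
        trials = build_trial_set(design, stage_seed(master_seed, f"trials-{s}"))
        t = run_trials(trials, thr, window, frontend)
        t["replicate"] = s
        tables.append(t)
    return pd.concat(tables, ignore_index=True)
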