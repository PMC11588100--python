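"""Generate a small example stimulus set and summarize its acoustics.

Builds a reduced Experiment-1-style trial set (texture backgrounds, brief
foreground events at two SNRs), writes the waveforms and trial manifest
under results/stimuli/, and prints the stationarity and periodicity
summaries that motivate the background/foreground constructions.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from noiseschema.io import write_wav
from noiseschema.metrics import nonstationarity, periodicity
from noiseschema.stimuli import (
    ForegroundSpec,
    TextureSpec,
    build_trial_set,
    experiment_design,
    gen_foreground,
    gen_spectrally_matched_noise,
    gen_texture_background,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
WAV_OUT = ROOT / "scratch" / "stimuli"   # audio is bulky; kept out of results
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    WAV_OUT.mkdir(parents=True, exist_ok=True)
    design = experiment_design("exp1", n_backgrounds=20)
    trials = build_trial_set(design, master_seed=SEED)
    rows = []
    for i, (w, spec) in enumerate(trials):
        name = f"trial_{i:03d}.wav"
        write_wav(WAV_OUT / name, w, subtype="float32")
        rows.append({
            "trial_id": i, "wav": name, "onset_ms": spec.onset_ms,
            "snr_db": spec.snr_db, "background_id": spec.background_id,
            "foreground_present": spec.foreground_id is not None,
        })
    pd.DataFrame(rows).to_csv(OUT / "stimulus_manifest.csv", index=False)
    print(f"wrote {len(rows)} stimuli to {WAV_OUT}")

    rng = np.random.default_rng(SEED)
    tex, matched = [], []
    for _ in range(10):
        src = gen_texture_background(
            TextureSpec(seed=int(rng.integers(2**31)), mod_depth=float(rng.uniform(0.5, 1)))
        )
        tex.append(nonstationarity(src).value)
        matched.append(nonstationarity(
            gen_spectrally_matched_noise(src, int(rng.integers(2**31)))).value)
    print(f"nonstationarity: texture mean {np.mean(tex):.2f}, "
          f"spectrally matched mean {np.mean(matched):.2f} "
          f"(matched more stationary on {np.mean(np.array(matched) < np.array(tex)):.0%} of pairs)")

    ph = [periodicity(gen_foreground(ForegroundSpec(seed=s, kind="harmonic",
                                                    f0=float(rng.uniform(120, 320)))))
          for s in range(10)]
    pn = [periodicity(gen_foreground(ForegroundSpec(seed=s, kind="noise_burst")))
          for s in range(10)]
    print(f"periodicity: harmonic {np.mean(ph):.2f} (min {min(ph):.2f}), "
          f"noise burst {np.mean(pn):.2f} (max {max(pn):.2f})")


if __name__ == "__main__":
    main()
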