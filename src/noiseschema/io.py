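"""WAV and tabular I/O."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .frontend import Waveform

_INT_SCALES = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31,
               np.dtype(np.uint8): 2**7}


def read_wav(path) -> Waveform:
    """Read a WAV file as a mono float Waveform.

    Integer PCM is scaled to [-1, 1); stereo input is downmixed by
    channel averaging with a warning.  Malformed files raise a ValueError
    naming the file.
    """
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", wavfile.WavFileWarning)
            sr, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - reraise with filename
        raise ValueError(f"failed to parse WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        warnings.warn(f"{path.name}: stereo input downmixed to mono by averaging")
        data = data.mean(axis=1)
    if data.dtype in _INT_SCALES:
        scale = _INT_SCALES[data.dtype]
        if data.dtype == np.dtype(np.uint8):
            data = (data.astype(np.float64) - 128.0) / scale
        else:
            data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64, copy=False)
    return Waveform(data, float(sr))


def write_wav(path, w: Waveform, subtype: str = "float64") -> None:
    """Write a Waveform as WAV (float64/float32 IEEE or int16 PCM)."""
    path = Path(path)
    if subtype == "float64":
        data = w.samples.astype(np.float64)
    elif subtype == "float32":
        data = w.samples.astype(np.float32)
    elif subtype == "int16":
        data = np.clip(np.round(w.samples * 2**15), -(2**15), 2**15 - 1).astype(
            np.int16
        )
    else:
        raise ValueError(f"unsupported subtype: {subtype}")
    wavfile.write(path, int(round(w.sample_rate)), data)
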