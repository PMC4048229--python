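"""Reading and writing inhaler-monitor recordings.

The acoustic monitor records mono audio at 8 kHz with 8-bit linear PCM
resolution and stamps each file with the time the inhaler was opened
(a real-time clock on the device). Files are stored as standard RIFF/WAV;
the opening timestamp and subject/device identity live in a JSON sidecar
next to the WAV so that the audio stays readable by any standard tool.

Amplitudes are expressed throughout the package in arbitrary units (AU),
defined as the fraction of digital full scale: an 8-bit code of +127 maps
to 1.0 AU.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = ["Recording", "read_recording", "write_recording", "sidecar_path"]

DEVICE_SAMPLE_RATE = 8000
DEVICE_BIT_DEPTH = 8


@dataclass
class Recording:
    """A mono recording plus the device metadata that travels with it.

    Parameters
    ----------
    samples:
        Waveform as floats in [-1, 1] (fraction of digital full scale).
    sample_rate:
        Sampling rate in Hz.
    bit_depth:
        Resolution of the originating PCM stream (8 or 16).
    opened_at:
        Time the inhaler was opened (starts the recording); ``None`` when
        the timestamp sidecar was missing or unreadable. Operations that
        need real time (dose logs, adherence) reject recordings without it.
    subject_id, device_id:
        Opaque identifiers.
    """

    samples: np.ndarray
    sample_rate: int = DEVICE_SAMPLE_RATE
    bit_depth: int = DEVICE_BIT_DEPTH
    opened_at: datetime | None = None
    subject_id: str = ""
    device_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Recording requires a 1-D (mono) sample array")
        if self.samples.size == 0:
            raise ValueError("Recording must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        peak = float(np.max(np.abs(self.samples)))
        if peak > 1.0 + 1e-9:
            raise ValueError(f"samples exceed full scale (peak {peak:.3g})")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


def sidecar_path(path: str | Path) -> Path:
    """JSON metadata sidecar associated with a WAV path (same stem)."""
    return Path(path).with_suffix(".json")


def _full_scale(bit_depth: int) -> int:
    if bit_depth == 8:
        return 127
    if bit_depth == 16:
        return 32767
    raise ValueError(f"unsupported bit depth: {bit_depth}")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write ``rec`` as linear-PCM WAV plus a JSON metadata sidecar.

    8-bit audio is stored as unsigned bytes with a 128 offset (the WAV
    convention); 16-bit as signed. Returns the WAV path.
    """
    path = Path(path)
    fs = _full_scale(rec.bit_depth)
    codes = np.round(np.clip(rec.samples, -1.0, 1.0) * fs)
    if rec.bit_depth == 8:
        data = (codes + 128).clip(0, 255).astype(np.uint8)
    else:
        data = codes.clip(-fs, fs).astype(np.int16)
    wavfile.write(path, int(rec.sample_rate), data)
    meta = {
        "opened_at": rec.opened_at.isoformat() if rec.opened_at else None,
        "subject_id": rec.subject_id,
        "device_id": rec.device_id,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path: str | Path, resample_to: int | None = None) -> Recording:
    """Read a mono WAV and its sidecar metadata into a :class:`Recording`.

    Parameters
    ----------
    path:
        WAV file path. A JSON sidecar with the same stem is read if present;
        a missing or unparseable sidecar leaves ``opened_at`` as ``None``.
    resample_to:
        If given and different from the file's rate, resample (polyphase)
        to this rate. Length rescales by the rate ratio; tonal content is
        preserved below the new Nyquist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path} is not mono ({data.shape[1]} channels)")
    if data.dtype == np.uint8:
        bit_depth = 8
        samples = (data.astype(np.float64) - 128.0) / 127.0
    elif data.dtype == np.int16:
        bit_depth = 16
        samples = data.astype(np.float64) / 32767.0
    elif data.dtype in (np.float32, np.float64):
        bit_depth = 16
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format: {data.dtype}")
    samples = np.clip(samples, -1.0, 1.0)

    if resample_to is not None and resample_to != rate:
        ratio = Fraction(int(resample_to), int(rate))
        samples = resample_poly(samples, ratio.numerator, ratio.denominator)
        samples = np.clip(samples, -1.0, 1.0)
        rate = int(resample_to)

    opened_at: datetime | None = None
    subject_id = device_id = ""
    sp = sidecar_path(path)
    if sp.exists():
        try:
            meta = json.loads(sp.read_text())
            if meta.get("opened_at"):
                opened_at = datetime.fromisoformat(meta["opened_at"])
            subject_id = meta.get("subject_id", "") or ""
            device_id = meta.get("device_id", "") or ""
        except (json.JSONDecodeError, ValueError, TypeError):
            opened_at = None  # recoverable: downstream temporal ops reject

    return Recording(
        samples=samples,
        sample_rate=int(rate),
        bit_depth=bit_depth,
        opened_at=opened_at,
        subject_id=subject_id,
        device_id=device_id,
    )
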