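"""Segmentation and classification of inhaler acoustic events.

A recording of one dose attempt contains up to three kinds of sound, each
with a distinct signature:

* **blister** (drug priming): a short burst of energy, roughly 20–30 ms,
  with high-frequency content near 2 kHz, preceded by a short burst of
  lower-frequency (~1 kHz) noise from the lever starting to move;
* **inhalation**: a broadband breath noise with a slow rise in amplitude
  and sustained spectral power; its median amplitude maps linearly to peak
  inspiratory flow;
* **exhalation**: a sharp rise in amplitude that tapers off, with band
  power migrating downward from ~2 kHz to ~500 Hz over the breath.

Segmentation finds maximal intervals whose short-time band energy exceeds
an adaptive threshold above the recording's own noise floor, with
hysteresis; classification then applies the signatures above.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.fft import rfft, rfftfreq

from .audio_io import Recording

__all__ = [
    "AcousticEvent",
    "SegmentationConfig",
    "BlisterConfig",
    "BreathConfig",
    "segment_events",
    "event_features",
    "detect_blister",
    "classify_breath",
    "detect_events",
]

EVENT_KINDS = ("blister", "inhalation", "exhalation", "unknown")


@dataclass
class AcousticEvent:
    """One segmented interval of a recording with its acoustic features.

    ``attack_ratio`` is the fraction of the event duration taken to reach
    the envelope peak; ``spectral_decay`` is the shift (Hz, signed) of the
    500–2500 Hz band-power centroid from the first to the last third of the
    event — negative values mean downward migration (exhalation-like).
    ``energy_db`` is referenced to digital full scale (a constant full-scale
    signal is 0 dB).
    """

    start_s: float
    end_s: float
    kind: str = "unknown"
    median_amplitude: float | None = None
    peak_amplitude: float | None = None
    energy_db: float | None = None
    spectral_peak_hz: float | None = None
    attack_ratio: float | None = None
    spectral_decay: float | None = None

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("event must have start_s < end_s")
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind: {self.kind!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SegmentationConfig:
    """Short-time analysis and hysteresis parameters.

    Frames of 25 ms with a 10 ms hop and a Hann window; an event opens
    when band energy exceeds the estimated noise floor by ``enter_db`` and
    extends in both directions while it stays above ``exit_db``. Gaps
    shorter than ``merge_gap_s`` are bridged; events shorter than
    ``min_event_s`` are dropped. Boundaries are then refined to ~1 ms
    resolution with a short RMS envelope. The noise floor is the
    ``noise_percentile``-th percentile of frame energy, which makes
    segmentation invariant to global gain changes.
    """

    frame_s: float = 0.025
    hop_s: float = 0.010
    enter_db: float = 12.0
    exit_db: float = 6.0
    merge_gap_s: float = 0.050
    min_event_s: float = 0.015
    band_hz: tuple[float, float] = (200.0, 3200.0)
    noise_percentile: float = 20.0


@dataclass
class BlisterConfig:
    """Blister-click decision rule parameters.

    Duration bounds cover the ~20–30 ms high-frequency click together with
    its ~10 ms low-frequency precursor, which segmentation merges into one
    event. The spectral peak of the event must fall in ``peak_band_hz``;
    when ``precursor_check`` is on, the opening of the event must carry
    more power in ``precursor_band_hz`` than in the click band.
    """

    min_duration_s: float = 0.015
    max_duration_s: float = 0.050
    peak_band_hz: tuple[float, float] = (1600.0, 2600.0)
    precursor_check: bool = True
    precursor_band_hz: tuple[float, float] = (700.0, 1300.0)
    precursor_window_s: float = 0.012


@dataclass
class BreathConfig:
    """Breath-direction decision rule parameters.

    An event is an exhalation when its attack is fast
    (``attack_ratio < attack_threshold``) and its band-power centroid
    migrates downward by more than ``decay_threshold_hz`` (a negative
    number). When the two features disagree, the spectral behaviour
    dominates. Events shorter than ``min_duration_s`` are left unknown.
    """

    min_duration_s: float = 0.2
    attack_threshold: float = 0.25
    decay_threshold_hz: float = -400.0


DEFAULT_SEGMENTATION = SegmentationConfig()
DEFAULT_BLISTER = BlisterConfig()
DEFAULT_BREATH = BreathConfig()

_EPS = 1e-20


def _frame_band_energy(
    x: np.ndarray, fs: float, cfg: SegmentationConfig
) -> tuple[np.ndarray, int, int]:
    """Per-frame in-band power via STFT. Returns (power, frame_len, hop)."""
    nperseg = max(int(round(cfg.frame_s * fs)), 16)
    hop = max(int(round(cfg.hop_s * fs)), 1)
    freqs, _, Z = sps.stft(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg - hop,
        boundary=None,
        padded=True,
    )
    lo, hi = cfg.band_hz
    mask = (freqs >= lo) & (freqs <= hi)
    power = np.sum(np.abs(Z[mask]) ** 2, axis=0)
    return power, nperseg, hop


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean array as half-open (start, stop)."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _short_rms(x: np.ndarray, win: int) -> np.ndarray:
    """Centered moving RMS with window ``win`` samples."""
    pad = win // 2
    sq = np.pad(x * x, pad, mode="edge")
    c = np.cumsum(np.insert(sq, 0, 0.0))
    out = (c[win:] - c[:-win]) / win
    return np.sqrt(np.maximum(out[: x.size], 0.0))


def segment_events(
    rec: Recording, config: SegmentationConfig = DEFAULT_SEGMENTATION
) -> list[AcousticEvent]:
    """Segment a recording into candidate events (kind ``unknown``).

    Returns ordered, non-overlapping events with features populated. An
    all-silent recording yields an empty list.
    """
    if rec.duration_s < 0.5:
        raise ValueError("recording shorter than 0.5 s cannot be segmented")
    x = rec.samples
    fs = rec.sample_rate

    power, nperseg, hop = _frame_band_energy(x, fs, config)
    frame_db = 10.0 * np.log10(power + _EPS)
    noise_db = float(np.percentile(frame_db, config.noise_percentile))
    enter = noise_db + config.enter_db
    exit_ = noise_db + config.exit_db

    above_exit = frame_db >= exit_
    regions = []
    for a, b in _runs(above_exit):
        if np.any(frame_db[a:b] >= enter):
            regions.append((a, b))

    # frame index -> sample interval (frame i spans [i*hop, i*hop + nperseg))
    spans = [(a * hop, (b - 1) * hop + nperseg) for a, b in regions]

    # merge close regions
    merge_gap = int(round(config.merge_gap_s * fs))
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    # refine boundaries with a 5 ms RMS envelope against an amplitude-domain
    # noise estimate (same percentile as the frame-level floor)
    rms = _short_rms(x, max(int(0.005 * fs), 4))
    rms_noise = float(np.percentile(rms, config.noise_percentile))
    thr = max(rms_noise * 10 ** (config.exit_db / 20.0), 1e-12)

    events: list[AcousticEvent] = []
    min_len = int(round(config.min_event_s * fs))
    n = x.size
    last_end = 0
    for s, e in merged:
        s = max(s, last_end)
        e = min(e, n)
        if e - s <= 0:
            continue
        seg = rms[s:e]
        idx = np.flatnonzero(seg >= thr)
        if idx.size:
            s2, e2 = s + idx[0], s + idx[-1] + 1
        else:
            s2, e2 = s, e
        if e2 - s2 < min_len:
            continue
        last_end = e2
        ev = AcousticEvent(start_s=s2 / fs, end_s=e2 / fs)
        event_features(ev, rec)
        events.append(ev)
    return events


def _band_centroid(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Power-weighted mean frequency within ``band``."""
    nfft = max(1024, 1 << int(np.ceil(np.log2(max(x.size, 2)))))
    w = np.hanning(x.size)
    spec = np.abs(rfft(x * w, n=nfft)) ** 2
    f = rfftfreq(nfft, 1.0 / fs)
    m = (f >= band[0]) & (f <= band[1])
    p = spec[m]
    if p.sum() <= 0:
        return float(np.mean(band))
    return float(np.sum(f[m] * p) / np.sum(p))


def event_features(ev: AcousticEvent, rec: Recording) -> AcousticEvent:
    """Populate the feature fields of ``ev`` in place (and return it)."""
    fs = rec.sample_rate
    a = int(round(ev.start_s * fs))
    b = int(round(ev.end_s * fs))
    x = rec.samples[a:b]
    if x.size == 0:
        raise ValueError("event interval is empty")

    absx = np.abs(x)
    ev.median_amplitude = float(np.median(absx))
    ev.peak_amplitude = float(np.max(absx))
    ev.energy_db = float(10.0 * np.log10(np.mean(x * x) + _EPS))

    nfft = max(1024, 1 << int(np.ceil(np.log2(max(x.size, 2)))))
    w = np.hanning(x.size)
    spec = np.abs(rfft(x * w, n=nfft))
    f = rfftfreq(nfft, 1.0 / fs)
    m = (f >= 100.0) & (f <= fs / 2 - 100.0)
    ev.spectral_peak_hz = float(f[m][np.argmax(spec[m])])

    env = _short_rms(x, max(int(0.020 * fs), 4))
    ev.attack_ratio = float(np.argmax(env) / max(x.size - 1, 1))

    third = x.size // 3
    if third >= 8:
        band = (400.0, 2500.0)
        c_first = _band_centroid(x[:third], fs, band)
        c_last = _band_centroid(x[2 * third :], fs, band)
        ev.spectral_decay = float(c_last - c_first)
    else:
        ev.spectral_decay = 0.0
    return ev


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    nfft = max(512, 1 << int(np.ceil(np.log2(max(x.size, 2)))))
    spec = np.abs(rfft(x * np.hanning(x.size), n=nfft)) ** 2
    f = rfftfreq(nfft, 1.0 / fs)
    m = (f >= band[0]) & (f <= band[1])
    return float(np.sum(spec[m]))


def detect_blister(
    events: Sequence[AcousticEvent],
    rec: Recording,
    config: BlisterConfig = DEFAULT_BLISTER,
) -> list[AcousticEvent]:
    """Assign ``kind='blister'`` to events matching the click signature.

    A blister is a short event (duration within the configured bounds)
    whose spectral peak lies in the ~2 kHz click band and — when the
    precursor check is enabled — whose opening milliseconds carry more
    ~1 kHz than ~2 kHz power (the lever's low-frequency precursor).
    Returns the same event list (modified in place).
    """
    fs = rec.sample_rate
    for ev in events:
        if ev.kind != "unknown":
            continue
        if not (config.min_duration_s <= ev.duration_s <= config.max_duration_s):
            continue
        if ev.spectral_peak_hz is None or not (
            config.peak_band_hz[0] <= ev.spectral_peak_hz <= config.peak_band_hz[1]
        ):
            continue
        if config.precursor_check:
            a = int(round(ev.start_s * fs))
            b = min(a + int(round(config.precursor_window_s * fs)), rec.samples.size)
            head = rec.samples[a:b]
            if head.size < 8:
                continue
            low = _band_power(head, fs, config.precursor_band_hz)
            high = _band_power(head, fs, config.peak_band_hz)
            if low <= high:
                continue
        ev.kind = "blister"
    return list(events)


def classify_breath(
    ev: AcousticEvent,
    rec: Recording,
    config: BreathConfig = DEFAULT_BREATH,
) -> str:
    """Classify a breath-scale event as inhalation or exhalation.

    Exhalations show a fast attack and downward spectral migration;
    inhalations a slow attack and sustained broadband power. When the two
    features disagree the spectral migration decides. Events shorter than
    the breath scale return ``"unknown"``.
    """
    if ev.duration_s < config.min_duration_s:
        return "unknown"
    if ev.attack_ratio is None or ev.spectral_decay is None:
        event_features(ev, rec)
    sharp_attack = ev.attack_ratio < config.attack_threshold
    falling = ev.spectral_decay < config.decay_threshold_hz
    if sharp_attack and falling:
        kind = "exhalation"
    elif not sharp_attack and not falling:
        kind = "inhalation"
    else:
        kind = "exhalation" if falling else "inhalation"
    ev.kind = kind
    return kind


def detect_events(
    rec: Recording,
    seg_config: SegmentationConfig = DEFAULT_SEGMENTATION,
    blister_config: BlisterConfig = DEFAULT_BLISTER,
    breath_config: BreathConfig = DEFAULT_BREATH,
) -> list[AcousticEvent]:
    """Full detection chain: segment, then classify every event."""
    events = segment_events(rec, seg_config)
    detect_blister(events, rec, blister_config)
    for ev in events:
        if ev.kind == "unknown" and ev.duration_s >= breath_config.min_duration_s:
            classify_breath(ev, rec, breath_config)
    return events
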