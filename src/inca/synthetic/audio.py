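"""Synthetic inhaler audio with ground-truth annotations.

No public corpus of inhaler-monitor recordings exists, so the package
ships a generator that emulates the documented acoustic signatures:

* blister click: ~25 ms burst of narrowband energy near 2 kHz, preceded
  by a ~10 ms burst of lower-frequency (~1 kHz) noise from the lever;
* inhalation: band-limited breath noise with a slow attack (envelope peak
  past 30 % of the duration); its median amplitude is the exact inverse
  of the amplitude→flow calibration at the requested inspiratory flow;
* exhalation: sharp attack (peak within the first ~6 % of the duration)
  that tapers off, with the carrier frequency decaying exponentially from
  2 kHz toward 500 Hz; its level is set by an "effort" in dB above the
  recording noise floor.

Recordings are assembled from non-overlapping segments, white Gaussian
noise is added at a configurable floor (default −50 dBFS, comfortably
above the −53 dBFS quantization floor of 8-bit audio but well below the
0.016 AU weak-inhalation threshold the device must resolve), and the
waveform is passed through the device's 8-bit quantizer. Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Sequence

import numpy as np
from scipy import signal as sps

from ..audio_io import Recording, DEVICE_SAMPLE_RATE
from ..technique import DEFAULT_CALIBRATION, CalibrationModel, flow_to_amplitude

__all__ = [
    "Segment",
    "ScenarioSpec",
    "SCENARIO_PRESETS",
    "generate_blister_click",
    "generate_breath",
    "generate_inhaler_recording",
    "scenario_preset",
]

DEFAULT_NOISE_FLOOR_DB = -50.0

# blister defaults (main click 20-30 ms near 2 kHz; short 1 kHz precursor)
BLISTER_MAIN_HZ = 2000.0
BLISTER_MAIN_S = 0.025
BLISTER_MAIN_AMP = 0.40
BLISTER_PRE_HZ = 1000.0
BLISTER_PRE_S = 0.010
BLISTER_PRE_AMP = 0.28


def _smooth_noise(rng: np.random.Generator, n: int, cutoff: float, fs: float) -> np.ndarray:
    """Unit-RMS low-passed Gaussian noise for gentle amplitude modulation."""
    x = rng.standard_normal(n)
    if n > 32:
        sos = sps.butter(2, min(cutoff / (fs / 2), 0.99), output="sos")
        x = sps.sosfiltfilt(sos, x)
    r = np.sqrt(np.mean(x * x))
    return x / r if r > 0 else x


def _tone_burst(
    rng: np.random.Generator,
    freq: float,
    duration_s: float,
    amplitude: float,
    fs: float,
) -> np.ndarray:
    """Hann-windowed narrowband burst with mild amplitude modulation."""
    n = max(int(round(duration_s * fs)), 8)
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * freq * t + phase)
    am = 1.0 + 0.15 * _smooth_noise(rng, n, 200.0, fs)
    return amplitude * carrier * np.hanning(n) * am


def generate_blister_click(
    seed: int,
    sample_rate: int = DEVICE_SAMPLE_RATE,
    main_duration_s: float = BLISTER_MAIN_S,
    main_freq_hz: float = BLISTER_MAIN_HZ,
    main_amplitude: float = BLISTER_MAIN_AMP,
    precursor_duration_s: float = BLISTER_PRE_S,
    precursor_freq_hz: float = BLISTER_PRE_HZ,
    precursor_amplitude: float = BLISTER_PRE_AMP,
) -> np.ndarray:
    """Synthesize one blister (drug-priming) click.

    The returned segment is the ~1 kHz precursor immediately followed by
    the ~2 kHz main burst. ``main_duration_s`` outside [15, 40] ms is
    rejected. Deterministic for a fixed seed.
    """
    if not 0.015 <= main_duration_s <= 0.040:
        raise ValueError("main click duration must be within [15, 40] ms")
    rng = np.random.default_rng(seed)
    pre = _tone_burst(rng, precursor_freq_hz, precursor_duration_s,
                      precursor_amplitude, sample_rate)
    main = _tone_burst(rng, main_freq_hz, main_duration_s,
                       main_amplitude, sample_rate)
    return np.concatenate([pre, main])


def _breath_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Broadband breath turbulence, band-limited to 300-2500 Hz."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, [300.0 / (fs / 2), 2500.0 / (fs / 2)],
                     btype="band", output="sos")
    return sps.sosfilt(sos, x)


def generate_breath(
    direction: str,
    intensity: float,
    duration_s: float = 2.0,
    seed: int = 0,
    sample_rate: int = DEVICE_SAMPLE_RATE,
    calibration: CalibrationModel = DEFAULT_CALIBRATION,
    effort_ref_db: float = DEFAULT_NOISE_FLOOR_DB,
) -> np.ndarray:
    """Synthesize a breath segment.

    For ``direction='inhalation'``, ``intensity`` is the peak inspiratory
    flow in L/min; the segment's median absolute amplitude equals the
    inverse calibration at that flow exactly (before quantization), and
    zero flow yields silence. For ``direction='exhalation'``, ``intensity``
    is the effort in dB above ``effort_ref_db`` (the recording noise
    floor), scaling the segment's mean-square energy.
    """
    if duration_s <= 0.2:
        raise ValueError("breath duration must exceed 0.2 s")
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / n  # normalized time in [0, 1)

    if direction == "inhalation":
        if intensity == 0:
            return np.zeros(n)
        # slow attack: raised-cosine rise to a peak at 40 % of the duration,
        # gentle fall afterwards; envelope floor keeps onset/offset audible
        peak_at = 0.40
        shape = np.where(
            t < peak_at,
            0.5 - 0.5 * np.cos(np.pi * t / peak_at),
            0.5 + 0.5 * np.cos(np.pi * (t - peak_at) / (1 - peak_at)),
        )
        env = 0.35 + 0.65 * shape
        x = _breath_noise(rng, n, sample_rate) * env
        target = flow_to_amplitude(intensity, calibration)
        med = np.median(np.abs(x))
        return x * (target / med) if med > 0 else x
    if direction == "exhalation":
        # sharp attack then exponential decay; carrier frequency falls
        # exponentially from 2 kHz toward 500 Hz
        attack = 0.06
        env = np.where(
            t < attack,
            0.5 - 0.5 * np.cos(np.pi * t / attack),
            np.exp(-(t - attack) / (1.0 / 3.0)),
        )
        f_inst = 500.0 + 1500.0 * np.exp(-3.0 * t)
        phase = 2 * np.pi * np.cumsum(f_inst) / sample_rate
        carrier = np.sin(phase + rng.uniform(0, 2 * np.pi))
        am = 1.0 + 0.30 * _smooth_noise(rng, n, 300.0, sample_rate)
        x = carrier * env * am
        target_ms = 10.0 ** ((effort_ref_db + intensity) / 10.0)
        ms = np.mean(x * x)
        return x * np.sqrt(target_ms / ms) if ms > 0 else x
    raise ValueError(f"unknown breath direction: {direction!r}")


@dataclass
class Segment:
    """One scheduled sound within a scenario."""

    kind: str  # blister | inhalation | exhalation | silence
    onset_s: float
    duration_s: float
    flow_lpm: float | None = None  # inhalations
    effort_db: float | None = None  # exhalations
    level: float | None = None  # optional amplitude override (blister)


@dataclass
class ScenarioSpec:
    """A full synthetic recording: ordered segments plus a noise floor."""

    segments: list[Segment]
    duration_s: float | None = None
    noise_floor_db: float = DEFAULT_NOISE_FLOOR_DB
    seed: int = 0
    sample_rate: int = DEVICE_SAMPLE_RATE
    opened_at: datetime | None = None
    subject_id: str = ""
    device_id: str = ""


def _segment_waveform(seg: Segment, seed: int, spec: ScenarioSpec) -> np.ndarray:
    if seg.kind == "blister":
        amp = seg.level if seg.level is not None else BLISTER_MAIN_AMP
        main_dur = min(max(seg.duration_s - BLISTER_PRE_S, 0.015), 0.040)
        return generate_blister_click(
            seed, spec.sample_rate, main_duration_s=main_dur, main_amplitude=amp
        )
    if seg.kind in ("inhalation", "exhalation"):
        intensity = seg.flow_lpm if seg.kind == "inhalation" else seg.effort_db
        return generate_breath(
            seg.kind,
            float(intensity),
            seg.duration_s,
            seed=seed,
            sample_rate=spec.sample_rate,
            effort_ref_db=spec.noise_floor_db,
        )
    if seg.kind == "silence":
        return np.zeros(int(round(seg.duration_s * spec.sample_rate)))
    raise ValueError(f"unknown segment kind: {seg.kind!r}")


def generate_inhaler_recording(
    spec: ScenarioSpec,
) -> tuple[Recording, list[dict]]:
    """Render a scenario to a device-format recording plus ground truth.

    The annotation is a list of dicts ``{kind, start_s, end_s, ...}`` with
    the true segment boundaries (blister annotations span precursor plus
    click). Segments must not overlap. The waveform is quantized through
    the 8-bit device path so that amplitudes match what a reader of the
    written WAV would see.
    """
    segs = sorted(
        (s for s in spec.segments if s.kind != "silence"),
        key=lambda s: s.onset_s,
    )
    for s in segs:
        if s.duration_s <= 0:
            raise ValueError("segment durations must be positive")
    for a, b in zip(segs, segs[1:]):
        if a.onset_s + a.duration_s > b.onset_s:
            raise ValueError(
                f"segments overlap at {b.onset_s:.2f}s ({a.kind} then {b.kind})"
            )

    fs = spec.sample_rate
    tail = 0.5
    total_s = spec.duration_s or (
        (segs[-1].onset_s + segs[-1].duration_s + tail) if segs else 3.0
    )
    n = int(round(total_s * fs))
    x = np.zeros(n)

    root = np.random.default_rng(spec.seed)
    seg_seeds = root.integers(0, 2**31 - 1, size=max(len(segs), 1))
    annotation: list[dict] = []
    for seg, seed in zip(segs, seg_seeds):
        w = _segment_waveform(seg, int(seed), spec)
        a = int(round(seg.onset_s * fs))
        b = min(a + w.size, n)
        x[a:b] += w[: b - a]
        note = {"kind": seg.kind, "start_s": a / fs, "end_s": b / fs}
        if seg.flow_lpm is not None:
            note["flow_lpm"] = seg.flow_lpm
        if seg.effort_db is not None:
            note["effort_db"] = seg.effort_db
        annotation.append(note)

    noise_sigma = 10.0 ** (spec.noise_floor_db / 20.0)
    x += root.normal(0.0, noise_sigma, size=n)
    # device 8-bit quantizer
    x = np.round(np.clip(x, -1.0, 1.0) * 127.0) / 127.0

    rec = Recording(
        samples=x,
        sample_rate=fs,
        bit_depth=8,
        opened_at=spec.opened_at,
        subject_id=spec.subject_id,
        device_id=spec.device_id,
    )
    return rec, annotation


#: Scenario presets by name; each is rendered with mild seed-driven
#: variation in flows, efforts and durations.
SCENARIO_PRESETS = (
    "correct",
    "exhale_after_prime",
    "weak_inhalation",
    "double_prime",
    "double_dose",
    "no_prime",
    "no_inhalation",
    "inhale_then_exhale",
    "noise_only",
)


def scenario_preset(
    name: str,
    seed: int = 0,
    noise_floor_db: float = DEFAULT_NOISE_FLOOR_DB,
    **overrides,
) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` for a named dose-attempt scenario.

    ``correct``: prime then a strong inhalation (≥ 30 L/min).
    ``exhale_after_prime``: an exhalation between priming and inhaling.
    ``weak_inhalation``: inhalation below the 30 L/min threshold.
    ``double_prime``: the lever moved twice before one inhalation.
    ``double_dose``: two complete prime+inhale sequences.
    ``no_prime``: inhalation without a blister click.
    ``no_inhalation``: priming with no inhalation.
    ``inhale_then_exhale``: breathing in and straight back out into the
    device after a valid prime+inhale.
    ``noise_only``: device opened and closed without use.
    """
    rng = np.random.default_rng(seed)
    strong = lambda: float(rng.uniform(40.0, 70.0))
    weak = lambda: float(rng.uniform(15.0, 25.0))
    effort = lambda: float(rng.uniform(12.0, 25.0))
    inh_dur = lambda: float(rng.uniform(1.6, 2.4))
    exh_dur = lambda: float(rng.uniform(0.8, 1.4))
    t0 = 0.8 + float(rng.uniform(-0.1, 0.1))

    if name == "correct":
        segs = [
            Segment("blister", t0, 0.035),
            Segment("inhalation", t0 + 0.7, inh_dur(), flow_lpm=strong()),
        ]
    elif name == "exhale_after_prime":
        d_ex = exh_dur()
        segs = [
            Segment("blister", t0, 0.035),
            Segment("exhalation", t0 + 0.5, d_ex, effort_db=effort()),
            Segment("inhalation", t0 + 0.5 + d_ex + 0.4, inh_dur(),
                    flow_lpm=strong()),
        ]
    elif name == "weak_inhalation":
        segs = [
            Segment("blister", t0, 0.035),
            Segment("inhalation", t0 + 0.7, inh_dur(), flow_lpm=weak()),
        ]
    elif name == "double_prime":
        segs = [
            Segment("blister", t0, 0.035),
            Segment("blister", t0 + 0.5, 0.035),
            Segment("inhalation", t0 + 1.2, inh_dur(), flow_lpm=strong()),
        ]
    elif name == "double_dose":
        d1 = inh_dur()
        t1 = t0 + 0.7 + d1 + 1.0
        segs = [
            Segment("blister", t0, 0.035),
            Segment("inhalation", t0 + 0.7, d1, flow_lpm=strong()),
            Segment("blister", t1, 0.035),
            Segment("inhalation", t1 + 0.7, inh_dur(), flow_lpm=strong()),
        ]
    elif name == "no_prime":
        segs = [Segment("inhalation", t0 + 0.3, inh_dur(), flow_lpm=strong())]
    elif name == "no_inhalation":
        segs = [Segment("blister", t0, 0.035)]
    elif name == "inhale_then_exhale":
        d1 = inh_dur()
        segs = [
            Segment("blister", t0, 0.035),
            Segment("inhalation", t0 + 0.7, d1, flow_lpm=strong()),
            Segment("exhalation", t0 + 0.7 + d1 + 0.3, exh_dur(),
                    effort_db=effort()),
        ]
    elif name == "noise_only":
        segs = []
    else:
        raise ValueError(f"unknown scenario preset: {name!r}")

    spec = ScenarioSpec(
        segments=segs,
        duration_s=5.0 if not segs else None,
        noise_floor_db=noise_floor_db,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec
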