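"""Technique-error classification for Diskus-style dry-powder inhalers.

A correct dose attempt is: prime once (lever click opens the foil blister),
then inhale forcefully through the mouthpiece; exhaling into the device
after priming disperses the powder, and a peak inspiratory flow below
~30 L/min delivers the drug poorly. This module houses

* the decision rules that turn an ordered list of acoustic events into a
  technique label for the dose attempt,
* the linear calibration between median inhalation amplitude (AU) and
  peak inspiratory flow (L/min), anchored at 0.016 AU ↔ 30 L/min, and
* the logistic drug-dispersal model for exhalations into the mouthpiece
  (≥ 50 % of the powder dispersed at an effort of 1 dB above the noise
  floor), used for reporting estimated dose loss — the error *label*
  follows the categorical rule "any exhalation after priming".

Only critical checklist steps produce error labels; non-critical steps
(keeping the device horizontal, the 5-s breath hold) are never penalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit, logit

from .events import AcousticEvent

__all__ = [
    "TechniqueLabel",
    "CalibrationModel",
    "DispersalModel",
    "TechniqueConfig",
    "LABEL_VALUES",
    "CRITICAL_LABELS",
    "classify_inhaler_event",
    "amplitude_to_flow",
    "fit_calibration",
    "dispersal_fraction",
]

#: All technique labels; every value except "correct" marks a critical error.
LABEL_VALUES = (
    "correct",
    "no_priming",
    "exhalation_after_priming",
    "weak_inhalation",
    "no_inhalation",
    "double_priming",
    "double_dose",
    "inadequate_technique",
)
CRITICAL_LABELS = tuple(v for v in LABEL_VALUES if v != "correct")

#: Median-amplitude threshold below which an inhalation is a critical error
#: (corresponds to a peak inspiratory flow of 30 L/min). Strict "<": an
#: inhalation at exactly 0.016 AU is adequate.
WEAK_INHALATION_AU = 0.016
WEAK_INHALATION_FLOW_LPM = 30.0


@dataclass(frozen=True)
class TechniqueLabel:
    """Outcome of classifying one dose attempt."""

    value: str
    critical: bool

    def __post_init__(self) -> None:
        if self.value not in LABEL_VALUES:
            raise ValueError(f"unknown technique label: {self.value!r}")

    @classmethod
    def of(cls, value: str) -> "TechniqueLabel":
        return cls(value=value, critical=value != "correct")

    def __str__(self) -> str:  # convenient for CSV round-trips
        return self.value


@dataclass(frozen=True)
class CalibrationModel:
    """Linear amplitude→flow map through the origin.

    ``gain`` has units (L/min) per AU; the default is fixed by the anchor
    0.016 AU ↔ 30 L/min. ``r_squared`` is populated when the model was
    fitted from calibration pairs.
    """

    gain: float = WEAK_INHALATION_FLOW_LPM / WEAK_INHALATION_AU
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError("calibration gain must be positive")


DEFAULT_CALIBRATION = CalibrationModel()


def amplitude_to_flow(
    median_amplitude: float, model: CalibrationModel = DEFAULT_CALIBRATION
) -> float:
    """Peak inspiratory flow (L/min) for a median inhalation amplitude (AU)."""
    if median_amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    return model.gain * float(median_amplitude)


def flow_to_amplitude(
    flow_lpm: float, model: CalibrationModel = DEFAULT_CALIBRATION
) -> float:
    """Inverse calibration: median amplitude (AU) producing a given flow."""
    if flow_lpm < 0:
        raise ValueError("flow must be non-negative")
    return float(flow_lpm) / model.gain


def fit_calibration(pairs: Iterable[tuple[float, float]]) -> CalibrationModel:
    """Least-squares line through the origin from (AU, L/min) pairs.

    Returns the fitted model with its coefficient of determination
    (computed against the mean-flow baseline).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (amplitude, flow) pairs")
    a, f = arr[:, 0], arr[:, 1]
    if np.all(a == 0):
        raise ValueError("degenerate calibration: all amplitudes are zero")
    gain = float(np.dot(a, f) / np.dot(a, a))
    resid = f - gain * a
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationModel(gain=gain, r_squared=r2)


@dataclass(frozen=True)
class DispersalModel:
    """Logistic model of the drug fraction dispersed by an exhalation.

    ``threshold_db`` is the exhalation effort, in dB above the recording's
    noise floor, at which ``fraction_at_threshold`` (default one half) of
    the primed powder is dispersed; ``steepness`` is the logistic slope in
    1/dB. The curve is non-decreasing with limits 0 and 1.
    """

    threshold_db: float = 1.0
    fraction_at_threshold: float = 0.5
    steepness: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.fraction_at_threshold < 1:
            raise ValueError("fraction_at_threshold must be in (0, 1)")
        if not self.steepness > 0:
            raise ValueError("steepness must be positive")


DEFAULT_DISPERSAL = DispersalModel()


def dispersal_fraction(
    effort_db: float, model: DispersalModel = DEFAULT_DISPERSAL
) -> float:
    """Fraction of the primed dose dispersed by an exhalation of given effort."""
    effort_db = float(effort_db)
    if not np.isfinite(effort_db):
        if np.isneginf(effort_db):
            return 0.0
        if np.isposinf(effort_db):
            return 1.0
        raise ValueError("effort must not be NaN")
    z = model.steepness * (effort_db - model.threshold_db) + logit(
        model.fraction_at_threshold
    )
    return float(expit(z))


@dataclass
class TechniqueConfig:
    """Tunables of the dose-attempt decision rules."""

    weak_inhalation_au: float = WEAK_INHALATION_AU
    #: maximum gap (s) between the end of the dose inhalation and a following
    #: exhalation for the pattern "breathe in and straight out into the
    #: device" to count as inadequate technique
    inhale_exhale_gap_s: float = 1.0
    #: window (s) within which a second complete prime+inhale sequence in a
    #: separate recording still counts as a double dose
    double_dose_window_s: float = 120.0


DEFAULT_TECHNIQUE = TechniqueConfig()


def _kind_events(events: Sequence[AcousticEvent], kind: str) -> list[AcousticEvent]:
    return [e for e in events if e.kind == kind]


def classify_inhaler_event(
    events: Sequence[AcousticEvent],
    config: TechniqueConfig = DEFAULT_TECHNIQUE,
    return_trace: bool = False,
):
    """Label one dose attempt from its ordered, classified acoustic events.

    The rules are evaluated in a fixed priority order so that co-occurring
    problems resolve deterministically: structural errors (priming and dose
    count) outrank breath-direction errors, which outrank amplitude errors.

    1. no blister click → ``no_priming`` (an empty recording — device opened
       and closed without use — also lands here);
    2. two blister clicks with no inhalation between them → ``double_priming``
       (the second lever movement wastes the first dose);
    3. two or more complete blister→inhalation sequences → ``double_dose``;
    4. any exhalation after the last blister and before an inhalation →
       ``exhalation_after_priming``;
    5. no inhalation after the last blister → ``no_inhalation``;
    6. dose inhalation with median amplitude strictly below 0.016 AU
       (< 30 L/min) → ``weak_inhalation``;
    7. dose inhalation immediately followed by an exhalation into the device
       → ``inadequate_technique``;
    otherwise ``correct``.

    With ``return_trace=True``, also returns the list of rule checks that
    were evaluated, for reporting.
    """
    events = sorted(events, key=lambda e: e.start_s)
    trace: list[str] = []

    def done(value: str):
        label = TechniqueLabel.of(value)
        return (label, trace) if return_trace else label

    blisters = _kind_events(events, "blister")
    inhalations = _kind_events(events, "inhalation")
    exhalations = _kind_events(events, "exhalation")

    # (1) priming
    if not blisters:
        trace.append("no blister click found -> no_priming")
        return done("no_priming")
    trace.append(f"{len(blisters)} blister click(s) found")

    # (2) repeated priming without an intervening inhalation
    for b1, b2 in zip(blisters, blisters[1:]):
        between = [
            i for i in inhalations if b1.start_s < i.start_s < b2.start_s
        ]
        if not between:
            trace.append(
                f"blisters at {b1.start_s:.2f}s and {b2.start_s:.2f}s with no "
                "inhalation between -> double_priming"
            )
            return done("double_priming")

    # (3) repeated complete dose sequences
    n_sequences = 0
    for idx, b in enumerate(blisters):
        next_b = blisters[idx + 1].start_s if idx + 1 < len(blisters) else np.inf
        if any(b.start_s < i.start_s < next_b for i in inhalations):
            n_sequences += 1
    if n_sequences >= 2:
        trace.append(f"{n_sequences} complete prime+inhale sequences -> double_dose")
        return done("double_dose")

    # (4) exhalation between priming and inhalation
    last_blister = blisters[-1]
    after = [i for i in inhalations if i.start_s > last_blister.start_s]
    first_inhalation = after[0] if after else None
    for x in exhalations:
        if x.start_s <= last_blister.start_s:
            continue
        if first_inhalation is None or x.start_s < first_inhalation.start_s:
            trace.append(
                f"exhalation at {x.start_s:.2f}s after priming and before any "
                "inhalation -> exhalation_after_priming"
            )
            return done("exhalation_after_priming")

    # (5) inhalation present?
    if first_inhalation is None:
        trace.append("no inhalation after priming -> no_inhalation")
        return done("no_inhalation")

    # (6) inhalation strength
    amp = first_inhalation.median_amplitude
    if amp is not None and amp < config.weak_inhalation_au:
        trace.append(
            f"dose inhalation median amplitude {amp:.4f} AU < "
            f"{config.weak_inhalation_au} AU -> weak_inhalation"
        )
        return done("weak_inhalation")

    # (7) residual abnormal patterns
    for x in exhalations:
        gap = x.start_s - first_inhalation.end_s
        if 0 <= gap <= config.inhale_exhale_gap_s:
            trace.append(
                f"exhalation into device {gap:.2f}s after the inhalation -> "
                "inadequate_technique"
            )
            return done("inadequate_technique")

    trace.append("nominal prime+inhale sequence -> correct")
    return done("correct")
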