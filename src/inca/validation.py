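"""Detector validation against synthetic ground truth.

Builds a corpus of scenario renders plus noise-only recordings, runs the
full detection chain, and scores blister/inhalation detection against the
generator's annotations: sensitivity over true blister and inhalation
events, and specificity over negatives (true exhalation intervals and
noise-only recordings, neither of which may attract a detected blister or
inhalation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import detect_events
from .synthetic.audio import generate_inhaler_recording, scenario_preset

__all__ = ["DetectionMetrics", "detection_metrics", "DEFAULT_CORPUS_PRESETS"]

DEFAULT_CORPUS_PRESETS = (
    "correct",
    "exhale_after_prime",
    "weak_inhalation",
    "double_prime",
)


@dataclass
class DetectionMetrics:
    """Event-level detection scores against ground truth."""

    true_positives: int
    false_negatives: int
    true_negatives: int
    false_positives: int

    @property
    def sensitivity(self) -> float:
        return self.true_positives / max(self.true_positives + self.false_negatives, 1)

    @property
    def specificity(self) -> float:
        return self.true_negatives / max(self.true_negatives + self.false_positives, 1)


def _overlap(a: float, b: float, c: float, d: float) -> float:
    return max(0.0, min(b, d) - max(a, c))


def _matches(event, truth) -> bool:
    dur_t = truth["end_s"] - truth["start_s"]
    return _overlap(
        event.start_s, event.end_s, truth["start_s"], truth["end_s"]
    ) >= 0.5 * min(event.duration_s, dur_t)


def detection_metrics(
    n_per_preset: int = 100,
    n_noise_only: int = 100,
    seed: int = 0,
    presets: tuple[str, ...] = DEFAULT_CORPUS_PRESETS,
) -> DetectionMetrics:
    """Score the detector on a freshly generated corpus.

    A true blister/inhalation counts as detected when a same-kind event
    overlaps at least half of the shorter of the two intervals. A negative
    (a true exhalation, or a whole noise-only recording) counts as a false
    positive when any detected blister or inhalation overlaps it.
    """
    rng = np.random.default_rng(seed)
    tp = fn = tn = fp = 0
    for preset in presets:
        for _ in range(n_per_preset):
            s = int(rng.integers(0, 2**31 - 1))
            rec, ann = generate_inhaler_recording(scenario_preset(preset, seed=s))
            events = detect_events(rec)
            for truth in ann:
                if truth["kind"] in ("blister", "inhalation"):
                    hit = any(
                        e.kind == truth["kind"] and _matches(e, truth)
                        for e in events
                    )
                    tp += hit
                    fn += not hit
                elif truth["kind"] == "exhalation":
                    bad = any(
                        e.kind in ("blister", "inhalation") and _matches(e, truth)
                        for e in events
                    )
                    fp += bad
                    tn += not bad
    for _ in range(n_noise_only):
        s = int(rng.integers(0, 2**31 - 1))
        rec, _ = generate_inhaler_recording(scenario_preset("noise_only", seed=s))
        events = detect_events(rec)
        bad = any(e.kind in ("blister", "inhalation") for e in events)
        fp += bad
        tn += not bad
    return DetectionMetrics(
        true_positives=tp, false_negatives=fn,
        true_negatives=tn, false_positives=fp,
    )
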