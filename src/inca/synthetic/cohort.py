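"""Synthetic dosing histories and clinical cohorts.

Emulates the study conditions of a 12-week twice-daily inhaler cohort:
each subject takes the morning/evening dose with a personal probability,
each taken dose carries a critical technique error with a configurable
probability, and the change in clinical outcome (AQLQ, PEFR) is linked
linearly to the subject's mean combined weekly adherence rate expressed
as a fraction of perfect adherence (slope/2). Baseline values are drawn
within the published cohort ranges (AQLQ ~1–7 with mean near 4, PEFR a
few hundred L/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from ..adherence import DoseLog, weekly_series
from ..technique import CRITICAL_LABELS, TechniqueLabel
from .audio import ScenarioSpec, scenario_preset

__all__ = [
    "OutcomeLink",
    "CohortSpec",
    "generate_subject_log",
    "generate_cohort",
    "scenario_for_label",
    "ERROR_LABEL_WEIGHTS",
]

#: Mix of critical-error types among error-labelled doses; exhaling into
#: the mouthpiece after priming is by far the most common error observed,
#: the remaining patterns are infrequent.
ERROR_LABEL_WEIGHTS = {
    "exhalation_after_priming": 0.55,
    "weak_inhalation": 0.20,
    "no_inhalation": 0.10,
    "double_priming": 0.10,
    "double_dose": 0.05,
}

#: Dosing slots: 08:00 and 20:00, jittered uniformly within +/- 90 min.
DOSE_SLOTS_H = (8, 20)
SLOT_JITTER_MIN = 90.0

_LABEL_TO_PRESET = {
    "correct": "correct",
    "no_priming": "no_prime",
    "exhalation_after_priming": "exhale_after_prime",
    "weak_inhalation": "weak_inhalation",
    "no_inhalation": "no_inhalation",
    "double_priming": "double_prime",
    "double_dose": "double_dose",
    "inadequate_technique": "inhale_then_exhale",
}


def scenario_for_label(label: TechniqueLabel | str, seed: int = 0) -> ScenarioSpec:
    """Audio scenario whose rendered recording carries the given label."""
    value = label.value if isinstance(label, TechniqueLabel) else str(label)
    return scenario_preset(_LABEL_TO_PRESET[value], seed=seed)


@dataclass(frozen=True)
class OutcomeLink:
    """Linear coefficients from mean combined rate fraction (slope/2) to
    outcome change: ΔAQLQ = aqlq·fraction + noise, ΔPEFR analogous."""

    aqlq: float = 0.7
    pefr: float = 25.0


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``adherence_profile`` gives each subject's per-slot dose-taking
    probability; if ``None`` profiles are drawn from a Beta distribution
    with mean 0.89 (the cohort-average adherence). ``error_rate`` is the
    probability that a taken dose contains a critical technique error,
    either a scalar or per-subject values.
    """

    n_subjects: int = 51
    days: int = 84
    prescribed_per_day: int = 2
    adherence_profile: Sequence[float] | None = None
    error_rate: float | Sequence[float] = 0.10
    outcome_link: OutcomeLink = field(default_factory=OutcomeLink)
    aqlq_noise_sd: float = 0.3
    pefr_noise_sd: float = 15.0
    start_date: date = date(2024, 1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.days < 7:
            raise ValueError("days must be >= 7")
        if self.adherence_profile is not None:
            p = np.asarray(self.adherence_profile, dtype=float)
            if p.size != self.n_subjects or np.any((p < 0) | (p > 1)):
                raise ValueError("adherence_profile must be n_subjects probabilities in [0,1]")
        e = np.atleast_1d(np.asarray(self.error_rate, dtype=float))
        if np.any((e < 0) | (e > 1)):
            raise ValueError("error_rate must be in [0,1]")


def generate_subject_log(
    subject_id: str,
    p_take: float,
    error_rate: float,
    days: int,
    start_date: date = date(2024, 1, 1),
    seed: int = 0,
    prescribed_per_day: int = 2,
) -> DoseLog:
    """Simulate one subject's dose log.

    Each of the twice-daily slots is taken independently with probability
    ``p_take``; a taken dose is a critical error with probability
    ``error_rate`` (type drawn from :data:`ERROR_LABEL_WEIGHTS`).
    Timestamps are jittered uniformly within ±90 min of the slot.
    """
    if not 0 <= p_take <= 1 or not 0 <= error_rate <= 1:
        raise ValueError("probabilities must be in [0,1]")
    rng = np.random.default_rng(seed)
    labels = list(ERROR_LABEL_WEIGHTS)
    weights = np.array([ERROR_LABEL_WEIGHTS[v] for v in labels])
    weights = weights / weights.sum()

    events: list[tuple[datetime, TechniqueLabel]] = []
    for day in range(days):
        for slot_h in DOSE_SLOTS_H[:prescribed_per_day]:
            if rng.random() >= p_take:
                continue
            jitter = rng.uniform(-SLOT_JITTER_MIN, SLOT_JITTER_MIN)
            ts = datetime.combine(
                start_date + timedelta(days=day), time(slot_h, 0)
            ) + timedelta(minutes=float(jitter))
            if rng.random() < error_rate:
                value = labels[rng.choice(len(labels), p=weights)]
            else:
                value = "correct"
            events.append((ts, TechniqueLabel.of(value)))
    return DoseLog(
        subject_id=subject_id,
        events=events,
        prescribed_per_day=prescribed_per_day,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[DoseLog], pd.DataFrame]:
    """Simulate dose logs and linked clinical records for a cohort.

    Returns ``(logs, clinical)`` where ``clinical`` has columns
    ``subject_id, aqlq_base, aqlq_end, pefr_base, pefr_end, age, bmi``.
    The outcome changes are ``link × (mean combined weekly slope / 2)``
    plus Gaussian noise; AQLQ values are clipped to the instrument's
    1–7 range (rarely binding at the default parameters).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    if spec.adherence_profile is not None:
        p_take = np.asarray(spec.adherence_profile, dtype=float)
    else:
        p_take = rng.beta(8.9, 1.1, size=n)  # mean 0.89
    err = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.error_rate, dtype=float)), (n,)
    ) if np.ndim(spec.error_rate) else np.full(n, float(spec.error_rate))

    seeds = rng.integers(0, 2**31 - 1, size=n)
    logs: list[DoseLog] = []
    mean_combined = np.zeros(n)
    weeks = spec.days // 7
    for i in range(n):
        log = generate_subject_log(
            subject_id=f"S{i:03d}",
            p_take=float(p_take[i]),
            error_rate=float(err[i]),
            days=spec.days,
            start_date=spec.start_date,
            seed=int(seeds[i]),
            prescribed_per_day=spec.prescribed_per_day,
        )
        logs.append(log)
        series = weekly_series(log, start=spec.start_date, weeks=weeks)
        mean_combined[i] = series["combined_slope"].mean()

    frac = mean_combined / 2.0  # fraction of perfect adherence
    aqlq_base = rng.uniform(2.6, 5.2, size=n)
    d_aqlq = spec.outcome_link.aqlq * frac + rng.normal(0, spec.aqlq_noise_sd, n)
    pefr_base = rng.uniform(250.0, 550.0, size=n)
    d_pefr = spec.outcome_link.pefr * frac + rng.normal(0, spec.pefr_noise_sd, n)

    clinical = pd.DataFrame(
        {
            "subject_id": [log.subject_id for log in logs],
            "aqlq_base": np.round(aqlq_base, 3),
            "aqlq_end": np.round(np.clip(aqlq_base + d_aqlq, 1.0, 7.0), 3),
            "pefr_base": np.round(pefr_base, 1),
            "pefr_end": np.round(np.maximum(pefr_base + d_pefr, 50.0), 1),
            "age": rng.integers(18, 81, size=n),
            "bmi": np.round(rng.uniform(17.0, 40.0, size=n), 1),
        }
    )
    return logs, clinical
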