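"""Agreement statistics and adherence–outcome comparisons.

Covers the validation statistics of the acoustic adherence method:
Bland–Altman agreement between dose-counting methods, Pearson correlation,
Cohen's kappa for inter-rater label agreement, grouping of subjects by the
minimum clinically important difference (MCID) of an outcome, and the
ANCOVA-style comparison of weekly adherence-rate trends between improver
and non-improver groups (a linear model with a week × group interaction;
the interaction p-value tests equality of slopes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "ClinicalRecord",
    "AgreementResult",
    "SlopeComparison",
    "bland_altman",
    "cohens_kappa",
    "classify_improver",
    "compare_group_slopes",
    "dose_agreement",
    "read_clinical_csv",
]

AQLQ_MCID = 0.5


@dataclass
class ClinicalRecord:
    """One subject's clinical measurements at baseline and study end."""

    subject_id: str
    aqlq_base: float
    aqlq_end: float
    pefr_base: float
    pefr_end: float
    age: float | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        for v in (self.aqlq_base, self.aqlq_end):
            if v is not None and not np.isnan(v) and not 1.0 <= v <= 7.0:
                raise ValueError("AQLQ scores must lie in [1, 7]")
        for v in (self.pefr_base, self.pefr_end):
            if v is not None and not np.isnan(v) and v <= 0:
                raise ValueError("PEFR must be positive")


def read_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    """Load clinical records from the standard CSV schema."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    return [
        ClinicalRecord(
            subject_id=str(r.subject_id),
            aqlq_base=float(r.aqlq_base),
            aqlq_end=float(r.aqlq_end),
            pefr_base=float(r.pefr_base),
            pefr_end=float(r.pefr_end),
            age=float(r.age) if "age" in df.columns else None,
            bmi=float(r.bmi) if "bmi" in df.columns else None,
        )
        for r in df.itertuples()
    ]


@dataclass
class AgreementResult:
    """Bland–Altman bias and 95 % limits of agreement, plus Pearson's r."""

    bias: float
    loa_lower: float
    loa_upper: float
    pearson_r: float | None
    sd_diff: float
    n: int


def bland_altman(
    measure_1: Sequence[float], measure_2: Sequence[float] | None = None
) -> AgreementResult:
    """Agreement between two paired measurement methods.

    Accepts either two parallel sequences or a single sequence of
    ``(m1, m2)`` pairs. Bias is ``mean(m1 − m2)``; the limits of agreement
    are ``bias ± 1.96·SD`` of the differences. Pearson's r is reported as
    ``None`` when undefined (a constant measure).
    """
    if measure_2 is None:
        arr = np.asarray(list(measure_1), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected (m1, m2) pairs")
        m1, m2 = arr[:, 0], arr[:, 1]
    else:
        m1 = np.asarray(measure_1, dtype=float)
        m2 = np.asarray(measure_2, dtype=float)
    if m1.size != m2.size:
        raise ValueError("measurement sequences must be the same length")
    if m1.size < 3:
        raise ValueError("need at least 3 pairs")
    d = m1 - m2
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if np.std(m1) > 0 and np.std(m2) > 0:
        r = float(stats.pearsonr(m1, m2).statistic)
    else:
        r = None
    return AgreementResult(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        pearson_r=r,
        sd_diff=sd,
        n=int(m1.size),
    )


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two raters' categorical labels.

    (p_o − p_e)/(1 − p_e) with marginal-product expected agreement. The
    degenerate case of both raters constant and identical (p_e = 1) is
    defined as perfect agreement, kappa = 1.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("label sequences must be parallel")
    if len(a) < 2:
        raise ValueError("need at least 2 rated items")
    if len(set(a)) == 1 and a == b:
        return 1.0
    return float(cohen_kappa_score(a, b))


def classify_improver(
    record: ClinicalRecord,
    outcome: str = "aqlq",
    mcid: float | None = None,
) -> str:
    """Group a subject as ``"improver"`` or ``"non-improver"``.

    For AQLQ the default MCID is 0.5 and the comparison is inclusive
    (a change of exactly 0.5 is an improvement, "at least" the MCID).
    For PEFR the default rule is any positive change (strict > 0);
    passing an explicit ``mcid`` makes the comparison inclusive at that
    threshold.
    """
    if outcome == "aqlq":
        base, end = record.aqlq_base, record.aqlq_end
        if mcid is None:
            mcid = AQLQ_MCID
        inclusive = True
    elif outcome == "pefr":
        base, end = record.pefr_base, record.pefr_end
        inclusive = mcid is not None
        if mcid is None:
            mcid = 0.0
    else:
        raise ValueError(f"unknown outcome: {outcome!r}")
    if base is None or end is None or np.isnan(base) or np.isnan(end):
        raise ValueError(f"missing {outcome} values for {record.subject_id}")
    delta = end - base
    improved = delta >= mcid if inclusive else delta > mcid
    return "improver" if improved else "non-improver"


@dataclass
class SlopeComparison:
    """Fitted weekly-rate trends for two groups and their equality test."""

    group_a: str
    group_b: str
    slope_a: float
    slope_b: float
    intercept_a: float
    intercept_b: float
    interaction_p: float
    n_a: int
    n_b: int


def compare_group_slopes(data: pd.DataFrame) -> SlopeComparison:
    """Test whether two groups' adherence-rate trends differ.

    ``data`` is tidy with columns ``subject_id, group, week, rate``
    (weekly adherence rates; exactly two groups). Duplicate subject-week
    entries are averaged, then a normal-theory linear model
    ``rate ~ week × group`` is fitted; the interaction p-value is the
    test of equal slopes and per-group fitted slopes/intercepts are
    returned. Groups are ordered alphabetically (a = first).
    """
    required = {"subject_id", "group", "week", "rate"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    df = (
        data.groupby(["group", "subject_id", "week"], as_index=False)["rate"]
        .mean()
    )
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    if df["week"].nunique() < 2:
        raise ValueError("need at least two distinct weeks")
    for g in groups:
        if df.loc[df["group"] == g, "subject_id"].nunique() < 2:
            raise ValueError("need at least two subjects per group")

    week = df["week"].to_numpy(dtype=float)
    gflag = (df["group"] == groups[1]).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), week, gflag, week * gflag])
    fit = sm.OLS(df["rate"].to_numpy(dtype=float), X).fit()
    b0, b_week, b_group, b_int = fit.params
    interaction_p = float(fit.pvalues[3])
    if not np.isfinite(interaction_p):
        # zero residual variance (e.g. exactly constant rates): the slopes
        # are known without error, so equality is decided by the estimate
        interaction_p = 1.0 if np.isclose(b_int, 0.0) else 0.0
    return SlopeComparison(
        group_a=str(groups[0]),
        group_b=str(groups[1]),
        slope_a=float(b_week),
        slope_b=float(b_week + b_int),
        intercept_a=float(b0),
        intercept_b=float(b0 + b_group),
        interaction_p=interaction_p,
        n_a=int((df["group"] == groups[0]).sum()),
        n_b=int((df["group"] == groups[1]).sum()),
    )


def dose_agreement(
    dose_counter: Sequence[float], n_recordings: Sequence[float]
) -> AgreementResult:
    """Agreement between the mechanical dose counter and the number of
    recordings per device-month (Bland–Altman plus Pearson's r)."""
    return bland_altman(dose_counter, n_recordings)
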