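"""Agreement statistics and group-trend comparison."""

import numpy as np
import pandas as pd
import pytest

from inca.outcomes import (
    ClinicalRecord,
    bland_altman,
    classify_improver,
    cohens_kappa,
    compare_group_slopes,
    dose_agreement,
)


def record(aqlq_base=4.0, aqlq_end=4.5, pefr_base=400.0, pefr_end=410.0):
    return ClinicalRecord("S0", aqlq_base, aqlq_end, pefr_base, pefr_end)


class TestBlandAltman:
    def test_identical_pairs_zero_bias_zero_width(self):
        res = bland_altman([60, 62, 58], [60, 62, 58])
        assert res.bias == 0.0
        assert res.loa_upper - res.loa_lower == 0.0
        assert res.pearson_r == pytest.approx(1.0)

    def test_constant_offset(self):
        res = bland_altman([61, 63, 59], [60, 62, 58])
        assert res.bias == pytest.approx(1.0)
        assert res.loa_upper == res.loa_lower == pytest.approx(1.0)

    def test_hand_computed_example(self):
        m1, m2 = [60, 62, 58, 61], [58, 62, 59, 60]
        d = np.array(m1) - np.array(m2)  # [2, 0, -1, 1]
        res = bland_altman(m1, m2)
        assert res.bias == pytest.approx(d.mean())
        sd = d.std(ddof=1)
        assert res.loa_lower == pytest.approx(d.mean() - 1.96 * sd)
        assert res.loa_upper == pytest.approx(d.mean() + 1.96 * sd)
        assert res.loa_lower <= res.bias <= res.loa_upper

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2])

    def test_zero_variance_measure_reports_r_absent(self):
        res = bland_altman([5, 5, 5], [4, 5, 6])
        assert res.pearson_r is None

    def test_limits_contain_about_95_percent_of_gaussian_differences(self):
        rng = np.random.default_rng(11)
        m1 = rng.normal(60, 5, 20000)
        m2 = m1 + rng.normal(0.5, 2.0, 20000)
        res = bland_altman(m1, m2)
        d = m1 - m2
        inside = np.mean((d >= res.loa_lower) & (d <= res.loa_upper))
        assert 0.94 <= inside <= 0.96


class TestKappa:
    def test_perfect_agreement_two_classes(self):
        assert cohens_kappa(list("ababab"), list("ababab")) == pytest.approx(1.0)

    def test_closed_form_2x2_confusion(self):
        # confusion [[45, 15], [25, 15]]: p_o = 0.6, p_e = 0.54
        a = ["x"] * 60 + ["y"] * 40
        b = ["x"] * 45 + ["y"] * 15 + ["x"] * 25 + ["y"] * 15
        expected = (0.6 - 0.54) / (1 - 0.54)
        assert cohens_kappa(a, b) == pytest.approx(expected)

    def test_independent_raters_kappa_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.choice(["p", "q"], 20000, p=[0.7, 0.3])
        b = rng.choice(["p", "q"], 20000, p=[0.6, 0.4])
        assert abs(cohens_kappa(a, b)) < 0.02

    def test_invariant_to_label_renaming(self):
        a = list("aabbabab")
        b = list("ababaabb")
        renamed = {"a": "Z", "b": "Q"}
        assert cohens_kappa(a, b) == pytest.approx(
            cohens_kappa([renamed[x] for x in a], [renamed[x] for x in b])
        )

    def test_both_raters_constant_identical_defined_as_one(self):
        assert cohens_kappa(["c", "c", "c"], ["c", "c", "c"]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(["a"], ["a", "b"])


class TestImprover:
    def test_aqlq_mcid_boundary_inclusive(self):
        assert classify_improver(record(4.0, 4.5)) == "improver"
        assert classify_improver(record(4.0, 4.0)) == "non-improver"
        assert classify_improver(record(4.0, 4.49)) == "non-improver"

    def test_pefr_any_positive_change(self):
        assert classify_improver(record(pefr_end=401.0), "pefr") == "improver"
        assert classify_improver(record(pefr_end=400.0), "pefr") == "non-improver"

    def test_missing_values_rejected(self):
        rec = record()
        rec.aqlq_end = float("nan")
        with pytest.raises(ValueError):
            classify_improver(rec)

    def test_invariants(self):
        with pytest.raises(ValueError):
            ClinicalRecord("S", 0.5, 4.0, 400, 400)
        with pytest.raises(ValueError):
            ClinicalRecord("S", 4.0, 4.0, -10, 400)


def _group_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "group", "week", "rate"])


class TestGroupSlopes:
    def test_constant_rates_fit_zero_slopes(self):
        rows = [
            (f"{g}{s}", g, w, 1.5)
            for g in ("a", "b")
            for s in range(3)
            for w in range(6)
        ]
        res = compare_group_slopes(_group_frame(rows))
        assert res.slope_a == pytest.approx(0.0, abs=1e-12)
        assert res.slope_b == pytest.approx(0.0, abs=1e-12)
        assert 0.0 <= res.interaction_p <= 1.0

    def test_planted_slope_difference_detected(self):
        rng = np.random.default_rng(21)
        rows = []
        for g, slope in (("improver", 0.1), ("non-improver", -0.1)):
            for s in range(25):
                for w in range(12):
                    rows.append((f"{g}{s}", g, w, 1.2 + slope * w + rng.normal(0, 0.3)))
        res = compare_group_slopes(_group_frame(rows))
        assert res.interaction_p < 0.05
        assert res.slope_a > 0 > res.slope_b  # improver sorts first

    def test_degenerate_designs_rejected(self):
        single_week = [("a0", "a", 0, 1.0), ("a1", "a", 0, 1.1),
                       ("b0", "b", 0, 0.9), ("b1", "b", 0, 1.2)]
        with pytest.raises(ValueError):
            compare_group_slopes(_group_frame(single_week))
        three_groups = [(f"{g}{s}", g, w, 1.0) for g in "abc"
                        for s in range(2) for w in range(3)]
        with pytest.raises(ValueError):
            compare_group_slopes(_group_frame(three_groups))


class TestDoseAgreement:
    def test_noise_free_counts_agree_perfectly(self):
        doses = [58.0, 60.0, 56.0, 62.0]
        res = dose_agreement(doses, doses)
        assert res.bias == 0.0 and res.pearson_r == pytest.approx(1.0)

    def test_anticorrelated_toy_pairs(self):
        res = dose_agreement([1, 2, 3], [3, 2, 1])
        assert res.pearson_r == pytest.approx(-1.0)

    def test_random_recording_loss_shifts_bias_by_expected_amount(self):
        rng = np.random.default_rng(3)
        biases = []
        for _ in range(20):
            doses = rng.integers(50, 61, 30).astype(float)
            recs = np.array([rng.binomial(int(n), 0.95) for n in doses], float)
            biases.append(dose_agreement(doses, recs).bias)
        assert np.mean(biases) == pytest.approx(0.05 * 55, rel=0.15)
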