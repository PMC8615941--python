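"""Detection-threshold scoring, classification, and rating statistics."""

import math
from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionosense.psychophysics import (ANOSMIC, CUTOFF_PRESETS, AfcResponseSeries,
                                     ConcentrationLadder, DEFAULT_LADDER,
                                     classify_sensitivity, descriptor_enrichment,
                                     identification_control, rating_anova,
                                     score_cohort, score_detection,
                                     threshold_by_ageclass)

C = DEFAULT_LADDER.concentrations_mol_per_L


def _suffix_oracle(pattern):
    """Independent statement of the rule: lowest k with all of k..top correct."""
    n = len(pattern)
    for k in range(n):
        if all(pattern[k:]):
            return k
    return None


class TestScoreDetection:
    @pytest.mark.parametrize(
        "pattern, expected_threshold",
        [
            ((0, 0, 0, 1, 1, 1), C[3]),   # clean suffix from rung 4
            ((1, 0, 1, 1, 1, 1), C[2]),   # isolated low hit discarded
            ((0, 0, 0, 0, 0, 0), ANOSMIC),
            ((1, 1, 1, 1, 1, 1), C[0]),
            ((1, 1, 1, 1, 1, 0), ANOSMIC),  # top rung wrong: no qualifying rung
        ],
    )
    def test_threshold_rule(self, pattern, expected_threshold):
        res = score_detection(AfcResponseSeries("p", pattern))
        assert res.threshold_mol_per_L == expected_threshold

    def test_all_64_patterns_match_suffix_oracle(self):
        for pattern in product((False, True), repeat=6):
            res = score_detection(AfcResponseSeries("p", pattern))
            k = _suffix_oracle(pattern)
            if k is None:
                assert res.threshold_mol_per_L == ANOSMIC
                assert res.detection_score == 0
            else:
                assert res.threshold_index == k
                assert res.detection_score == 6 - k

    def test_intensity_labels_do_not_affect_threshold(self):
        base = AfcResponseSeries("p", (0, 0, 0, 1, 1, 1))
        labelled = AfcResponseSeries(
            "p", (0, 0, 0, 1, 1, 1),
            ("nothing", "slight", "distinct", "NA", "distinct", "distinct"))
        assert (score_detection(base).threshold_mol_per_L
                == score_detection(labelled).threshold_mol_per_L)
        assert score_detection(labelled).na_intensity_flag

    def test_length_mismatch_and_bad_label_rejected(self):
        with pytest.raises(ValueError, match="rungs"):
            score_detection(AfcResponseSeries("p", (1, 1, 1)))
        with pytest.raises(ValueError, match="intensity"):
            AfcResponseSeries("p", (1,) * 6, ("loud",) * 6)

    @given(st.lists(st.booleans(), min_size=6, max_size=6),
           st.integers(min_value=0, max_value=5))
    @settings(deadline=None, max_examples=100)
    def test_fixing_a_wrong_answer_never_raises_threshold(self, pattern, flip):
        before = score_detection(AfcResponseSeries("p", tuple(pattern)))
        improved = list(pattern)
        improved[flip] = True
        after = score_detection(AfcResponseSeries("p", tuple(improved)))
        assert after.threshold_mol_per_L <= before.threshold_mol_per_L


class TestClassify:
    @pytest.mark.parametrize(
        "threshold, cutoff, expected",
        [
            (C[3], "methods", "normosmic"),
            (C[5], "methods", "hyposmic"),
            (ANOSMIC, "methods", "hyposmic"),
            (C[4], "methods", "normosmic"),     # at the cutoff: inclusive
            (C[3], "normosmic", "normosmic"),
            (C[5], "hyposmic", "normosmic"),    # top rung included by that preset
        ],
    )
    def test_presets(self, threshold, cutoff, expected):
        res = score_detection(
            AfcResponseSeries("p", tuple(c >= threshold for c in C))
        ) if threshold is not ANOSMIC else score_detection(
            AfcResponseSeries("p", (0,) * 6))
        assert classify_sensitivity(res, cutoff) == expected

    def test_monotone_in_cutoff(self):
        for pattern in product((False, True), repeat=6):
            res = score_detection(AfcResponseSeries("p", pattern))
            classes = [classify_sensitivity(res, c) for c in sorted(C)]
            # raising the cutoff can only switch hyposmic -> normosmic
            assert "".join("N" if c == "normosmic" else "H" for c in classes) \
                == "H" * classes.count("hyposmic") + "N" * classes.count("normosmic")

    def test_unknown_preset_rejected(self):
        res = score_detection(AfcResponseSeries("p", (1,) * 6))
        with pytest.raises(ValueError, match="preset"):
            classify_sensitivity(res, "bogus")


def test_score_cohort_tidy_table():
    rows = []
    for i, c in enumerate(C):
        rows.append({"participant_id": "a", "concentration_mol_per_L": c,
                     "chosen_vial": 1 if i >= 3 else 2, "correct_vial": 1,
                     "intensity_label": "distinct" if i >= 3 else "nothing"})
        rows.append({"participant_id": "b", "concentration_mol_per_L": c,
                     "chosen_vial": 2, "correct_vial": 1,
                     "intensity_label": "nothing"})
    out = score_cohort(pd.DataFrame(rows)).set_index("participant_id")
    assert out.loc["a", "threshold_mol_per_L"] == C[3]
    assert out.loc["a", "class"] == "normosmic"
    assert out.loc["b", "threshold_mol_per_L"] == ANOSMIC
    assert out.loc["b", "class"] == "hyposmic"


class TestRatingAnova:
    def test_matches_textbook_formula_on_hand_sized_input(self):
        data = {"AA": [1, 2, 3, 4], "AG": [2, 3, 4, 5], "GG": [5, 5, 6, 7]}
        table = pd.DataFrame(
            [{"genotype": g, "intensity": v} for g, vals in data.items() for v in vals]
        )
        res = rating_anova(table, "intensity")
        grand = np.mean([v for vals in data.values() for v in vals])
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in data.values())
        ss_within = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in data.values())
        f_expected = (ss_between / 2) / (ss_within / 9)
        assert res.f_statistic == pytest.approx(f_expected, rel=1e-12)

    def test_constant_groups_flagged_degenerate(self):
        table = pd.DataFrame(
            [{"genotype": g, "hedonic": 4} for g in ("AA", "AG", "GG") for _ in range(3)]
        )
        with pytest.warns(UserWarning, match="variance"):
            res = rating_anova(table, "hedonic")
        assert res.degenerate and math.isnan(res.f_statistic)

    def test_published_intensity_effect_is_reliably_detected(self):
        # intensity means/SDs and group sizes from the rating phase
        rng = np.random.default_rng(42)
        n_sig = 0
        n_sims = 200
        for _ in range(n_sims):
            rows = []
            for g, n, mu, sd in (("AG", 105, 4.14, 1.12), ("GG", 33, 4.36, 0.78),
                                 ("AA", 97, 3.22, 1.06)):
                vals = np.clip(np.round(rng.normal(mu, sd, n)), 1, 7)
                rows += [{"genotype": g, "intensity": v} for v in vals]
            res = rating_anova(pd.DataFrame(rows), "intensity")
            sig = res.tukey.set_index(["group_1", "group_2"])["significant"]
            if sig[("AA", "AG")] and sig[("AA", "GG")]:
                n_sig += 1
        assert n_sig / n_sims > 0.97

    def test_degenerate_group_sizes_rejected(self):
        table = pd.DataFrame([{"genotype": "AA", "hedonic": 3}])
        with pytest.raises(ValueError):
            rating_anova(table, "hedonic")


class TestDescriptorEnrichment:
    def test_rose_usage_difference(self):
        wc = pd.DataFrame({"word": ["rose"] * 2, "genotype": ["AA", "AG"],
                           "count": [6, 19]})
        out = descriptor_enrichment(wc, {"AA": 97, "AG": 105})
        p = out.set_index(["group_1", "group_2"]).loc[("AA", "AG"), "p_two_tailed"]
        assert round(p, 2) == 0.01

    def test_identical_proportions_give_p_one(self):
        wc = pd.DataFrame({"word": ["x"] * 2, "genotype": ["AA", "GG"],
                           "count": [5, 5]})
        out = descriptor_enrichment(wc, {"AA": 50, "GG": 50})
        assert out["p_two_tailed"].iloc[0] == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration_on_small_margins(self):
        # every 2x2 with both totals <= 6
        for n1, n2 in product(range(1, 7), range(1, 7)):
            for a, b in product(range(n1 + 1), range(n2 + 1)):
                wc = pd.DataFrame({"word": ["w"] * 2, "genotype": ["g1", "g2"],
                                   "count": [a, b]})
                p_impl = descriptor_enrichment(wc, {"g1": n1, "g2": n2})[
                    "p_two_tailed"].iloc[0]
                k = a + b
                lo, hi = max(0, k - n2), min(n1, k)
                probs = {
                    x: Fraction(comb(n1, x) * comb(n2, k - x), comb(n1 + n2, k))
                    for x in range(lo, hi + 1)
                }
                cut = probs[a] * Fraction(10**7 + 1, 10**7)
                p_oracle = float(sum(q for q in probs.values() if q <= cut))
                assert p_impl == pytest.approx(p_oracle, abs=1e-9)

    def test_count_exceeding_total_rejected(self):
        wc = pd.DataFrame({"word": ["w"], "genotype": ["AA"], "count": [10]})
        with pytest.raises(ValueError, match="total"):
            descriptor_enrichment(wc, {"AA": 5})


class TestIdentificationControl:
    def test_control_odorant_identification_rates(self):
        res = identification_control({"AA": (81, 84), "G_carrier": (118, 122)})
        assert res.overall_rate == pytest.approx(199 / 206)
        assert res.p_value > 0.3  # no genotype effect on the control odorant

    def test_all_groups_perfect_gives_p_one(self):
        res = identification_control({"AA": (10, 10), "AG": (7, 7), "GG": (5, 5)})
        assert res.p_value == pytest.approx(1.0)

    def test_three_group_exact_test_matches_direct_enumeration(self):
        groups = {"AA": (3, 6), "AG": (5, 5), "GG": (2, 4)}
        res = identification_control(groups)
        totals = [6, 5, 4]
        k = 10
        probs = []
        denom = comb(15, k)
        for x1 in range(7):
            for x2 in range(6):
                x3 = k - x1 - x2
                if 0 <= x3 <= 4:
                    probs.append(((x1, x2, x3),
                                  Fraction(comb(6, x1) * comb(5, x2) * comb(4, x3), denom)))
        obs = dict(probs)[(3, 5, 2)]
        expected = float(sum(p for _, p in probs if p <= obs))
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            identification_control({"AA": (0, 0)})


class TestThresholdByAge:
    def test_disjoint_age_groups_detected(self):
        scores = [1, 1, 2, 2, 1, 2, 6, 6, 5, 6, 5, 6]
        ages = [18, 19, 18, 20, 19, 20, 22, 23, 24, 22, 25, 23]
        _, p = threshold_by_ageclass(scores, ages, bins=((16, 20), (21, 25)))
        assert p < 0.01

    def test_single_populated_bin_rejected(self):
        with pytest.warns(UserWarning, match="dropped"):
            with pytest.raises(ValueError, match="two populated"):
                threshold_by_ageclass([1, 2, 3], [18, 19, 20],
                                      bins=((16, 20), (21, 25)))

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(7)
        n_sims, hits = 400, 0
        for _ in range(n_sims):
            ages = rng.integers(16, 34, size=120)
            scores = rng.integers(0, 7, size=120)
            _, p = threshold_by_ageclass(scores, ages)
            hits += p < 0.05
        rate = hits / n_sims
        se = math.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < 3 * se + 0.01  # KW is discrete at these n
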