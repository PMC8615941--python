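"""Forced-choice detection scoring and perceptual-rating statistics.

The detection task is an ascending series of 4-alternative forced-choice
(4-AFC) trials, one per concentration rung. The individual threshold is the
lowest concentration that is answered correctly together with *every* higher
concentration: a participant who truly smells the odorant at some rung is
assumed not to err above it, so isolated lucky guesses low on the ladder are
discarded. A participant who misses the top rung has no qualifying rung and
is recorded with the ANOSMIC sentinel (threshold = +inf).

Sensitivity classes are cut on the threshold concentration. Three published
operating points are exposed as named presets: the methods cutoff 2.05e-3
mol/L that separates sensitive from insensitive, the normosmic definition
2.05e-4 mol/L (where carriers of the functional receptor detect), and the
hyposmic definition 2.05e-2 mol/L (the ladder top).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ANOSMIC",
    "CUTOFF_PRESETS",
    "ConcentrationLadder",
    "AfcResponseSeries",
    "DetectionResult",
    "score_detection",
    "classify_sensitivity",
    "score_cohort",
    "rating_anova",
    "descriptor_enrichment",
    "identification_control",
    "threshold_by_ageclass",
]

#: Sentinel threshold for series with no qualifying rung (top rung wrong).
ANOSMIC = math.inf

INTENSITY_LABELS = frozenset({"nothing", "slight", "distinct", "NA"})

#: Published classification cutoffs (mol/L).
CUTOFF_PRESETS = {
    "methods": 2.05e-3,    # sensitive/insensitive discrimination cutoff
    "normosmic": 2.05e-4,  # concentration detected by functional-allele carriers
    "hyposmic": 2.05e-2,   # ladder top; 100-fold detection-score definition
}


@dataclass(frozen=True)
class ConcentrationLadder:
    """Ascending odorant concentrations presented one 4-AFC trial each.

    Parameters
    ----------
    concentrations_mol_per_L :
        Strictly increasing concentrations, low to high.
    n_alternatives :
        Vials per trial (one odorous, rest blank); chance success is
        ``1 / n_alternatives``.
    """

    concentrations_mol_per_L: tuple[float, ...] = (
        2.05e-7, 2.05e-6, 2.05e-5, 2.05e-4, 2.05e-3, 2.05e-2,
    )
    n_alternatives: int = 4

    def __post_init__(self) -> None:
        c = self.concentrations_mol_per_L
        if len(c) < 1:
            raise ValueError("ladder needs at least one concentration")
        if any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("concentrations must be strictly increasing")
        if self.n_alternatives < 2:
            raise ValueError("n_alternatives must be >= 2")
        object.__setattr__(self, "concentrations_mol_per_L", tuple(float(x) for x in c))

    def __len__(self) -> int:
        return len(self.concentrations_mol_per_L)

    @property
    def chance_level(self) -> float:
        return 1.0 / self.n_alternatives

    def index_of(self, concentration: float, rtol: float = 1e-6) -> int:
        for i, c in enumerate(self.concentrations_mol_per_L):
            if math.isclose(c, concentration, rel_tol=rtol):
                return i
        raise ValueError(f"concentration {concentration!r} is not a ladder rung")


DEFAULT_LADDER = ConcentrationLadder()


@dataclass(frozen=True)
class AfcResponseSeries:
    """One participant's per-rung 4-AFC outcomes, ascending concentration order."""

    participant_id: str
    correct: tuple[bool, ...]
    intensity: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "correct", tuple(bool(x) for x in self.correct))
        if not self.intensity:
            object.__setattr__(self, "intensity", ("NA",) * len(self.correct))
        if len(self.intensity) != len(self.correct):
            raise ValueError("intensity labels must match the number of rungs")
        bad = set(self.intensity) - INTENSITY_LABELS
        if bad:
            raise ValueError(f"unknown intensity labels: {sorted(bad)}")


@dataclass(frozen=True)
class DetectionResult:
    """Scored detection series.

    ``detection_score`` counts rungs from the top of the ladder: it is the
    length of the maximal all-correct suffix (6 = detected from the lowest
    rung, 1 = top rung only, 0 = ANOSMIC, one past the top).
    """

    participant_id: str
    threshold_mol_per_L: float  # ANOSMIC (= inf) when no rung qualifies
    threshold_index: int | None
    detection_score: int
    na_intensity_flag: bool = False


def score_detection(series: AfcResponseSeries, ladder: ConcentrationLadder = DEFAULT_LADDER) -> DetectionResult:
    """Apply the maximal all-correct-suffix threshold rule.

    The threshold is the lowest rung ``k`` such that rungs ``k..top`` are all
    correct. Intensity labels never affect scoring; a correct answer with a
    missing ("NA") rating is counted as correct and flagged.
    """
    if len(series.correct) != len(ladder):
        raise ValueError(
            f"series has {len(series.correct)} rungs, ladder has {len(ladder)}"
        )
    k = len(ladder)
    for i in range(len(ladder) - 1, -1, -1):
        if not series.correct[i]:
            break
        k = i
    score = len(ladder) - k
    threshold = ladder.concentrations_mol_per_L[k] if k < len(ladder) else ANOSMIC
    na_flag = any(
        c and lab == "NA" for c, lab in zip(series.correct, series.intensity)
    )
    return DetectionResult(
        participant_id=series.participant_id,
        threshold_mol_per_L=threshold,
        threshold_index=k if k < len(ladder) else None,
        detection_score=score,
        na_intensity_flag=na_flag,
    )


def classify_sensitivity(
    result: DetectionResult, cutoff_mol_per_L: float | str = "methods"
) -> str:
    """Classify a scored series as ``"normosmic"`` or ``"hyposmic"``.

    Normosmic iff the threshold concentration is at or below the cutoff; the
    ANOSMIC sentinel is always hyposmic. ``cutoff_mol_per_L`` may be a preset
    name from :data:`CUTOFF_PRESETS` or a concentration.
    """
    if isinstance(cutoff_mol_per_L, str):
        try:
            cutoff = CUTOFF_PRESETS[cutoff_mol_per_L]
        except KeyError:
            raise ValueError(
                f"unknown cutoff preset {cutoff_mol_per_L!r}; "
                f"choose from {sorted(CUTOFF_PRESETS)} or pass a concentration"
            ) from None
    else:
        cutoff = float(cutoff_mol_per_L)
    # tolerate float representation noise on rung == cutoff comparisons
    return "normosmic" if result.threshold_mol_per_L <= cutoff * (1 + 1e-9) else "hyposmic"


def score_cohort(
    responses: pd.DataFrame,
    ladder: ConcentrationLadder = DEFAULT_LADDER,
    cutoff_mol_per_L: float | str = "methods",
) -> pd.DataFrame:
    """Score a tidy trial table into one row per participant.

    ``responses`` columns: participant_id, concentration_mol_per_L,
    chosen_vial, correct_vial, intensity_label (optional).
    """
    required = {"participant_id", "concentration_mol_per_L", "chosen_vial", "correct_vial"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"responses table missing columns: {sorted(missing)}")
    rows = []
    for pid, grp in responses.groupby("participant_id", sort=True):
        grp = grp.sort_values("concentration_mol_per_L")
        correct = tuple(
            bool(a == b) for a, b in zip(grp["chosen_vial"], grp["correct_vial"])
        )
        if "intensity_label" in grp.columns:
            labels = tuple(
                lab if isinstance(lab, str) and lab else "NA"
                for lab in grp["intensity_label"].fillna("NA")
            )
        else:
            labels = ()
        series = AfcResponseSeries(str(pid), correct, labels)
        res = score_detection(series, ladder)
        rows.append(
            {
                "participant_id": res.participant_id,
                "threshold_mol_per_L": res.threshold_mol_per_L,
                "detection_score": res.detection_score,
                "class": classify_sensitivity(res, cutoff_mol_per_L),
                "na_intensity_flag": res.na_intensity_flag,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnovaResult:
    scale: str
    f_statistic: float
    p_value: float
    group_stats: pd.DataFrame  # genotype, n, mean, sd
    tukey: pd.DataFrame  # group_1, group_2, mean_diff, p_adj, significant
    degenerate: bool = False  # zero within-group variance


def rating_anova(table: pd.DataFrame, scale: str, alpha: float = 0.05) -> AnovaResult:
    """One-way fixed-effects ANOVA of a 7-point rating across genotype groups,
    with Tukey HSD (Tukey–Kramer for unequal n) pairwise decisions at ``alpha``.

    ``table`` columns: ``genotype`` plus the named scale column.
    """
    if scale not in table.columns:
        raise ValueError(f"scale {scale!r} not in table")
    groups = {g: np.asarray(sub[scale], dtype=float) for g, sub in table.groupby("genotype")}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    names = sorted(groups)
    samples = [groups[g] for g in names]
    stats_df = pd.DataFrame(
        {
            "genotype": names,
            "n": [len(s) for s in samples],
            "mean": [s.mean() for s in samples],
            "sd": [s.std(ddof=1) for s in samples],
        }
    )
    degenerate = all(s.std(ddof=1) == 0 for s in samples)
    if degenerate:
        warnings.warn("zero within-group variance; F undefined", stacklevel=2)
        f_stat, p = math.nan, math.nan
        tukey = pd.DataFrame(
            columns=["group_1", "group_2", "mean_diff", "p_adj", "significant"]
        )
    else:
        f_stat, p = stats.f_oneway(*samples)
        hsd = stats.tukey_hsd(*samples)
        rows = []
        for i, j in combinations(range(len(names)), 2):
            rows.append(
                {
                    "group_1": names[i],
                    "group_2": names[j],
                    "mean_diff": samples[i].mean() - samples[j].mean(),
                    "p_adj": float(hsd.pvalue[i, j]),
                    "significant": bool(hsd.pvalue[i, j] < alpha),
                }
            )
        tukey = pd.DataFrame(rows)
    return AnovaResult(scale, float(f_stat), float(p), stats_df, tukey, degenerate)


def descriptor_enrichment(
    word_counts: pd.DataFrame, genotype_totals: dict[str, int]
) -> pd.DataFrame:
    """Pairwise two-tailed Fisher tests of descriptor usage between genotypes.

    For every word and every genotype pair, the 2x2 table is
    (used, not used) x (group 1, group 2); the two-tailed p sums point
    probabilities no larger than the observed one (standard software
    convention, as implemented by scipy).

    ``word_counts`` columns: word, genotype, count (users of the word).
    """
    required = {"word", "genotype", "count"}
    if required - set(word_counts.columns):
        raise ValueError(f"word_counts needs columns {sorted(required)}")
    if (word_counts["count"] < 0).any():
        raise ValueError("negative counts")
    wide = (
        word_counts.pivot_table(index="word", columns="genotype", values="count",
                                aggfunc="sum", fill_value=0)
    )
    for g in wide.columns:
        if g not in genotype_totals:
            raise ValueError(f"no total for genotype {g!r}")
        if (wide[g] > genotype_totals[g]).any():
            raise ValueError(f"count exceeds total for genotype {g!r}")
    rows = []
    for word, row in wide.iterrows():
        for g1, g2 in combinations(sorted(wide.columns), 2):
            a, b = int(row[g1]), int(row[g2])
            table = [[a, genotype_totals[g1] - a], [b, genotype_totals[g2] - b]]
            p = stats.fisher_exact(table, alternative="two-sided")[1]
            rows.append(
                {"word": word, "group_1": g1, "group_2": g2,
                 "count_1": a, "count_2": b, "p_two_tailed": float(p)}
            )
    return pd.DataFrame(rows)


def _exact_rx2_p(success: np.ndarray, totals: np.ndarray) -> float:
    """Conditional exact p for an r x 2 table (Freeman–Halton for 2 columns).

    Enumerates all tables with the observed margins; p is the total
    probability of tables no more probable than the observed one under the
    multivariate hypergeometric null.
    """
    from math import comb

    k = int(success.sum())
    n = totals.astype(int)
    denom = comb(int(n.sum()), k)

    def prob(cells: tuple[int, ...]) -> float:
        num = 1
        for c, t in zip(cells, n):
            num *= comb(int(t), c)
        return num / denom

    p_obs = prob(tuple(int(x) for x in success))
    total = 0.0
    # depth-first over compositions of k bounded by row totals
    def rec(i: int, remaining: int, cells: list[int]) -> None:
        nonlocal total
        if i == len(n) - 1:
            if remaining <= n[i]:
                p = prob(tuple(cells + [remaining]))
                if p <= p_obs * (1 + 1e-12):
                    total += p
            return
        tail_cap = int(n[i + 1 :].sum())
        for c in range(max(0, remaining - tail_cap), min(int(n[i]), remaining) + 1):
            rec(i + 1, remaining - c, cells + [c])

    rec(0, k, [])
    return min(total, 1.0)


@dataclass(frozen=True)
class IdentificationControl:
    rates: pd.DataFrame  # group, n_correct, n_total, rate
    overall_rate: float
    p_value: float


def identification_control(groups: dict[str, tuple[int, int]]) -> IdentificationControl:
    """Exact test of identification success (e.g., of a control odorant)
    across genotype groups.

    ``groups`` maps group label to ``(n_correct, n_total)``. Two groups use
    the 2x2 Fisher exact test; more use its r x 2 (Freeman–Halton)
    generalisation by full enumeration.
    """
    if not groups:
        raise ValueError("no groups")
    for g, (c, t) in groups.items():
        if t <= 0:
            raise ValueError(f"empty group {g!r}")
        if not 0 <= c <= t:
            raise ValueError(f"bad counts for group {g!r}")
    names = sorted(groups)
    correct = np.array([groups[g][0] for g in names])
    totals = np.array([groups[g][1] for g in names])
    if len(names) == 2:
        table = [[correct[0], totals[0] - correct[0]], [correct[1], totals[1] - correct[1]]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        p = _exact_rx2_p(correct, totals)
    rates = pd.DataFrame(
        {"group": names, "n_correct": correct, "n_total": totals,
         "rate": correct / totals}
    )
    return IdentificationControl(rates, float(correct.sum() / totals.sum()), p)


DEFAULT_AGE_BINS = ((16, 20), (21, 25), (26, 33))


def threshold_by_ageclass(
    scores: Sequence[float],
    ages: Sequence[float],
    bins: Sequence[tuple[int, int]] = DEFAULT_AGE_BINS,
) -> tuple[float, float]:
    """Kruskal–Wallis comparison of detection scores across age classes.

    Empty bins are dropped with a warning; fewer than two populated bins is
    an error. Returns ``(H, p)``.
    """
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(scores) != len(ages):
        raise ValueError("scores and ages differ in length")
    groups = []
    for lo, hi in bins:
        sel = scores[(ages >= lo) & (ages <= hi)]
        if len(sel) == 0:
            warnings.warn(f"age bin {lo}-{hi} has no members; dropped", stacklevel=2)
        else:
            groups.append(sel)
    if len(groups) < 2:
        raise ValueError("need at least two populated age bins")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
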