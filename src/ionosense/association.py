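"""Genotype-level statistics for a biallelic locus and a binary phenotype.

Covers allele frequencies, the Hardy–Weinberg exact test (conditioning on
allele counts), the recessive-model 2x2 association with a conditional-MLE
odds ratio and exact confidence interval, genotype-based phenotype
prediction accuracy, two-sample Kolmogorov–Smirnov comparison of detection
scores, and a minimal allelic genome scan with quality filters.

Allele roles follow the focal receptor variant: A is the insensitive
(loss-of-function) allele, G the functional one; the insensitive phenotype
is recessive, so association tables contrast AA against G carriers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import lgamma, log

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.stats import nchypergeom_fisher

__all__ = [
    "GenotypeCounts",
    "TwoByTwo",
    "AssociationResult",
    "allele_frequency",
    "hwe_exact",
    "recessive_table",
    "fisher_association",
    "prediction_accuracy",
    "ks_two_sample",
    "gwas_scan",
]

HYPOSMIC, NORMOSMIC = "hyposmic", "normosmic"
GENOTYPES = ("AA", "AG", "GG")


@dataclass(frozen=True)
class GenotypeCounts:
    """Diploid genotype counts at a biallelic site (A/G coding)."""

    n_AA: int
    n_AG: int
    n_GG: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_AG, self.n_GG) < 0:
            raise ValueError("negative genotype count")
        if self.total < 1:
            raise ValueError("empty genotype table")

    @property
    def total(self) -> int:
        return self.n_AA + self.n_AG + self.n_GG

    @classmethod
    def from_labels(cls, genotypes) -> "GenotypeCounts":
        g = pd.Series(list(genotypes)).replace({"GA": "AG"})
        bad = set(g) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotype labels: {sorted(bad)}")
        c = g.value_counts()
        return cls(int(c.get("AA", 0)), int(c.get("AG", 0)), int(c.get("GG", 0)))


def allele_frequency(counts: GenotypeCounts) -> float:
    """Frequency of the A allele: (2 n_AA + n_AG) / (2 n)."""
    return (2 * counts.n_AA + counts.n_AG) / (2 * counts.total)


def hwe_exact(counts: GenotypeCounts, mid_p: bool = False) -> float:
    """Exact Hardy–Weinberg test conditioning on the observed allele counts.

    The p-value sums the probabilities of all heterozygote counts compatible
    with the allele margin that are no more probable than the observed one
    (plain exact p; ``mid_p=True`` halves the observed count's own
    contribution).
    """
    n = counts.total
    n_a = 2 * counts.n_AA + counts.n_AG  # copies of the rarer-or-not allele A
    n_minor = min(n_a, 2 * n - n_a)

    def log_prob(h: int) -> float:
        # P(het = h | allele counts) under HWE, h same parity as n_minor
        n_hom_minor = (n_minor - h) // 2
        n_hom_major = n - h - n_hom_minor
        return (
            lgamma(n + 1)
            - lgamma(n_hom_minor + 1) - lgamma(h + 1) - lgamma(n_hom_major + 1)
            + h * log(2)
            + lgamma(n_minor + 1) + lgamma(2 * n - n_minor + 1) - lgamma(2 * n + 1)
        )

    hs = range(n_minor % 2, n_minor + 1, 2)
    probs = {h: math.exp(log_prob(h)) for h in hs}
    p_obs = probs[counts.n_AG]
    p = sum(q for q in probs.values() if q <= p_obs * (1 + 1e-12))
    if mid_p:
        p -= 0.5 * p_obs
    return min(p, 1.0)


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 count table, exposure rows (e.g. AA vs G carrier) by outcome
    columns (e.g. hyposmic vs normosmic)."""

    a: int  # exposed, outcome
    b: int  # exposed, no outcome
    c: int  # unexposed, outcome
    d: int  # unexposed, no outcome

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class AssociationResult:
    sample_or: float
    cond_mle_or: float
    ci95: tuple[float, float]
    p_two_tailed: float
    haldane_or: float  # +0.5-corrected sample OR, for zero-cell transparency


def _cmle_support(t: TwoByTwo) -> tuple[int, int, int, int, int]:
    N = t.a + t.b + t.c + t.d
    K = t.a + t.b   # row-1 margin
    n = t.a + t.c   # col-1 margin
    lo = max(0, n + K - N)
    hi = min(K, n)
    return N, K, n, lo, hi


def _conditional_mle(t: TwoByTwo) -> float:
    """Odds ratio maximising the noncentral hypergeometric likelihood of the
    table given its margins; solved via the score equation E[a | psi] = a
    (exponential-family identity) by bracketed root finding on log(psi)."""
    N, K, n, lo, hi = _cmle_support(t)
    if t.a == lo:
        return 0.0
    if t.a == hi:
        return math.inf
    xs = np.arange(lo, hi + 1)
    log_base = np.array(
        [lgamma(K + 1) - lgamma(x + 1) - lgamma(K - x + 1)
         + lgamma(N - K + 1) - lgamma(n - x + 1) - lgamma(N - K - n + x + 1)
         for x in xs]
    )

    def mean_minus_obs(log_psi: float) -> float:
        w = log_base + xs * log_psi
        w -= w.max()
        w = np.exp(w)
        return float((xs * w).sum() / w.sum()) - t.a

    return math.exp(brentq(mean_minus_obs, -50.0, 50.0, xtol=1e-12, rtol=1e-10))


def _exact_ci(t: TwoByTwo, level: float = 0.95) -> tuple[float, float]:
    """CI by inverting the one-sided exact tests at (1-level)/2 each: the
    bounds solve P(X >= a | psi_lo) = alpha/2 and P(X <= a | psi_hi) = alpha/2
    on the conditional (noncentral hypergeometric) distribution."""
    N, K, n, lo, hi = _cmle_support(t)
    alpha = (1 - level) / 2

    def upper_tail(log_psi: float) -> float:
        return nchypergeom_fisher.sf(t.a - 1, N, n, K, math.exp(log_psi)) - alpha

    def lower_tail(log_psi: float) -> float:
        return nchypergeom_fisher.cdf(t.a, N, n, K, math.exp(log_psi)) - alpha

    ci_lo = 0.0 if t.a == lo else math.exp(brentq(upper_tail, -50, 50, xtol=1e-10))
    ci_hi = math.inf if t.a == hi else math.exp(brentq(lower_tail, -50, 50, xtol=1e-10))
    return ci_lo, ci_hi


def fisher_association(t: TwoByTwo) -> AssociationResult:
    """Exact 2x2 association: sample odds ratio ad/bc, conditional-MLE odds
    ratio, 95% CI by exact-test inversion, and the two-tailed Fisher p
    (point-probability summation)."""
    if t.b * t.c == 0:
        sample_or = math.inf if t.a * t.d > 0 else math.nan
    else:
        sample_or = (t.a * t.d) / (t.b * t.c)
    haldane = ((t.a + 0.5) * (t.d + 0.5)) / ((t.b + 0.5) * (t.c + 0.5))
    p = float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])
    return AssociationResult(
        sample_or=sample_or,
        cond_mle_or=_conditional_mle(t),
        ci95=_exact_ci(t),
        p_two_tailed=p,
        haldane_or=haldane,
    )


def recessive_table(genotypes, phenotypes) -> TwoByTwo:
    """Cross-tabulate AA vs G-carrier against hyposmic vs normosmic."""
    genotypes = ["AG" if g == "GA" else g for g in genotypes]
    phenotypes = list(phenotypes)
    if len(genotypes) != len(phenotypes):
        raise ValueError("genotype/phenotype length mismatch")
    if not genotypes:
        raise ValueError("empty input")
    bad_g = set(genotypes) - set(GENOTYPES)
    bad_p = set(phenotypes) - {HYPOSMIC, NORMOSMIC}
    if bad_g or bad_p:
        raise ValueError(f"unknown labels: {sorted(bad_g | bad_p)}")
    a = sum(1 for g, p in zip(genotypes, phenotypes) if g == "AA" and p == HYPOSMIC)
    b = sum(1 for g, p in zip(genotypes, phenotypes) if g == "AA" and p == NORMOSMIC)
    c = sum(1 for g, p in zip(genotypes, phenotypes) if g != "AA" and p == HYPOSMIC)
    d = sum(1 for g, p in zip(genotypes, phenotypes) if g != "AA" and p == NORMOSMIC)
    return TwoByTwo(a, b, c, d)


def prediction_accuracy(genotypes, phenotypes) -> float:
    """Fraction of phenotypes matching the recessive rule AA -> hyposmic,
    G carrier -> normosmic."""
    t = recessive_table(genotypes, phenotypes)
    return (t.a + t.d) / (t.a + t.b + t.c + t.d)


def ks_two_sample(scores_1, scores_2) -> tuple[float, float]:
    """Two-sided Kolmogorov–Smirnov test (max ECDF gap D, asymptotic p)."""
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("empty sample")
    res = stats.ks_2samp(s1, s2, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def _genotype_counts_from_row(row: np.ndarray) -> GenotypeCounts | None:
    obs = row[row >= 0]
    if len(obs) == 0:
        return None
    return GenotypeCounts(
        int((obs == 2).sum()), int((obs == 1).sum()), int((obs == 0).sum())
    )


def gwas_scan(
    genotype_matrix: np.ndarray,
    phenotypes,
    site_ids=None,
    missing_threshold: float = 0.2,
    hwe_threshold: float = 1e-6,
) -> tuple[pd.DataFrame, dict]:
    """Minimal allelic case/control scan over a sites x individuals matrix.

    Genotypes are alt-allele (A) dosages 0/1/2 with -1 for missing. Sites
    are filtered in order — missingness > ``missing_threshold``, then HWE
    exact p < ``hwe_threshold`` — before testing. Each remaining site gets an
    allelic 2x2 chi-square (case vs control allele counts), replaced by the
    Fisher exact test whenever any expected cell is below 5. Returns the site
    table sorted by p plus a report with filter counts and the genomic
    inflation factor lambda (median chi-square over its null median).
    """
    G = np.asarray(genotype_matrix)
    phen = np.asarray(phenotypes)
    if G.ndim != 2 or G.shape[1] != len(phen):
        raise ValueError("genotype matrix columns must match phenotype length")
    if site_ids is None:
        site_ids = [f"site{i}" for i in range(G.shape[0])]
    case = phen == HYPOSMIC
    rows, n_missing_fail, n_hwe_fail = [], 0, 0
    chi_stats = []
    for i in range(G.shape[0]):
        row = G[i]
        missing_frac = float((row < 0).mean())
        if missing_frac > missing_threshold:
            n_missing_fail += 1
            rows.append({"id": site_ids[i], "p": math.nan, "or": math.nan,
                         "filter_status": "missingness"})
            continue
        counts = _genotype_counts_from_row(row)
        if counts is None or hwe_exact(counts) < hwe_threshold:
            n_hwe_fail += 1
            rows.append({"id": site_ids[i], "p": math.nan, "or": math.nan,
                         "filter_status": "hwe"})
            continue
        ok = row >= 0
        a = int(row[ok & case].sum())                  # case A alleles
        b = int(2 * (ok & case).sum() - a)
        c = int(row[ok & ~case].sum())
        d = int(2 * (ok & ~case).sum() - c)
        table = np.array([[a, b], [c, d]])
        if table.sum() == 0:
            rows.append({"id": site_ids[i], "p": math.nan, "or": math.nan,
                         "filter_status": "empty"})
            continue
        expected = stats.contingency.expected_freq(table) if table.min() >= 0 else None
        or_ = (a * d) / (b * c) if b * c > 0 else math.inf if a * d > 0 else math.nan
        if expected is not None and expected.min() >= 5:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            chi_stats.append(float(chi2))
        else:
            p = float(stats.fisher_exact(table)[1])
            # convert to an equivalent chi-square quantile for lambda
            chi_stats.append(float(stats.chi2.isf(max(p, 1e-300), df=1)))
        rows.append({"id": site_ids[i], "p": float(p), "or": float(or_),
                     "filter_status": "pass"})
    result = pd.DataFrame(rows)
    passed = result["filter_status"] == "pass"
    n_tests = int(passed.sum())
    result.loc[passed, "p_bonferroni"] = (result.loc[passed, "p"] * n_tests).clip(upper=1.0)
    result = result.sort_values("p", na_position="last").reset_index(drop=True)
    lam = (
        float(np.median(chi_stats) / stats.chi2.median(df=1)) if chi_stats else math.nan
    )
    report = {
        "n_sites": G.shape[0],
        "n_failed_missingness": n_missing_fail,
        "n_failed_hwe": n_hwe_fail,
        "n_tested": n_tests,
        "lambda_gc": lam,
    }
    return result, report
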