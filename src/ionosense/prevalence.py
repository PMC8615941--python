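"""Ancestry-stratified genotype tables, source-population estimates, and
counterfactual admixture projections.

The central object is the 3 (ancestry diplotype strata) x 3 (genotype) count
table. Source-population allele and genotype frequencies are estimated from
the ancestry-homogeneous strata only: individuals whose two locus copies both
trace to the same source carry unmixed information about that source, while
dual-ancestry individuals are excluded from source estimation. Counterfactual
prevalence of the insensitive (AA) genotype under a hypothetical admixture
proportion alpha follows from mixing the source allele frequencies and
applying random-mating (Hardy–Weinberg) proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestry import STATES, UNASSIGNED, DiplotypeCall
from .association import AssociationResult, TwoByTwo, fisher_association

__all__ = [
    "StratifiedTable",
    "SourceEstimate",
    "stratify",
    "mean_locus_ancestry",
    "wilson_interval",
    "source_frequencies",
    "ancestry_phenotype_association",
    "project_prevalence",
    "counterfactual_report",
]

GENOTYPES = ("AA", "AG", "GG")
PHENOTYPES = ("hyposmic", "normosmic")


@dataclass(frozen=True)
class StratifiedTable:
    """Counts per ancestry stratum, by genotype and optionally phenotype."""

    genotype_counts: pd.DataFrame            # index STATES, columns GENOTYPES
    phenotype_counts: pd.DataFrame | None    # index STATES, columns PHENOTYPES
    n_unassigned: int = 0

    def __post_init__(self) -> None:
        gc = self.genotype_counts
        if list(gc.index) != list(STATES) or list(gc.columns) != list(GENOTYPES):
            raise ValueError("genotype_counts must be indexed by the 3 strata x 3 genotypes")
        if (gc.values < 0).any():
            raise ValueError("negative count")

    @property
    def stratum_totals(self) -> pd.Series:
        return self.genotype_counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.genotype_counts.values.sum())

    def render(self) -> pd.DataFrame:
        """'percent (count)' rendering of the genotype table, two decimals,
        half-up — comparable by string with the published stratified table."""
        from decimal import ROUND_HALF_UP, Decimal

        def cell(count: int, total: int) -> str:
            if total == 0:
                return "- (0)"
            pct = Decimal(100 * count) / Decimal(total)
            pct = pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
            return f"{pct.normalize()}% ({count})"

        rows = {}
        for stratum in STATES:
            total = int(self.stratum_totals[stratum])
            rows[stratum] = [
                cell(int(self.genotype_counts.loc[stratum, g]), total)
                for g in GENOTYPES
            ] + [total]
        out = pd.DataFrame.from_dict(rows, orient="index",
                                     columns=[*GENOTYPES, "Total"])
        out.index.name = "locus_ancestry"
        return out


def stratify(
    calls: list[DiplotypeCall] | pd.DataFrame,
    genotypes: pd.Series | dict,
    phenotypes: pd.Series | dict | None = None,
) -> StratifiedTable:
    """Cross-tabulate genotype (and optionally phenotype) by ancestry
    diplotype stratum. UNASSIGNED calls are excluded and counted.

    ``calls`` is either a DataFrame with columns participant_id/state or a
    list of calls aligned with the genotype index; genotypes and phenotypes
    are participant-id-keyed.
    """
    if isinstance(calls, pd.DataFrame):
        call_states = pd.Series(
            calls["state"].values, index=calls["participant_id"].astype(str)
        )
    else:
        gt_index = pd.Series(dict(genotypes)).index
        if len(calls) != len(gt_index):
            raise ValueError("calls and genotypes differ in length")
        call_states = pd.Series([c.state for c in calls], index=gt_index)
    gt = pd.Series(dict(genotypes)).astype(str).replace({"GA": "AG"})
    gt.index = gt.index.astype(str)
    missing = set(call_states.index) ^ set(gt.index)
    if missing:
        raise ValueError(f"ids do not join across inputs: {sorted(missing)[:5]} ...")
    joined = pd.DataFrame({"state": call_states, "genotype": gt.loc[call_states.index]})
    if phenotypes is not None:
        ph = pd.Series(dict(phenotypes)).astype(str)
        ph.index = ph.index.astype(str)
        if set(ph.index) != set(joined.index):
            raise ValueError("phenotype ids do not join")
        joined["phenotype"] = ph.loc[joined.index]
    n_unassigned = int((joined["state"] == UNASSIGNED).sum())
    joined = joined[joined["state"] != UNASSIGNED]
    gc = (
        joined.groupby(["state", "genotype"]).size().unstack(fill_value=0)
        .reindex(index=STATES, columns=GENOTYPES, fill_value=0)
    )
    pc = None
    if phenotypes is not None:
        pc = (
            joined.groupby(["state", "phenotype"]).size().unstack(fill_value=0)
            .reindex(index=STATES, columns=PHENOTYPES, fill_value=0)
        )
    return StratifiedTable(gc, pc, n_unassigned)


def mean_locus_ancestry(table: StratifiedTable) -> float:
    """African fraction of locus copies: (2 n_AFR/AFR + n_AFR/EAS) / (2 n)."""
    t = table.stratum_totals
    total = int(t.sum())
    if total == 0:
        raise ValueError("empty table")
    return float((2 * t["AFR/AFR"] + t["AFR/EAS"]) / (2 * total))


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    from scipy.stats import norm

    if n == 0:
        raise ValueError("n must be positive")
    z = norm.ppf(0.5 + level / 2)
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


@dataclass(frozen=True)
class SourceEstimate:
    """Per-source insensitive-allele frequency f_A and insensitive-genotype
    frequency f_AA, estimated from the homogeneous-ancestry strata, with
    Wilson 95% CIs."""

    f_A_afr: float
    f_A_afr_ci: tuple[float, float]
    f_AA_afr: float
    f_AA_afr_ci: tuple[float, float]
    f_A_eas: float
    f_A_eas_ci: tuple[float, float]
    f_AA_eas: float
    f_AA_eas_ci: tuple[float, float]
    n_afr: int
    n_eas: int


def source_frequencies(table: StratifiedTable) -> SourceEstimate:
    """Source-population frequencies from the homogeneous strata only
    (AFR/AFR informs the African source, EAS/EAS the East Asian source)."""
    gc = table.genotype_counts
    out = {}
    for src, stratum in (("afr", "AFR/AFR"), ("eas", "EAS/EAS")):
        row = gc.loc[stratum]
        n = int(row.sum())
        if n == 0:
            raise ValueError(f"empty homogeneous stratum {stratum}: "
                             f"{src} source estimate undefined")
        k_alleles = int(2 * row["AA"] + row["AG"])
        out[f"f_A_{src}"] = k_alleles / (2 * n)
        out[f"f_A_{src}_ci"] = wilson_interval(k_alleles, 2 * n)
        out[f"f_AA_{src}"] = int(row["AA"]) / n
        out[f"f_AA_{src}_ci"] = wilson_interval(int(row["AA"]), n)
        out[f"n_{src}"] = n
    return SourceEstimate(**out)


def ancestry_phenotype_association(table: StratifiedTable) -> tuple[AssociationResult, dict]:
    """Association between homogeneous locus ancestry and hyposmia: 2x2 of
    (EAS/EAS vs AFR/AFR) x (hyposmic vs normosmic). The dual-ancestry stratum
    is reported separately, not pooled."""
    if table.phenotype_counts is None:
        raise ValueError("table has no phenotype counts")
    pc = table.phenotype_counts
    for stratum in ("AFR/AFR", "EAS/EAS"):
        if pc.loc[stratum].sum() == 0:
            raise ValueError(f"empty stratum {stratum}")
    t = TwoByTwo(
        a=int(pc.loc["EAS/EAS", "hyposmic"]),
        b=int(pc.loc["EAS/EAS", "normosmic"]),
        c=int(pc.loc["AFR/AFR", "hyposmic"]),
        d=int(pc.loc["AFR/AFR", "normosmic"]),
    )
    het = pc.loc["AFR/EAS"]
    het_total = int(het.sum())
    aside = {
        "het_n": het_total,
        "het_normosmic_fraction": (
            float(het["normosmic"] / het_total) if het_total else math.nan
        ),
    }
    return fisher_association(t), aside


def project_prevalence(
    f_A_afr: float,
    f_A_eas: float,
    alpha: float,
    mode: str = "random_mating_hwe",
    f_AA_afr: float | None = None,
    f_AA_eas: float | None = None,
) -> float:
    """Expected insensitive-genotype (AA) prevalence at admixture proportion
    ``alpha`` (African fraction of locus copies).

    ``random_mating_hwe`` mixes allele frequencies and squares:
    (alpha f_afr + (1-alpha) f_eas)^2. ``side_by_side`` pairs locus copies by
    ancestry draw — alpha^2 f_AA_afr + 2 alpha(1-alpha) f_afr f_eas +
    (1-alpha)^2 f_AA_eas — using observed within-source genotype frequencies;
    the two coincide exactly when each source is itself in Hardy–Weinberg
    proportions (f_AA = f_A^2).
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    for f in (f_A_afr, f_A_eas):
        if not 0 <= f <= 1:
            raise ValueError("allele frequency outside [0, 1]")
    if mode == "random_mating_hwe":
        f_mix = alpha * f_A_afr + (1 - alpha) * f_A_eas
        return f_mix**2
    if mode == "side_by_side":
        faa = f_A_afr**2 if f_AA_afr is None else f_AA_afr
        fee = f_A_eas**2 if f_AA_eas is None else f_AA_eas
        return (
            alpha**2 * faa
            + 2 * alpha * (1 - alpha) * f_A_afr * f_A_eas
            + (1 - alpha) ** 2 * fee
        )
    raise ValueError(f"unknown projection mode {mode!r}")


def counterfactual_report(
    est: SourceEstimate, alpha_observed: float, mode: str = "random_mating_hwe"
) -> pd.DataFrame:
    """Projected AA prevalence at alpha in {0, observed, 1} and the absolute
    and relative reduction attributable to African gene flow (vs alpha = 0)."""
    alphas = {"no_gene_flow": 0.0, "observed": float(alpha_observed),
              "full_replacement": 1.0}
    prev = {
        k: project_prevalence(
            est.f_A_afr, est.f_A_eas, a, mode=mode,
            f_AA_afr=est.f_AA_afr, f_AA_eas=est.f_AA_eas,
        )
        for k, a in alphas.items()
    }
    base = prev["no_gene_flow"]
    rows = [
        {
            "scenario": k,
            "alpha": alphas[k],
            "aa_prevalence": v,
            "abs_reduction_vs_no_flow": base - v,
            "rel_reduction_vs_no_flow": (base - v) / base if base > 0 else math.nan,
        }
        for k, v in prev.items()
    ]
    return pd.DataFrame(rows)
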