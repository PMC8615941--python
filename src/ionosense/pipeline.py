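"""End-to-end analysis chain on a synthetic (or user-supplied) cohort.

Order mirrors the study: genotype summary (allele frequency, Hardy–Weinberg),
detection scoring and recessive association, locus-ancestry decoding,
ancestry stratification, source-population estimates, and the counterfactual
gene-flow projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import ancestry as anc
from . import association as assoc
from . import prevalence as prev
from . import psychophysics as psy
from .io import config_hash, responses_frame
from .synthetic import Cohort, CohortConfig, generate_cohort

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """Failure wrapped with the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Options of an end-to-end run on a synthetic cohort."""

    cohort: CohortConfig
    cutoff: float | str = "methods"
    call_threshold: float = 0.9
    seed: int | None = None  # overrides cohort.seed when given

    def resolved_cohort(self) -> CohortConfig:
        if self.seed is None:
            return self.cohort
        from dataclasses import replace

        return replace(self.cohort, seed=self.seed)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - re-labelled for the report
                raise StageError(name, e) from e
        return wrapped
    return deco


@_stage("simulate")
def _simulate(cfg: CohortConfig) -> Cohort:
    return generate_cohort(cfg)


@_stage("score")
def _score(cohort: Cohort, cutoff):
    scored = psy.score_cohort(responses_frame(cohort), cohort.config.ladder, cutoff)
    return scored.set_index("participant_id")


@_stage("associate")
def _associate(cohort: Cohort, scored) -> dict[str, Any]:
    genotypes = {ind.id: ind.genotype for ind in cohort.individuals}
    classes = scored["class"]
    counts = assoc.GenotypeCounts.from_labels(genotypes.values())
    table = assoc.recessive_table(
        [genotypes[i] for i in classes.index], classes.values
    )
    res = assoc.fisher_association(table)
    scores_by_g = {
        g: scored.loc[[i for i, gt in genotypes.items() if gt == g],
                      "detection_score"].values
        for g in ("AA", "AG", "GG")
    }
    ks = {}
    for g1, g2 in (("AG", "AA"), ("GG", "AA"), ("AG", "GG")):
        if len(scores_by_g[g1]) and len(scores_by_g[g2]):
            d, p = assoc.ks_two_sample(scores_by_g[g1], scores_by_g[g2])
            ks[f"{g1}_vs_{g2}"] = {"D": d, "p": p}
    return {
        "allele_freq": assoc.allele_frequency(counts),
        "hwe_p": assoc.hwe_exact(counts),
        "genotype_counts": {"AA": counts.n_AA, "AG": counts.n_AG, "GG": counts.n_GG},
        "recessive_table": [table.a, table.b, table.c, table.d],
        "or_recessive": {
            "sample": res.sample_or, "cond_mle": res.cond_mle_or,
            "ci95": list(res.ci95), "p": res.p_two_tailed,
        },
        "accuracy": assoc.prediction_accuracy(
            [genotypes[i] for i in classes.index], classes.values
        ),
        "ks_detection_scores": ks,
    }


@_stage("ancestry")
def _ancestry(cohort: Cohort, call_threshold: float):
    cfg = cohort.config
    hmm = anc.build_hmm(cohort.panel, cfg.admixture_alpha,
                        cfg.generations_since_admixture)
    post, _ = anc.posterior_decode_matrix(hmm, cohort.marker_genotypes)
    locus = cohort.panel.nearest_index(cfg.focal_position_morgans)
    calls = [anc.call_locus(post[i], locus, call_threshold)
             for i in range(len(cohort))]
    dosages = post[:, locus, :] @ anc.AFR_COPIES
    return calls, dosages


@_stage("prevalence")
def _prevalence(cohort: Cohort, calls, dosages, scored) -> dict[str, Any]:
    genotypes = {ind.id: ind.genotype for ind in cohort.individuals}
    classes = dict(scored["class"])
    table = prev.stratify(calls, genotypes, classes)
    est = prev.source_frequencies(table)
    res, het = prev.ancestry_phenotype_association(table)
    alpha_moment = float(np.mean(dosages) / 2)
    alpha_called = prev.mean_locus_ancestry(table)
    report = prev.counterfactual_report(est, alpha_called)
    return {
        "stratified_counts": table.genotype_counts.to_dict(),
        "n_unassigned": table.n_unassigned,
        "mean_afr_ancestry": alpha_called,
        "mean_afr_ancestry_moment": alpha_moment,
        "or_ancestry": {
            "sample": res.sample_or, "cond_mle": res.cond_mle_or,
            "ci95": list(res.ci95), "p": res.p_two_tailed,
            "het_normosmic_fraction": het["het_normosmic_fraction"],
        },
        "source_estimates": {
            "f_A_afr": est.f_A_afr, "f_A_afr_ci": list(est.f_A_afr_ci),
            "f_AA_afr": est.f_AA_afr, "f_AA_afr_ci": list(est.f_AA_afr_ci),
            "f_A_eas": est.f_A_eas, "f_A_eas_ci": list(est.f_A_eas_ci),
            "f_AA_eas": est.f_AA_eas, "f_AA_eas_ci": list(est.f_AA_eas_ci),
        },
        "projections": report.to_dict(orient="records"),
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full chain and return one JSON-serialisable report."""
    cohort_cfg = config.resolved_cohort()
    cohort = _simulate(cohort_cfg)
    scored = _score(cohort, config.cutoff)
    report: dict[str, Any] = {
        "seed": cohort_cfg.seed,
        "config_sha": config_hash(cohort_cfg),
        "n_individuals": len(cohort),
    }
    report.update(_associate(cohort, scored))
    calls, dosages = _ancestry(cohort, config.call_threshold)
    report.update(_prevalence(cohort, calls, dosages, scored))
    # observed AA fraction for comparison with the projected prevalence
    report["observed_aa_fraction"] = float(
        np.mean([ind.genotype == "AA" for ind in cohort.individuals])
    )
    return report
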