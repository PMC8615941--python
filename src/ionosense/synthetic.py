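"""Synthetic admixed cohorts with known ground truth.

Emulates the study design end to end: a two-source (African / East Asian)
admixed population generated under a pulse-admixture model — ancestry tracts
laid down as a Poisson recombination process with i.i.d. source labels — a
focal biallelic SNP whose insensitive allele A has source-specific
frequencies, a recessive penetrance model mapping genotype to the
hyposmic/normosmic phenotype with published misclassification rates, an
ascending 6-rung 4-AFC detection task with a 25% guessing floor, and
genotype-dependent 7-point perceptual ratings.

Every draw descends from one root seed through named child streams, so a
cohort is byte-reproducible from its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .panel import MarkerPanel, default_marker_panel
from .psychophysics import DEFAULT_LADDER, AfcResponseSeries, ConcentrationLadder

__all__ = [
    "PenetranceModel",
    "RatingModel",
    "CohortConfig",
    "TrueIndividual",
    "Cohort",
    "simulate_tracts",
    "source_at",
    "draw_focal_genotypes",
    "draw_phenotypes",
    "simulate_afc_responses",
    "generate_cohort",
]

AFR, EAS = "AFR", "EAS"
STATE_OF_COPIES = {2: "AFR/AFR", 1: "AFR/EAS", 0: "EAS/EAS"}

RATING_SCALES = ("hedonic", "intensity", "familiarity", "edibility")


@dataclass(frozen=True)
class PenetranceModel:
    """Recessive penetrance: P(phenotype class | genotype).

    Defaults are the published misclassification-aware rates: 95% of AA are
    hyposmic, 98.9% of AG and 92.9% of GG are normosmic.
    """

    p_hyposmic_given_AA: float = 0.95
    p_normosmic_given_AG: float = 0.989
    p_normosmic_given_GG: float = 0.929

    def __post_init__(self) -> None:
        for v in (self.p_hyposmic_given_AA, self.p_normosmic_given_AG,
                  self.p_normosmic_given_GG):
            if not 0 <= v <= 1:
                raise ValueError("penetrance probabilities must lie in [0, 1]")

    def p_hyposmic(self, genotype: str) -> float:
        if genotype == "AA":
            return self.p_hyposmic_given_AA
        if genotype in ("AG", "GA"):
            return 1 - self.p_normosmic_given_AG
        if genotype == "GG":
            return 1 - self.p_normosmic_given_GG
        raise ValueError(f"unknown genotype {genotype!r}")


#: Published per-genotype rating means and SDs on the four 7-point scales.
DEFAULT_RATING_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "hedonic":     {"AA": (4.18, 1.14), "AG": (4.58, 1.35), "GG": (5.00, 1.30)},
    "intensity":   {"AA": (3.22, 1.06), "AG": (4.14, 1.12), "GG": (4.36, 0.78)},
    "familiarity": {"AA": (2.84, 1.58), "AG": (3.73, 1.55), "GG": (4.12, 1.52)},
    "edibility":   {"AA": (3.30, 1.49), "AG": (3.79, 1.52), "GG": (4.00, 1.52)},
}

RatingModel = dict[str, dict[str, tuple[float, float]]]


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth parameters of a simulated cohort.

    Defaults reproduce the study conditions: admixture proportion
    alpha = 0.313 African, insensitive-allele frequency 0.50 in the African
    and 0.704 in the East Asian source, a ~1000-year-old admixture pulse
    (40 generations at 25 y/generation) on a 1-morgan chromosome, and the
    published penetrance and rating distributions.
    """

    n_individuals: int
    admixture_alpha: float = 0.313
    f_A_afr: float = 0.50
    f_A_eas: float = 0.704
    penetrance: PenetranceModel = field(default_factory=PenetranceModel)
    ladder: ConcentrationLadder = DEFAULT_LADDER
    rating_model: RatingModel = field(default_factory=lambda: DEFAULT_RATING_MODEL)
    generations_since_admixture: int = 40
    chromosome_length_morgans: float = 0.5
    focal_position_morgans: float = 0.25
    normosmic_threshold_index: int = 3  # ladder rung 2.05e-4 mol/L
    guess_prob: float = 0.25
    p_male: float = 154 / 237
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.generations_since_admixture < 1:
            raise ValueError("generations_since_admixture must be >= 1")
        if self.chromosome_length_morgans <= 0:
            raise ValueError("chromosome length must be positive")
        for name in ("admixture_alpha", "f_A_afr", "f_A_eas", "guess_prob", "p_male"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.guess_prob >= 1:
            raise ValueError("guess_prob must be < 1")
        if not 0 <= self.focal_position_morgans <= self.chromosome_length_morgans:
            raise ValueError("focal position outside the chromosome")


@dataclass(frozen=True)
class TrueIndividual:
    """One simulant with all latent and observed layers."""

    id: str
    ancestry_tracts: tuple[tuple[tuple[float, float, str], ...], ...]  # 2 haplotypes
    locus_diplotype: str  # AFR/AFR, AFR/EAS, EAS/EAS at the focal SNP
    genotype: str         # AA / AG / GG at the focal SNP
    phenotype_class: str  # normosmic / hyposmic
    true_threshold_index: int | None  # None = above the ladder top
    responses: AfcResponseSeries
    ratings: dict[str, int]
    sex: str
    age: int


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    panel: MarkerPanel
    individuals: tuple[TrueIndividual, ...]
    marker_genotypes: np.ndarray  # (n_individuals, n_markers) alt dosages

    def __len__(self) -> int:
        return len(self.individuals)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named child RNG streams spawned from one root seed (fixed order)."""
    names = ("tracts", "focal", "markers", "phenotype", "afc", "ratings", "demographics")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_tracts(
    rng: np.random.Generator,
    alpha: float,
    generations: float,
    length_morgans: float,
    haplotype_count: int,
) -> list[tuple[tuple[float, float, str], ...]]:
    """Pulse-admixture ancestry tracts for ``haplotype_count`` haplotypes.

    Breakpoints are a Poisson process with rate generations x length; each
    tract's source is African with probability ``alpha``, independently.
    Tracts tile [0, length) per haplotype.
    """
    if length_morgans <= 0 or generations <= 0:
        raise ValueError("length and generations must be positive")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    out = []
    n_breaks = rng.poisson(generations * length_morgans, size=haplotype_count)
    for nb in n_breaks:
        breaks = np.sort(rng.uniform(0, length_morgans, size=nb))
        edges = np.concatenate([[0.0], breaks, [length_morgans]])
        sources = np.where(rng.random(len(edges) - 1) < alpha, AFR, EAS)
        out.append(tuple(
            (float(a), float(b), str(s))
            for a, b, s in zip(edges[:-1], edges[1:], sources)
        ))
    return out


def source_at(tracts, positions) -> np.ndarray:
    """Source label of one haplotype at each query position."""
    edges = np.array([t[1] for t in tracts])
    sources = np.array([t[2] for t in tracts])
    idx = np.searchsorted(edges, np.atleast_1d(positions), side="right")
    idx = np.clip(idx, 0, len(sources) - 1)
    return sources[idx]


def draw_focal_genotypes(
    copy_sources: np.ndarray,
    f_A_afr: float,
    f_A_eas: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unordered genotypes from per-copy sources: each locus copy carries the
    insensitive allele A with its source's frequency.

    ``copy_sources`` has shape (n, 2) with entries "AFR"/"EAS".
    """
    for f in (f_A_afr, f_A_eas):
        if not 0 <= f <= 1:
            raise ValueError("allele frequency outside [0, 1]")
    copy_sources = np.asarray(copy_sources)
    f = np.where(copy_sources == AFR, f_A_afr, f_A_eas)
    a_copies = (rng.random(copy_sources.shape) < f).sum(axis=1)
    return np.array(["GG", "AG", "AA"])[a_copies]


def draw_phenotypes(
    genotypes, penetrance: PenetranceModel, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli phenotype classes under the recessive penetrance model."""
    p_hypo = np.array([penetrance.p_hyposmic(g) for g in genotypes])
    return np.where(rng.random(len(p_hypo)) < p_hypo, "hyposmic", "normosmic")


def simulate_afc_responses(
    participant_id: str,
    true_threshold_index: int | None,
    ladder: ConcentrationLadder,
    guess_prob: float = 0.25,
    rng: np.random.Generator | None = None,
) -> AfcResponseSeries:
    """Per-rung 4-AFC outcomes for one simulant.

    At or above the true threshold the correct vial is always chosen and the
    odor rated (slight at the threshold rung, distinct above); below it —
    or everywhere, when the threshold lies above the ladder top
    (``true_threshold_index`` None or past the last rung) — the correct vial
    is hit with probability ``guess_prob`` and the vial rated as odorless.
    """
    if not 0 <= guess_prob < 1:
        raise ValueError("guess_prob must lie in [0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    m = len(ladder)
    thr = m if true_threshold_index is None else int(true_threshold_index)
    correct, labels = [], []
    for k in range(m):
        if k >= thr:
            correct.append(True)
            labels.append("slight" if k == thr else "distinct")
        else:
            correct.append(bool(rng.random() < guess_prob))
            labels.append("nothing")
    return AfcResponseSeries(participant_id, tuple(correct), tuple(labels))


def _draw_ratings(
    genotype: str, model: RatingModel, rng: np.random.Generator
) -> dict[str, int]:
    """Rounded, [1, 7]-truncated normal draws per scale."""
    out = {}
    for scale in RATING_SCALES:
        mean, sd = model[scale][genotype]
        out[scale] = int(np.clip(np.round(rng.normal(mean, sd)), 1, 7))
    return out


def generate_cohort(config: CohortConfig, panel: MarkerPanel | None = None) -> Cohort:
    """Generate a complete cohort: tracts, focal genotypes, marker matrix,
    phenotypes, detection responses, ratings, and demographic labels."""
    if panel is None:
        panel = default_marker_panel(length_morgans=config.chromosome_length_morgans)
    if panel.positions_morgans[-1] > config.chromosome_length_morgans:
        raise ValueError("panel extends beyond the chromosome")
    rngs = _streams(config.seed)
    n = config.n_individuals

    haplos = simulate_tracts(
        rngs["tracts"], config.admixture_alpha, config.generations_since_admixture,
        config.chromosome_length_morgans, 2 * n,
    )
    hap_pairs = [(haplos[2 * i], haplos[2 * i + 1]) for i in range(n)]

    # per-copy source at the focal SNP and at every panel marker
    focal_sources = np.array([
        [source_at(h, config.focal_position_morgans)[0] for h in pair]
        for pair in hap_pairs
    ])
    genotypes = draw_focal_genotypes(
        focal_sources, config.f_A_afr, config.f_A_eas, rngs["focal"]
    )
    diplotypes = np.array([
        STATE_OF_COPIES[int((pair == AFR).sum())] for pair in focal_sources
    ])

    pos = panel.positions_morgans
    marker_rng = rngs["markers"]
    G = np.empty((n, len(panel)), dtype=np.int8)
    for i, pair in enumerate(hap_pairs):
        dosage = np.zeros(len(panel), dtype=np.int8)
        for h in pair:
            f = np.where(source_at(h, pos) == AFR, panel.f_alt_afr, panel.f_alt_eas)
            dosage += marker_rng.random(len(panel)) < f
        G[i] = dosage

    phenotypes = draw_phenotypes(genotypes, config.penetrance, rngs["phenotype"])

    afc_rng, rating_rng, demo_rng = rngs["afc"], rngs["ratings"], rngs["demographics"]
    sexes = np.where(demo_rng.random(n) < config.p_male, "M", "F")
    ages = np.clip(np.round(demo_rng.normal(23, 2.82, size=n)), 18, 33).astype(int)

    individuals = []
    width = max(4, len(str(n)))
    for i in range(n):
        pid = f"S{i:0{width}d}"
        thr = (config.normosmic_threshold_index
               if phenotypes[i] == "normosmic" else None)
        responses = simulate_afc_responses(
            pid, thr, config.ladder, config.guess_prob, afc_rng
        )
        individuals.append(TrueIndividual(
            id=pid,
            ancestry_tracts=hap_pairs[i],
            locus_diplotype=str(diplotypes[i]),
            genotype=str(genotypes[i]),
            phenotype_class=str(phenotypes[i]),
            true_threshold_index=thr,
            responses=responses,
            ratings=_draw_ratings(str(genotypes[i]), config.rating_model, rating_rng),
            sex=str(sexes[i]),
            age=int(ages[i]),
        ))
    return Cohort(config=config, panel=panel, individuals=tuple(individuals),
                  marker_genotypes=G)
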