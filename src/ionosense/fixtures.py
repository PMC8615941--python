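"""Published count fixtures for the Malagasy beta-ionone cohort.

These are the printed summary counts of the study this package models: the
rs6591536 genotype distribution, the descriptor-usage table, the ancestry x
genotype stratification, and the 2x2 tables reconstructed from the printed
percentages and margins. They let every headline statistic be recomputed
without the (non-deposited) raw data.
"""

from __future__ import annotations

import pandas as pd

from .association import GenotypeCounts, TwoByTwo
from .prevalence import GENOTYPES, PHENOTYPES, STATES, StratifiedTable

__all__ = [
    "GENOTYPE_COUNTS_ALL",
    "GENOTYPE_COUNTS_TESTED",
    "TABLE_DESCRIPTORS",
    "DESCRIPTOR_TOTALS",
    "stratified_table",
    "RECESSIVE_2X2",
    "ANCESTRY_2X2",
    "IDENTIFICATION_CONTROL_GROUPS",
    "AGE_BIN_SIZES",
]

#: rs6591536 genotype counts among all 235 genotyped participants.
GENOTYPE_COUNTS_ALL = GenotypeCounts(n_AA=97, n_AG=105, n_GG=33)

#: Genotype margins among the 206 participants who took the detection task.
GENOTYPE_COUNTS_TESTED = GenotypeCounts(n_AA=84, n_AG=94, n_GG=28)

#: Descriptor usage (participants using each word, by genotype; words used by
#: more than five participants).
TABLE_DESCRIPTORS = pd.DataFrame(
    [
        ("rose", 6, 19, 3),
        ("flower", 9, 9, 5),
        ("medicine", 11, 6, 3),
        ("perfume", 9, 5, 2),
        ("vitamin", 7, 4, 3),
        ("soap", 4, 5, 2),
        ("candy", 4, 3, 0),
        ("syrup", 6, 1, 0),
        ("fruits", 2, 3, 0),
    ],
    columns=["word", "AA", "AG", "GG"],
)

#: Rating-phase genotype group sizes (n = 235).
DESCRIPTOR_TOTALS = {"AA": 97, "AG": 105, "GG": 33}

#: Ancestry-diplotype x genotype counts (n = 206). Note the published
#: EAS/EAS row total prints 93 although its cells sum to 94; counts are
#: authoritative here.
_STRATA_GENOTYPES = {
    "AFR/AFR": (3, 10, 3),
    "AFR/EAS": (35, 45, 17),
    "EAS/EAS": (46, 40, 8),
}

#: Phenotype counts per stratum, reconstructed from the printed normosmic
#: percentages (93.8% of 16, 61.9% of 97, 51.6% of 93) at the printed totals.
_STRATA_PHENOTYPES = {
    "AFR/AFR": (1, 15),   # hyposmic, normosmic
    "AFR/EAS": (37, 60),
    "EAS/EAS": (45, 48),
}


def stratified_table(with_phenotypes: bool = True) -> StratifiedTable:
    """The published ancestry x genotype stratification as a
    :class:`~ionosense.prevalence.StratifiedTable`."""
    gc = pd.DataFrame.from_dict(_STRATA_GENOTYPES, orient="index",
                                columns=list(GENOTYPES)).reindex(list(STATES))
    pc = None
    if with_phenotypes:
        pc = pd.DataFrame.from_dict(_STRATA_PHENOTYPES, orient="index",
                                    columns=list(PHENOTYPES)).reindex(list(STATES))
    return StratifiedTable(gc, pc, n_unassigned=0)


#: AA vs G carrier x hyposmic vs normosmic, reconstructed from the printed
#: penetrance percentages (95% of 84 AA hyposmic; 98.9% of 94 AG and 92.9%
#: of 28 GG normosmic) rounded to the nearest count.
RECESSIVE_2X2 = TwoByTwo(a=80, b=4, c=3, d=119)

#: EAS/EAS vs AFR/AFR x hyposmic vs normosmic (from the stratified table).
ANCESTRY_2X2 = TwoByTwo(a=45, b=48, c=1, d=15)

#: Control-odorant (tetrahydrothiophene) identification: the printed AA vs
#: G-carrier failure split (3 vs 4 of 7) at the tested genotype margins.
IDENTIFICATION_CONTROL_GROUPS = {
    "AA": (81, 84),        # correct, total
    "G_carrier": (118, 122),
}

#: Age-class sizes used for the threshold-by-age comparison.
AGE_BIN_SIZES = {(16, 20): 85, (21, 25): 99, (26, 33): 22}
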