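"""File formats: VCF genotypes, BED-like ancestry tracts, tidy response /
rating / call tables, and YAML configuration.

Conventions: VCF positions are 1-based; tract files are 0-based half-open
(stated in their headers). Genetic positions (morgans) are mapped to
integer base-pair coordinates at a constant 1 cM/Mb for file output.
Missing genotypes are "." in VCF and empty fields in delimited tables.
Every file this module writes starts with comment headers carrying the tool
version, the seed, and a configuration hash.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import warnings
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .panel import MarkerPanel
from .synthetic import Cohort, CohortConfig, PenetranceModel

__all__ = [
    "config_hash",
    "write_vcf",
    "read_vcf_genotypes",
    "write_tracts",
    "read_tracts",
    "responses_frame",
    "ratings_frame",
    "write_table",
    "read_table",
    "write_config",
    "read_config",
    "FOCAL_ID",
]

FOCAL_ID = "rs6591536"
CHROM = "chr11"
BP_PER_MORGAN = 1e8  # 1 cM/Mb


def config_hash(obj) -> str:
    """Short stable hash of a configuration object."""
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(seed, cfg_hash: str, extra: dict | None = None) -> list[str]:
    lines = [
        f"# ionosense v{__version__}",
        f"# seed: {seed}",
        f"# config_sha: {cfg_hash}",
    ]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def _pos_bp(pos_morgans: float) -> int:
    return int(round(pos_morgans * BP_PER_MORGAN)) + 1


# ---------------------------------------------------------------- VCF

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
_FOCAL_DOSAGE = {"GG": 0, "AG": 1, "GA": 1, "AA": 2}


def write_vcf(path, cohort: Cohort) -> None:
    """Write the cohort's marker matrix plus the focal SNP as a multi-sample
    VCF. The focal SNP carries ID rs6591536 with REF=G, ALT=A (A is the
    insensitive allele), so alt dosage counts A copies."""
    cfg = cohort.config
    panel = cohort.panel
    sample_ids = [ind.id for ind in cohort.individuals]
    records = []  # (pos_bp, id, ref, alt, dosages)
    for j in range(len(panel)):
        records.append(
            (_pos_bp(panel.positions_morgans[j]), panel.ids[j], "T", "C",
             cohort.marker_genotypes[:, j])
        )
    focal = np.array([_FOCAL_DOSAGE[ind.genotype] for ind in cohort.individuals])
    records.append((_pos_bp(cfg.focal_position_morgans), FOCAL_ID, "G", "A", focal))
    records.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=ionosense v{__version__}\n")
        fh.write(f"##ionosense_seed={cfg.seed}\n")
        fh.write(f"##ionosense_config_sha={config_hash(cfg)}\n")
        fh.write(f"##contig=<ID={CHROM}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for pos, vid, ref, alt, dos in records:
            gts = "\t".join(_GT[int(d)] for d in dos)
            fh.write(f"{CHROM}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


@dataclass(frozen=True)
class VcfData:
    """Alt-dosage matrix (sites x samples, -1 missing) plus the focal record
    pulled out separately when requested."""

    matrix: np.ndarray
    site_ids: list[str]
    positions_bp: np.ndarray
    sample_ids: list[str]
    focal_dosage: np.ndarray | None = None
    focal_pos_bp: int | None = None

    @property
    def focal_pos_morgans(self) -> float:
        if self.focal_pos_bp is None:
            raise ValueError("no focal record was read")
        return (self.focal_pos_bp - 1) / BP_PER_MORGAN


def read_vcf_genotypes(path, focal_id: str | None = FOCAL_ID) -> VcfData:
    """Read a multi-sample VCF into a :class:`VcfData`.

    Biallelic SNVs only — multiallelic records are skipped with a warning.
    When ``focal_id`` is given, that record is separated from the marker
    matrix; its absence is an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, site_ids, positions = [], [], []
    focal_row, focal_pos = None, None
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        dosage = np.array(
            [a + b if a >= 0 and b >= 0 else -1
             for a, b, *_ in variant.genotypes],
            dtype=np.int8,
        )
        if focal_id is not None and variant.ID == focal_id:
            focal_row, focal_pos = dosage, int(variant.POS)
            continue
        rows.append(dosage)
        site_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        positions.append(variant.POS)
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic record(s)", stacklevel=2)
    if focal_id is not None and focal_row is None:
        raise ValueError(
            f"focal ID {focal_id!r} not found among {len(site_ids)} biallelic sites"
        )
    matrix = np.vstack(rows) if rows else np.empty((0, len(sample_ids)), dtype=np.int8)
    return VcfData(matrix, site_ids, np.array(positions), sample_ids,
                   focal_row, focal_pos)


# ---------------------------------------------------------------- tracts

def write_tracts(path, cohort: Cohort) -> None:
    """Ancestry truth as BED-like 0-based half-open intervals:
    chrom, start, end, participant_id, haplotype (0/1), source."""
    cfg = cohort.config
    with open(path, "w") as fh:
        for line in _header_lines(cfg.seed, config_hash(cfg),
                                  {"coordinates": "0-based half-open",
                                   "bp_per_morgan": int(BP_PER_MORGAN)}):
            fh.write(line + "\n")
        fh.write("#chrom\tstart\tend\tparticipant_id\thaplotype\tsource\n")
        for ind in cohort.individuals:
            for h, tracts in enumerate(ind.ancestry_tracts):
                for start, end, source in tracts:
                    s = int(round(start * BP_PER_MORGAN))
                    e = int(round(end * BP_PER_MORGAN))
                    fh.write(f"{CHROM}\t{s}\t{e}\t{ind.id}\t{h}\t{source}\n")


def read_tracts(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "participant_id", "haplotype", "source"],
    )
    df["start_morgans"] = df["start"] / BP_PER_MORGAN
    df["end_morgans"] = df["end"] / BP_PER_MORGAN
    return df


# ---------------------------------------------------------------- tables

def responses_frame(cohort: Cohort) -> pd.DataFrame:
    """Tidy per-trial 4-AFC table. The odorous vial is vial 1 by convention;
    a wrong answer is recorded as vial 2."""
    rows = []
    conc = cohort.config.ladder.concentrations_mol_per_L
    for ind in cohort.individuals:
        for c, ok, lab in zip(conc, ind.responses.correct, ind.responses.intensity):
            rows.append({
                "participant_id": ind.id,
                "concentration_mol_per_L": c,
                "chosen_vial": 1 if ok else 2,
                "correct_vial": 1,
                "intensity_label": lab,
            })
    return pd.DataFrame(rows)


def ratings_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for ind in cohort.individuals:
        rows.append({"participant_id": ind.id, "genotype": ind.genotype,
                     **ind.ratings})
    return pd.DataFrame(rows)


def write_table(path, df: pd.DataFrame, seed, cfg_hash: str,
                extra: dict | None = None) -> None:
    """Write a delimited table with an ionosense comment header."""
    buf = _io.StringIO()
    for line in _header_lines(seed, cfg_hash, extra):
        buf.write(line + "\n")
    df.to_csv(buf, sep="\t", index=False, na_rep="")
    Path(path).write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------- config

def write_config(path, config: CohortConfig) -> None:
    d = asdict(config)
    d["ladder"] = {
        "concentrations_mol_per_L": list(config.ladder.concentrations_mol_per_L),
        "n_alternatives": config.ladder.n_alternatives,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_config(path) -> CohortConfig:
    from .psychophysics import ConcentrationLadder

    d = yaml.safe_load(Path(path).read_text())
    if "ladder" in d:
        lad = d["ladder"]
        d["ladder"] = ConcentrationLadder(
            tuple(lad["concentrations_mol_per_L"]), int(lad["n_alternatives"])
        )
    if "penetrance" in d and isinstance(d["penetrance"], dict):
        d["penetrance"] = PenetranceModel(**d["penetrance"])
    if "rating_model" in d and d["rating_model"] is not None:
        d["rating_model"] = {
            scale: {g: tuple(ms) for g, ms in per.items()}
            for scale, per in d["rating_model"].items()
        }
    return CohortConfig(**d)
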