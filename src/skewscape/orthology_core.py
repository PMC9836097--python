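"""Orthologue presence matrices, core-gene calling and peak enrichment.

The input is a Proteinortho-style matrix: one row per gene family, one
column per genome, cells holding comma-separated gene identifiers or ``*``
for absence. A family is *core* when present in at least ceil(fraction * n)
genomes (fraction 0.9 by default, mirroring the >=90 % rule; the ceiling
generalises the nearest-count rule used for very small cohorts).

Enrichment of core genes in GC-skew peak regions is summarised as
(% of peak-region genes that are core)/(% of non-peak genes that are core).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import GenomeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologueMatrix",
    "read_proteinortho",
    "call_core",
    "core_peak_enrichment",
    "family_peak_frequency",
    "localization_heatmap",
]

ABSENT = "*"


@dataclass
class OrthologueMatrix:
    """Family x genome membership with optional family labels.

    ``membership.loc[family, genome]`` is a (possibly empty) tuple of gene
    ids; co-orthologues appear as multi-element tuples.
    """

    membership: pd.DataFrame
    labels: dict[str, str] = field(default_factory=dict)  # family -> core|gta|other

    @property
    def families(self) -> list[str]:
        return list(self.membership.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.membership.columns)

    def presence(self) -> pd.DataFrame:
        """Boolean family x genome presence (any member gene counts)."""
        return self.membership.map(lambda cell: len(cell) > 0)

    def gene_to_family(self) -> dict[str, dict[str, str]]:
        """genome -> gene id -> family id."""
        out: dict[str, dict[str, str]] = {g: {} for g in self.genomes}
        for fam, row in self.membership.iterrows():
            for genome, cell in row.items():
                for gid in cell:
                    out[genome][gid] = fam
        return out

    def write_tsv(self, path: str | Path) -> None:
        """Emit the Proteinortho dialect (# Species, Genes, Alg.-Conn., ...)."""
        pres = self.presence()
        with open(path, "w") as fh:
            fh.write("# Species\tGenes\tAlg.-Conn.\t" + "\t".join(self.genomes) + "\n")
            for fam, row in self.membership.iterrows():
                n_species = int(pres.loc[fam].sum())
                n_genes = int(sum(len(c) for c in row))
                cells = [",".join(c) if c else ABSENT for c in row]
                fh.write(f"{n_species}\t{n_genes}\t1\t" + "\t".join(cells) + "\n")


def read_proteinortho(tsv_path: str | Path) -> OrthologueMatrix:
    """Parse a Proteinortho-dialect TSV into an :class:`OrthologueMatrix`.

    The first three columns (species/gene counts, algebraic connectivity)
    are bookkeeping of the upstream tool and discarded; family ids are
    synthesised as ``fam_0000``... in row order.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 4:
        raise ValueError("Proteinortho table needs >=1 genome column")
    genome_cols = list(df.columns[3:])
    width = df.shape[1]
    records = {}
    for i, row in df.iterrows():
        if row.count() != width:
            raise ValueError(f"ragged row {i} in {tsv_path}")
        fam = f"fam_{i:04d}"
        records[fam] = {
            g: tuple() if row[g] in (ABSENT, "") else tuple(row[g].split(","))
            for g in genome_cols
        }
    membership = pd.DataFrame.from_dict(records, orient="index", columns=genome_cols)
    membership = membership.map(lambda c: c if isinstance(c, tuple) else tuple())
    return OrthologueMatrix(membership=membership)


def call_core(matrix: OrthologueMatrix, fraction: float = 0.9) -> set[str]:
    """Families present in at least ceil(fraction * n_genomes) genomes."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(matrix.genomes)
    if n < 1:
        raise ValueError("matrix has no genomes")
    threshold = math.ceil(fraction * n)
    counts = matrix.presence().sum(axis=1)
    return set(counts.index[counts >= threshold])


def _gene_core_flags(
    matrix: OrthologueMatrix,
    peak_labels: dict[str, dict[str, str]],
    core_families: set[str],
) -> pd.DataFrame:
    g2f = matrix.gene_to_family()
    rows = []
    for genome, labels in peak_labels.items():
        fam_of = g2f.get(genome, {})
        for gid, lab in labels.items():
            fam = fam_of.get(gid)
            rows.append(
                {
                    "genome": genome,
                    "gene_id": gid,
                    "family": fam,
                    "core": fam in core_families,
                    "peak": lab == "peak",
                }
            )
    return pd.DataFrame(rows)


def core_peak_enrichment(
    matrix: OrthologueMatrix,
    peak_labels: dict[str, dict[str, str]],
    core_families: set[str] | None = None,
    fraction: float = 0.9,
) -> float:
    """Ratio of core-gene percentages in peak vs non-peak regions.

    ``peak_labels`` maps genome -> gene id -> 'peak'/'non_peak' (every gene
    labelled). Genes not referenced by the matrix count as non-core.
    """
    if core_families is None:
        core_families = call_core(matrix, fraction)
    df = _gene_core_flags(matrix, peak_labels, core_families)
    if df.empty:
        raise ValueError("no labelled genes")
    peak = df[df["peak"]]
    non = df[~df["peak"]]
    if len(peak) == 0 or len(non) == 0:
        raise ValueError("need both peak and non-peak genes")
    pct_peak = peak["core"].mean()
    pct_non = non["core"].mean()
    if pct_non == 0:
        raise ZeroDivisionError("no core genes outside peaks")
    return float(pct_peak / pct_non)


def family_peak_frequency(
    matrix: OrthologueMatrix, peak_labels: dict[str, dict[str, str]]
) -> pd.DataFrame:
    """Per family: genomes with presence, and genomes where it is in a peak.

    A family counts as "in peak" in a genome when any of its member genes
    there is peak-labelled. Families absent everywhere are excluded.
    """
    rows = []
    for fam, row in matrix.membership.iterrows():
        n_present = 0
        n_peak = 0
        for genome, cell in row.items():
            if not cell:
                continue
            n_present += 1
            labels = peak_labels.get(genome, {})
            if any(labels.get(g) == "peak" for g in cell):
                n_peak += 1
        if n_present:
            rows.append(
                {"family": fam, "n_genomes_present": n_present, "n_in_peak": n_peak}
            )
    return pd.DataFrame(
        rows, columns=["family", "n_genomes_present", "n_in_peak"]
    ).set_index("family")


def localization_heatmap(
    records: list[GenomeRecord],
    matrix: OrthologueMatrix,
    families: list[str],
    n_bins: int = 16,
) -> pd.DataFrame:
    """Counts of family homologues per normalized chromosome bin.

    Chromosomes must be ori-oriented; each homologue's circular midpoint m
    on a chromosome of length L lands in bin floor(n_bins * m/L), capped at
    n_bins - 1 (0-based). Row sums equal the total homologues found per
    family.
    """
    g2f = matrix.gene_to_family()
    counts = np.zeros((len(families), n_bins), dtype=int)
    fam_idx = {f: i for i, f in enumerate(families)}
    for rec in records:
        genome = rec.chromosome.id
        n = rec.chromosome.length
        fam_of = g2f.get(genome, {})
        for gene in rec.genes:
            fam = fam_of.get(gene.gene_id) or gene.family_id
            if fam not in fam_idx:
                continue
            mid = gene.midpoint(n)
            b = min(n_bins - 1, int(n_bins * mid / n))
            counts[fam_idx[fam], b] += 1
    return pd.DataFrame(counts, index=families, columns=range(n_bins))
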