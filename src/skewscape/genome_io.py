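"""Circular chromosomes with gene annotations: reading, rotation, writing.

Bacterial chromosomes are circular, but FASTA/GFF3 files linearise them at an
arbitrary point. Analyses of replichore architecture need every chromosome
anchored at a biologically meaningful position — the origin of replication
(*ori*) or a marker gene such as the GTA major capsid protein gene — so this
module models the circle explicitly and provides lossless rotation of both the
sequence and its annotations.

Conventions
-----------
* Coordinates are 1-based inclusive (GFF3). A gene with ``start > end`` wraps
  the linearisation point of the circle.
* In emitted/ingested GFF3, a wrapping CDS is written with ``end`` beyond the
  sequence length together with ``Is_circular=true`` on the ``region``
  feature, following the GFF3 circular-genome convention.
* Rotation never changes strand labels, base content, gene lengths or any
  pairwise circular distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._dna import (
    circular_midpoint,
    circular_slice,
    interval_span,
    revcomp,
    validate_sequence,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CircularChromosome",
    "GeneAnnotation",
    "GenomeRecord",
    "read_genome",
    "write_genome",
    "reorient_to_position",
    "reorient_to_gene",
    "read_ori_table",
]


@dataclass
class CircularChromosome:
    """A closed circular DNA molecule with declared replication landmarks.

    ``ori`` is the origin of replication (supplied externally, e.g. from an
    Ori-Finder style table); ``ter`` the terminus, which may be left unset and
    inferred later (see :mod:`skewscape.strand_architecture`).
    """

    id: str
    sequence: str
    ori: int = 1
    ter: int | None = None

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence)
        if len(self.sequence) == 0:
            raise ValueError("empty chromosome sequence")
        if not 1 <= self.ori <= self.length:
            raise ValueError(f"ori {self.ori} outside [1, {self.length}]")
        if self.ter is not None and not 1 <= self.ter <= self.length:
            raise ValueError(f"ter {self.ter} outside [1, {self.length}]")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Sequence of a circular 1-based inclusive interval."""
        return circular_slice(self.sequence, start, end)


@dataclass
class GeneAnnotation:
    """A protein-coding gene on a circular chromosome.

    ``start > end`` means the gene wraps the linearisation point. ``strand``
    is ``'+'`` or ``'-'``; ``family_id`` links the gene to an orthologue
    family when an orthology matrix is available.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    product: str | None = None
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"gene {self.gene_id}: coordinates must be >= 1")

    def span(self, chromosome_length: int) -> int:
        return interval_span(self.start, self.end, chromosome_length)

    def midpoint(self, chromosome_length: int) -> int:
        return circular_midpoint(self.start, self.end, chromosome_length)

    def five_prime(self) -> int:
        """5' end of the coding strand: start for '+', end for '-'."""
        return self.start if self.strand == "+" else self.end


@dataclass
class GenomeRecord:
    """A chromosome plus its (uniquely identified) genes."""

    chromosome: CircularChromosome
    genes: list[GeneAnnotation] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids: {dup}")
        n = self.chromosome.length
        for g in self.genes:
            if g.start > n or g.end > n:
                raise ValueError(
                    f"gene {g.gene_id} ({g.start}..{g.end}) outside chromosome "
                    f"of length {n}"
                )

    def gene(self, gene_id: str) -> GeneAnnotation:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"unknown gene id {gene_id!r}")

    def region_sequence(self, gene: GeneAnnotation) -> str:
        """Reference-strand sequence of the gene's interval."""
        return self.chromosome.slice(gene.start, gene.end)

    def coding_sequence(self, gene: GeneAnnotation) -> str:
        """Coding-strand sequence (reverse complement for '-' genes)."""
        seq = self.region_sequence(gene)
        return seq if gene.strand == "+" else revcomp(seq)


# ---------------------------------------------------------------------------
# rotation


def _remap(pos: int, new_first: int, length: int) -> int:
    return (pos - new_first) % length + 1


def reorient_to_position(record: GenomeRecord, new_first: int) -> GenomeRecord:
    """Rotate the chromosome so that ``new_first`` becomes coordinate 1.

    Every annotation, plus *ori*/*ter*, is remapped modulo the length; strand
    labels are untouched. Composing rotations adds their offsets modulo the
    length (group action on the circle).
    """
    chrom = record.chromosome
    n = chrom.length
    if not 1 <= new_first <= n:
        raise ValueError(f"rotation position {new_first} outside [1, {n}]")
    seq = chrom.sequence[new_first - 1 :] + chrom.sequence[: new_first - 1]
    new_chrom = CircularChromosome(
        id=chrom.id,
        sequence=seq,
        ori=_remap(chrom.ori, new_first, n),
        ter=None if chrom.ter is None else _remap(chrom.ter, new_first, n),
    )
    genes = [
        replace(
            g,
            start=_remap(g.start, new_first, n),
            end=_remap(g.end, new_first, n),
        )
        for g in record.genes
    ]
    prov = (record.provenance + "; " if record.provenance else "") + (
        f"rotated to put position {new_first} first"
    )
    return GenomeRecord(chromosome=new_chrom, genes=genes, provenance=prov)


def reorient_to_gene(record: GenomeRecord, gene_id: str) -> GenomeRecord:
    """Rotate so the 5' end (on the coding strand) of ``gene_id`` is first."""
    gene = record.gene(gene_id)
    return reorient_to_position(record, gene.five_prime())


# ---------------------------------------------------------------------------
# file I/O


def read_genome(
    fasta_path: str | Path,
    gff_path: str | Path,
    ori_position: int | None = None,
) -> GenomeRecord:
    """Read one chromosome (FASTA) and its CDS features (GFF3).

    Only CDS features are retained as genes. ``ori_position`` is recorded as
    given; when omitted, ori defaults to 1 with a logged warning (origin
    prediction is not performed here).
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    if not gff_path.exists():
        raise FileNotFoundError(gff_path)

    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ValueError(f"no FASTA records in {fasta_path}")

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    features = list(db.features_of_type("CDS"))
    seqids = {f.seqid for f in features}
    if len(seqids) > 1:
        raise ValueError(f"GFF references multiple sequences: {sorted(seqids)}")
    if features:
        (seqid,) = seqids
        if seqid not in seqs:
            raise ValueError(
                f"GFF sequence id {seqid!r} not found in FASTA ({sorted(seqs)})"
            )
    else:
        seqid = next(iter(seqs))
    sequence = seqs[seqid]
    n = len(sequence)

    circular = False
    for f in db.features_of_type("region"):
        if f.attributes.get("Is_circular", ["false"])[0].lower() == "true":
            circular = True

    genes: list[GeneAnnotation] = []
    for i, f in enumerate(features):
        gene_id = f.attributes.get("ID", [f.attributes.get("locus_tag", [f"cds{i}"])[0]])[0]
        start, end = f.start, f.end
        if end > n:
            if not circular:
                raise ValueError(
                    f"CDS {gene_id} end {end} beyond sequence length {n} and no "
                    "circular wrap declared (Is_circular=true on the region)"
                )
            end -= n  # wraps the origin -> start > end convention
        if start > n:
            raise ValueError(f"CDS {gene_id} start {start} beyond length {n}")
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                start=start,
                end=end,
                strand=f.strand,
                product=f.attributes.get("product", [None])[0],
                family_id=f.attributes.get("family_id", [None])[0],
            )
        )

    if ori_position is None:
        logger.warning("no ori supplied for %s; defaulting to position 1", seqid)
        ori_position = 1
    chrom = CircularChromosome(id=seqid, sequence=sequence, ori=ori_position)
    return GenomeRecord(
        chromosome=chrom,
        genes=genes,
        provenance=f"read from {fasta_path.name} + {gff_path.name}",
    )


def write_genome(
    record: GenomeRecord, fasta_path: str | Path, gff_path: str | Path
) -> None:
    """Write a record as FASTA + GFF3 such that :func:`read_genome` recovers it."""
    chrom = record.chromosome
    n = chrom.length
    seq_rec = SeqRecord(Seq(chrom.sequence), id=chrom.id, description="")
    with open(fasta_path, "w") as fh:
        SeqIO.write([seq_rec], fh, "fasta")

    lines = ["##gff-version 3", f"##sequence-region {chrom.id} 1 {n}"]
    attrs = f"ID={chrom.id};Is_circular=true"
    lines.append(
        "\t".join([chrom.id, "skewscape", "region", "1", str(n), ".", "+", ".", attrs])
    )
    for g in record.genes:
        end = g.end if g.start <= g.end else g.end + n
        attr_parts = [f"ID={g.gene_id}"]
        if g.product:
            attr_parts.append(f"product={g.product}")
        if g.family_id:
            attr_parts.append(f"family_id={g.family_id}")
        lines.append(
            "\t".join(
                [
                    chrom.id,
                    "skewscape",
                    "CDS",
                    str(g.start),
                    str(end),
                    ".",
                    g.strand,
                    "0",
                    ";".join(attr_parts),
                ]
            )
        )
    Path(gff_path).write_text("\n".join(lines) + "\n")


def read_ori_table(path: str | Path) -> dict[str, int]:
    """Read a TSV with columns ``chromosome_id`` and ``ori_position``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chromosome_id", "ori_position"}
    if not required.issubset(df.columns):
        raise ValueError(f"ori table must have columns {sorted(required)}")
    return dict(zip(df["chromosome_id"].astype(str), df["ori_position"].astype(int)))
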