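"""Replichore assignment, leading/lagging strand, typicality and repeats.

A circular chromosome is split by *ori* and *ter* into the right replichore
(the arc running clockwise from *ori* to *ter*) and the left replichore (the
complementary arc). A gene is *leading* (co-directional with the replication
fork) when it sits on the '+' strand of the right replichore or the '-'
strand of the left one, *lagging* (head-on) otherwise.

A gene follows the *typical* GC skew when its reference-strand skew is
positive on the right replichore or negative on the left; a gene that
violates this is flagged as a *potential inversion*, i.e. its composition
suggests it once resided in the opposite orientation. The eight combinations
of replichore x strand x skew sign form a fixed truth table which
:func:`classify_gene_architecture` reproduces.

Long (>800 bp), highly similar (>90 % identity) repeat pairs mark regions of
elevated plasticity; genes are classified *near*/*far* from repeats at a
threshold of 1/1000 of the genome size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._dna import position_in_interval
from .genome_io import GeneAnnotation, GenomeRecord
from .skew_profile import binned_skew, per_gene_skew

logger = logging.getLogger(__name__)

__all__ = [
    "ReplichoreModel",
    "GeneArchitecture",
    "RepeatPair",
    "infer_ter",
    "classify_gene_architecture",
    "classify_record",
    "architecture_summary",
    "compare_groups_kruskal",
    "filter_repeats",
    "read_repeats",
    "repeat_distance_class",
]


@dataclass
class ReplichoreModel:
    """Partition of the circle into right (ori->ter clockwise) and left arcs."""

    ori: int
    ter: int
    length: int

    def __post_init__(self) -> None:
        if self.ori == self.ter:
            raise ValueError("ori and ter must differ")

    def replichore(self, pos: int) -> str:
        """'right' for the arc [ori, ter), 'left' for [ter, ori)."""
        if self.ori < self.ter:
            return "right" if self.ori <= pos < self.ter else "left"
        return "right" if (pos >= self.ori or pos < self.ter) else "left"


@dataclass
class GeneArchitecture:
    """Replichore/strand/skew classification of one gene (one Table row)."""

    gene_id: str
    replichore: str  # right | left
    strand_class: str  # leading | lagging
    skew_sign: str  # positive | negative | zero
    typical: bool
    potential_inversion: bool


def infer_ter(record: GenomeRecord, method: str = "antipodal") -> int:
    """Locate the replication terminus.

    ``antipodal``: the point diametrically opposite *ori* (default).
    ``skew_extremum``: the position where the cumulative GC skew of the
    ori-oriented chromosome is maximal in absolute deviation — on a typical
    chromosome the running sum of the skew rises along the right replichore
    and falls along the left, peaking at *ter*.
    """
    chrom = record.chromosome
    n = chrom.length
    if chrom.ori is None:
        raise ValueError("ori is not set")
    if method == "antipodal":
        return (chrom.ori - 1 + n // 2) % n + 1
    if method == "skew_extremum":
        n_bins = max(100, min(1000, n // 1000))
        from .genome_io import reorient_to_position

        rec = record
        if chrom.ori != 1:
            rec = reorient_to_position(record, chrom.ori)
        track = binned_skew(rec.chromosome, n_bins)
        cum = np.nancumsum(np.nan_to_num(track, nan=0.0))
        k = int(np.argmax(np.abs(cum)))
        pos_oriented = int((k + 1) * n / n_bins)  # end of extremal bin
        return (pos_oriented - 1 + chrom.ori - 1) % n + 1
    raise ValueError(f"unknown ter inference method {method!r}")


def classify_gene_architecture(
    gene: GeneAnnotation, model: ReplichoreModel, gene_skew: float
) -> GeneArchitecture:
    """Classify a gene's replichore, strand class and skew typicality.

    Genes with zero or undefined skew get ``skew_sign='zero'`` and neither
    flag set; they form a third category excluded from typicality
    percentages downstream. A midpoint exactly at *ori*/*ter* is assigned to
    the right replichore (logged).
    """
    mid = gene.midpoint(model.length)
    if mid in (model.ori, model.ter):
        logger.info(
            "gene %s midpoint coincides with ori/ter; assigning right replichore",
            gene.gene_id,
        )
    repl = model.replichore(mid)
    leading = (repl == "right" and gene.strand == "+") or (
        repl == "left" and gene.strand == "-"
    )
    if not np.isfinite(gene_skew) or gene_skew == 0:
        sign = "zero"
        typical = False
        inversion = False
    else:
        sign = "positive" if gene_skew > 0 else "negative"
        typical = (repl == "right") == (gene_skew > 0)
        inversion = not typical
    return GeneArchitecture(
        gene_id=gene.gene_id,
        replichore=repl,
        strand_class="leading" if leading else "lagging",
        skew_sign=sign,
        typical=typical,
        potential_inversion=inversion,
    )


def classify_record(
    record: GenomeRecord,
    ter_method: str = "antipodal",
    gene_skews: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene architecture table for one genome."""
    chrom = record.chromosome
    ter = chrom.ter if chrom.ter is not None else infer_ter(record, ter_method)
    model = ReplichoreModel(ori=chrom.ori, ter=ter, length=chrom.length)
    if gene_skews is None:
        gene_skews = per_gene_skew(record)
    rows = []
    for g in record.genes:
        arch = classify_gene_architecture(g, model, float(gene_skews.loc[g.gene_id, "gc_skew"]))
        rows.append(
            {
                "gene_id": arch.gene_id,
                "replichore": arch.replichore,
                "strand_class": arch.strand_class,
                "skew_sign": arch.skew_sign,
                "typical": arch.typical,
                "potential_inversion": arch.potential_inversion,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def architecture_summary(
    records: list[GenomeRecord],
    gene_sets: dict[str, dict[str, str]] | None = None,
    ter_method: str = "antipodal",
) -> pd.DataFrame:
    """Per-genome (and per gene-group) strand/typicality percentages.

    ``gene_sets`` optionally maps genome id -> gene id -> group label (e.g.
    ``core`` or ``gta``); the group ``all`` is always reported. Percentages
    of the four (strand_class x typicality) categories are over genes with a
    defined non-zero skew and sum to 100 per genome/group; ``pct_leading`` is
    over all genes.
    """
    if not records:
        raise ValueError("empty genome list")
    rows = []
    for rec in records:
        gid = rec.chromosome.id
        table = classify_record(rec, ter_method=ter_method)
        groups = {"all": table.index}
        if gene_sets and gid in gene_sets:
            labels = gene_sets[gid]
            for lab in sorted(set(labels.values())):
                groups[lab] = [g for g in table.index if labels.get(g) == lab]
        for group, idx in groups.items():
            sub = table.loc[idx]
            n = len(sub)
            if n == 0:
                continue
            defined = sub[sub["skew_sign"] != "zero"]
            nd = len(defined)
            row = {
                "genome": gid,
                "group": group,
                "n_genes": n,
                "pct_leading": 100 * (sub["strand_class"] == "leading").mean(),
                "pct_lagging": 100 * (sub["strand_class"] == "lagging").mean(),
                "pct_typical": 100 * defined["typical"].mean() if nd else float("nan"),
            }
            for strand in ("leading", "lagging"):
                for typ, name in ((True, "typical"), (False, "inverted")):
                    frac = (
                        (
                            (defined["strand_class"] == strand)
                            & (defined["typical"] == typ)
                        ).sum()
                        / nd
                        if nd
                        else float("nan")
                    )
                    row[f"pct_{strand}_{name}"] = 100 * frac
            rows.append(row)
    return pd.DataFrame(rows)


def compare_groups_kruskal(groups: dict[str, list[float]]) -> tuple[float, float]:
    """Kruskal-Wallis rank test over named groups of per-genome proportions.

    Returns (H, p). When every observation is identical the statistic is
    undefined; reported as (0, 1) with a warning.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least two observations")
    try:
        h, p = stats.kruskal(*samples)
    except ValueError:
        h, p = float("nan"), float("nan")
    if not (np.isfinite(h) and np.isfinite(p)):
        logger.warning("all values identical; Kruskal-Wallis undefined, reporting p=1")
        return 0.0, 1.0
    return float(h), float(p)


@dataclass
class RepeatPair:
    """Two copies of a repeated element on one chromosome (RepSeek-style)."""

    copy1: tuple[int, int]
    copy2: tuple[int, int]
    length: int
    identity: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("repeat length must be positive")
        if not 0 <= self.identity <= 1:
            raise ValueError("identity must be in [0, 1]")


def read_repeats(path) -> list[RepeatPair]:
    """Read a RepSeek-like TSV: start1, end1, start2, end2, length, identity.

    Malformed rows are skipped with a logged count. Identity may be given as
    a fraction or a percentage (values > 1 are divided by 100).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = ["start1", "end1", "start2", "end2", "length", "identity"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"repeat table missing columns {missing}")
    out, skipped = [], 0
    for _, r in df.iterrows():
        try:
            ident = float(r["identity"])
            if ident > 1:
                ident /= 100
            out.append(
                RepeatPair(
                    copy1=(int(r["start1"]), int(r["end1"])),
                    copy2=(int(r["start2"]), int(r["end2"])),
                    length=int(r["length"]),
                    identity=ident,
                )
            )
        except (ValueError, TypeError):
            skipped += 1
    if skipped:
        logger.warning("skipped %d malformed repeat rows", skipped)
    return out


def _linear_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def filter_repeats(
    raw: list[RepeatPair], min_len: int = 800, min_identity: float = 0.90
) -> list[RepeatPair]:
    """Keep long, high-identity, non-self-overlapping repeat pairs.

    Thresholds are strict (> min_len, > min_identity); pairs whose two copies
    overlap each other (tandem/self-overlapping repeats) are discarded as
    unlikely drivers of large-scale rearrangement.
    """
    kept = []
    for rp in raw:
        if rp.length <= min_len or rp.identity <= min_identity:
            continue
        if _linear_overlap(rp.copy1, rp.copy2):
            continue
        kept.append(rp)
    return kept


def _circular_interval_gap(
    a: tuple[int, int], b: tuple[int, int], length: int
) -> int:
    """Minimum circular gap in bp between two intervals (0 when overlapping).

    The gap is the number of bases strictly between the two intervals along
    the shorter arc. Intervals are 1-based inclusive; ``a`` may wrap
    (start > end), ``b`` is linear.
    """
    a_parts = [a] if a[0] <= a[1] else [(a[0], length), (1, a[1])]
    best = length
    for ap in a_parts:
        if _linear_overlap(ap, b):
            return 0
        gap_cw = (b[0] - ap[1]) % length - 1
        gap_ccw = (ap[0] - b[1]) % length - 1
        best = min(best, gap_cw, gap_ccw)
    return best


def repeat_distance_class(
    gene: GeneAnnotation,
    repeats: list[RepeatPair],
    chromosome_length: int,
) -> tuple[str, int]:
    """Classify a gene as near/far from the closest repeat copy.

    Distance is the minimum circular gap between the gene interval and any
    repeat copy; *far* means distance > length/1000. With no repeats on the
    chromosome the gene is reported far at the maximal possible distance
    (length/2), logged.
    """
    threshold = chromosome_length / 1000
    gene_iv = (gene.start, gene.end)
    if not repeats:
        logger.warning("no repeats on chromosome; distances capped at length/2")
        return "far", chromosome_length // 2
    dist = min(
        _circular_interval_gap(gene_iv, copy, chromosome_length)
        for rp in repeats
        for copy in (rp.copy1, rp.copy2)
    )
    return ("far" if dist > threshold else "near"), dist
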