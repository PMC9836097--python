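"""Codon counting and relative codon usage between gene groups.

Genes found in GC-skew peak regions tend to prefer codons with an excess of
G over C (positive codon GC skew). This module counts codons on the coding
strand of gene sets, computes the relative usage of each codon between a
"peak" group and a background group, and correlates usage with simple codon
covariates (GC count, GC skew, G count, C count).

Two relative-usage formulas are supported, both in use in the field:

* ``difference_ratio`` (default): (f_peak - f_background)/f_background
* ``ratio``: f_peak/f_background

where f are within-group codon frequencies per genome, so genome size does
not dominate multi-genome medians. The genetic code is the bacterial table
11 throughout.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .genome_io import GenomeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CODONS",
    "CodonProfile",
    "codon_counts",
    "relative_codon_usage",
    "median_relative_usage",
    "codon_gc_stats",
    "matched_codon_table",
    "usage_correlations",
]

CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=3)
)

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS: frozenset[str] = frozenset(_TABLE11.stop_codons)


def amino_acid(codon: str) -> str:
    """One-letter amino acid for a sense codon, '*' for a stop (table 11)."""
    if codon in STOP_CODONS:
        return "*"
    return _TABLE11.forward_table[codon]


@dataclass
class CodonProfile:
    """Summed codon counts over a gene set of one genome."""

    counts: pd.Series  # index = 64 codons
    group: str
    genome_id: str

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(CODONS).fillna(0).astype(int)
        if (self.counts < 0).any():
            raise ValueError("negative codon count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> pd.Series:
        """Counts normalised to frequencies within the profile."""
        tot = self.total
        if tot == 0:
            return self.counts.astype(float) * np.nan
        return self.counts / tot


def codon_counts(
    record: GenomeRecord, gene_ids: list[str], group: str = ""
) -> CodonProfile:
    """Count codons on the coding strand over a gene set.

    Genes whose sequence contains N are excluded; a trailing remainder when
    a gene length is not divisible by 3 is dropped with a warning.
    """
    if not gene_ids:
        raise ValueError("empty gene set")
    counts: dict[str, int] = {}
    for gid in gene_ids:
        seq = record.coding_sequence(record.gene(gid))
        if "N" in seq:
            logger.info("gene %s contains N; excluded from codon profile", gid)
            continue
        if len(seq) % 3:
            logger.warning(
                "gene %s length %d not divisible by 3; trailing bases dropped",
                gid,
                len(seq),
            )
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            counts[codon] = counts.get(codon, 0) + 1
    return CodonProfile(
        counts=pd.Series(counts, dtype=float),
        group=group,
        genome_id=record.chromosome.id,
    )


def relative_codon_usage(
    peak: CodonProfile,
    non_peak: CodonProfile,
    mode: str = "difference_ratio",
) -> pd.Series:
    """Per-codon relative usage of ``peak`` against ``non_peak``.

    Frequencies are computed within each group first. Codons with zero
    background frequency are NaN. Against itself, ``difference_ratio`` is
    identically 0 and ``ratio`` identically 1.
    """
    if mode not in ("difference_ratio", "ratio"):
        raise ValueError(f"unknown mode {mode!r}")
    fp = peak.frequencies()
    fb = non_peak.frequencies()
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "difference_ratio":
            out = (fp - fb) / fb
        else:
            out = fp / fb
    out[fb == 0] = np.nan
    out.name = mode
    return out


def median_relative_usage(
    pairs: list[tuple[CodonProfile, CodonProfile]],
    mode: str = "difference_ratio",
) -> pd.Series:
    """Median across genomes of the per-genome relative codon usage.

    ``pairs`` holds one (peak, background) profile pair per genome; the
    median is taken codon-wise, ignoring NaNs.
    """
    if not pairs:
        raise ValueError("no profile pairs")
    per_genome = pd.DataFrame(
        {i: relative_codon_usage(p, b, mode=mode) for i, (p, b) in enumerate(pairs)}
    )
    med = per_genome.median(axis=1, skipna=True)
    med.name = f"median_{mode}"
    return med


def codon_gc_stats(codon: str) -> dict:
    """GC count and GC skew of a single codon.

    gc_skew = (#G - #C)/(#G + #C), NaN when the codon has no G or C (those
    codons are excluded from skew-based comparisons downstream).
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    g, c = codon.count("G"), codon.count("C")
    return {
        "codon": codon,
        "amino_acid": amino_acid(codon),
        "gc_count": g + c,
        "g_count": g,
        "c_count": c,
        "gc_skew": (g - c) / (g + c) if g + c else float("nan"),
    }


def codon_stats_table() -> pd.DataFrame:
    """Stats for all 64 codons, indexed by codon."""
    return pd.DataFrame([codon_gc_stats(c) for c in CODONS]).set_index("codon")


def matched_codon_table() -> pd.DataFrame:
    """Groups of sense codons sharing (amino acid, GC count), GC count > 0.

    Only groups of at least two codons are retained; within a group the
    codons differ in GC skew at identical GC content, enabling the
    G-versus-C preference comparison.
    """
    table = codon_stats_table()
    sense = table[table["amino_acid"] != "*"]
    sense = sense[sense["gc_count"] > 0]
    grouped = sense.groupby(["amino_acid", "gc_count"])
    keep = grouped.filter(lambda g: len(g) >= 2)
    return keep.sort_values(["amino_acid", "gc_count", "codon"])


def usage_correlations(
    usage: pd.Series, covariate: str = "gc_skew"
) -> tuple[float, float]:
    """Spearman correlation of per-codon usage with a codon covariate.

    ``covariate`` is one of gc_count, gc_skew, g_count, c_count. Stop codons
    are always excluded; codons with undefined usage or covariate are
    dropped. Returns (rho, p).
    """
    table = codon_stats_table()
    if covariate not in ("gc_count", "gc_skew", "g_count", "c_count"):
        raise ValueError(f"unknown covariate {covariate!r}")
    df = pd.DataFrame({"usage": usage, "cov": table[covariate]})
    df = df[table["amino_acid"] != "*"].dropna()
    if len(df) < 4:
        raise ValueError("need at least 4 codons with defined values")
    if df["cov"].nunique() == 1:
        raise ValueError("constant covariate")
    rho, p = stats.spearmanr(df["usage"], df["cov"])
    return float(rho), float(p)
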