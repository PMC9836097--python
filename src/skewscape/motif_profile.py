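"""IUPAC motif scanning and positional density profiles.

The CcrM methyltransferase of the Alphaproteobacteria recognises GANTC; the
chromosomal density of this motif proxies the methylation-based regulatory
potential of a region. Profiles are computed on chromosomes anchored at
*ori* or at a marker gene (rotate first with :mod:`skewscape.genome_io`),
as counts in 100 equal bins and as a cumulative curve over the chromosome
normalised to 1000 points.

GANTC is self-reverse-complementary as a pattern, so a single-strand scan
finds the same number of sites as a double-strand scan; non-palindromic
motifs are scanned on both strands with footprints reported in reference
coordinates. Matches may overlap and may wrap the origin; N in the sequence
never matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from ._dna import revcomp

__all__ = [
    "MotifProfile",
    "find_motif_sites",
    "control_motifs",
    "binned_profile",
    "cumulative_profile",
    "profile_motif",
    "is_palindromic_pattern",
]


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for code in motif.upper():
        if code not in ambiguous_dna_values:
            raise ValueError(f"invalid IUPAC code {code!r} in motif {motif!r}")
        charset = ambiguous_dna_values[code]  # expands over ACGT only
        parts.append(charset if len(charset) == 1 else f"[{charset}]")
    # lookahead so overlapping matches are all reported
    return re.compile("(?=" + "".join(parts) + ")")


def _revcomp_motif(motif: str) -> str:
    comp = {
        "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
        "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
        "N": "N",
    }
    return "".join(comp[c] for c in motif.upper()[::-1])


def is_palindromic_pattern(motif: str) -> bool:
    """True when the motif equals its own reverse complement as a pattern."""
    return motif.upper() == _revcomp_motif(motif)


def find_motif_sites(chromosome, motif: str = "GANTC") -> list[int]:
    """All match start positions (1-based, reference strand) on the circle.

    Palindromic patterns (like GANTC) are scanned on the forward strand
    only; other motifs are scanned on both strands with each match reported
    as the start of its footprint on the reference strand, deduplicated.
    Matches wrapping the origin are included.
    """
    seq = chromosome.sequence.upper()
    n = len(seq)
    k = len(motif)
    pat = _iupac_regex(motif)
    if k > n:
        return []
    extended = seq + seq[: k - 1]  # circular wrap

    sites = set()
    for m in pat.finditer(extended):
        if m.start() < n:
            sites.add(m.start() + 1)
    if not is_palindromic_pattern(motif):
        pat_rc = _iupac_regex(_revcomp_motif(motif))
        for m in pat_rc.finditer(extended):
            if m.start() < n:
                sites.add(m.start() + 1)
    return sorted(sites)


def control_motifs(motif: str) -> list[str]:
    """Base-composition-matched control patterns for a supported motif.

    For GANTC these are the two rotations CGANT and CTGAN, which preserve
    the letter multiset; other motifs require user-supplied controls.
    """
    if motif.upper() != "GANTC":
        raise ValueError(
            f"no built-in controls for {motif!r}; supply control motifs explicitly"
        )
    return ["CGANT", "CTGAN"]


def binned_profile(
    sites: list[int], chromosome_length: int, n_bins: int = 100
) -> np.ndarray:
    """Site counts in equal-width bins over the chromosome."""
    counts = np.zeros(n_bins, dtype=int)
    for pos in sites:
        if not 1 <= pos <= chromosome_length:
            raise ValueError(f"site {pos} outside [1, {chromosome_length}]")
        counts[int((pos - 1) * n_bins / chromosome_length)] += 1
    return counts


def cumulative_profile(
    sites: list[int],
    chromosome_length: int,
    n_points: int = 1000,
) -> np.ndarray:
    """Cumulative site count at each of ``n_points`` normalised positions.

    Element k (0-based) counts sites with position <= (k+1) * L/n_points;
    the final element equals the total number of sites. The chromosome must
    already be rotated to the desired anchor (ori or a marker gene).
    """
    arr = np.asarray(sorted(sites), dtype=float)
    edges = (np.arange(1, n_points + 1) * chromosome_length) / n_points
    return np.searchsorted(arr, edges, side="right")


@dataclass
class MotifProfile:
    """Sites plus binned and cumulative positional profiles for one motif."""

    motif: str
    chromosome_id: str
    sites: list[int]
    bin_counts: np.ndarray
    cumulative: np.ndarray
    anchor: str = "ori"

    def __post_init__(self) -> None:
        if int(self.bin_counts.sum()) != len(self.sites):
            raise ValueError("bin counts do not sum to the number of sites")
        if len(self.sites) and int(self.cumulative[-1]) != len(self.sites):
            raise ValueError("cumulative profile must end at the site count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": np.arange(len(self.bin_counts)), "count": self.bin_counts}
        ).assign(motif=self.motif, chromosome=self.chromosome_id)


def profile_motif(
    chromosome,
    motif: str = "GANTC",
    n_bins: int = 100,
    n_points: int = 1000,
    anchor: str = "ori",
) -> MotifProfile:
    """Scan a motif and build both positional profiles in one call."""
    sites = find_motif_sites(chromosome, motif)
    return MotifProfile(
        motif=motif,
        chromosome_id=chromosome.id,
        sites=sites,
        bin_counts=binned_profile(sites, chromosome.length, n_bins),
        cumulative=cumulative_profile(sites, chromosome.length, n_points),
        anchor=anchor,
    )
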