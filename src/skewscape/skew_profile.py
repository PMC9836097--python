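"""GC-skew and GC-content tracks, order-averaged profiles and peak calling.

The GC skew of a window is (G - C)/(G + C); its sign typically tracks the
direction of replication, positive on the right replichore and negative on
the left. Regions of locally extreme skew ("peaks") are called with a sliding
empirical quantile: a windowed track value is flagged when it falls strictly
in the upper (or lower) q tail of the values inside a large local window
centred on it (defaults: q = 0.03, local window 150 kb, track window 10 kb).

Undefined skew (windows with G+C = 0) is represented as NaN, never as 0, and
is excluded from every quantile pool and every mean.

Per-gene skew is computed on the reference (+) strand regardless of the
gene's coding strand: replichore typicality (see
:mod:`skewscape.strand_architecture`) is a property of the chromosomal
location, not of gene orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dna import position_in_interval, seq_to_array
from .genome_io import GenomeRecord, reorient_to_position

logger = logging.getLogger(__name__)

__all__ = [
    "SkewTrack",
    "PeakAnnotation",
    "gc_skew",
    "gc_content",
    "skew_track",
    "binned_skew",
    "mean_normalized_track",
    "detect_skew_peaks",
    "relative_skew",
    "per_gene_skew",
    "assign_genes_to_peaks",
]

_G, _C = ord("G"), ord("C")
_ACGT = np.array([ord(b) for b in "ACGT"], dtype=np.uint8)


def gc_skew(segment: str) -> float:
    """(G - C)/(G + C) of a sequence; NaN when G + C = 0. N is ignored."""
    if not segment:
        raise ValueError("empty segment")
    arr = seq_to_array(segment.upper())
    g = int((arr == _G).sum())
    c = int((arr == _C).sum())
    if g + c == 0:
        return float("nan")
    return (g - c) / (g + c)


def gc_content(segment: str) -> float:
    """(G + C) over the number of A/C/G/T bases (N excluded from both)."""
    if not segment:
        raise ValueError("empty segment")
    arr = seq_to_array(segment.upper())
    g = int((arr == _G).sum())
    c = int((arr == _C).sum())
    n_valid = int(np.isin(arr, _ACGT).sum())
    if n_valid == 0:
        return float("nan")
    return (g + c) / n_valid


@dataclass
class SkewTrack:
    """Windowed GC skew over a circular chromosome.

    ``positions`` are window-centre coordinates (1-based); ``values`` the skew
    per window placement (NaN where G+C = 0).
    """

    chromosome_id: str
    positions: np.ndarray
    values: np.ndarray
    window: int
    step: int
    length: int = 0  # chromosome length in bp (0 = infer as step * n_values)
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length == 0:
            self.length = int(self.step) * len(np.asarray(self.values))
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 or finite.max() > 1):
            raise ValueError("skew values must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome_id,
                "position": self.positions,
                "gc_skew": self.values,
            }
        )


@dataclass
class PeakAnnotation:
    """High/low GC-skew intervals called on a track.

    ``intervals`` is a list of ``(start, end, side)`` with side ``'high'`` or
    ``'low'``; 1-based inclusive, possibly wrapping (start > end).
    """

    chromosome_id: str
    intervals: list[tuple[int, int, str]] = field(default_factory=list)
    quantile: float = 0.03
    local_window: int = 150_000

    def side(self, side: str) -> list[tuple[int, int]]:
        return [(s, e) for s, e, sd in self.intervals if sd == side]

    def contains(self, pos: int) -> str | None:
        for s, e, sd in self.intervals:
            if position_in_interval(pos, s, e):
                return sd
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intervals, columns=["start", "end", "side"]
        ).assign(chromosome=self.chromosome_id)


def _window_gc_counts(seq: str, starts: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """G and C counts for circular windows starting at ``starts`` (1-based)."""
    n = len(seq)
    arr = seq_to_array(seq)
    # pad with the first window-1 bases so circular windows are contiguous
    padded = np.concatenate([arr, arr[: window - 1]])
    cg = np.concatenate([[0], np.cumsum(padded == _G)])
    cc = np.concatenate([[0], np.cumsum(padded == _C)])
    s0 = starts - 1
    return cg[s0 + window] - cg[s0], cc[s0 + window] - cc[s0]


def skew_track(
    chromosome, window: int = 10_000, step: int = 1_000
) -> SkewTrack:
    """Sliding-window GC skew of a circular chromosome.

    Window placements start at 1, 1+step, ... and wrap the origin; each value
    is anchored at the centre of its window.
    """
    seq = chromosome.sequence
    n = len(seq)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds chromosome length {n}")
    if step < 1:
        raise ValueError("step must be >= 1")
    starts = np.arange(1, n + 1, step, dtype=np.int64)
    g, c = _window_gc_counts(seq, starts, window)
    denom = (g + c).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, (g - c) / denom, np.nan)
    centers = (starts - 1 + window // 2) % n + 1
    return SkewTrack(
        chromosome_id=chromosome.id,
        positions=centers,
        values=values,
        window=window,
        step=step,
        length=n,
    )


def binned_skew(chromosome, n_bins: int) -> np.ndarray:
    """GC skew in ``n_bins`` equal non-overlapping bins from coordinate 1."""
    seq = chromosome.sequence
    n = len(seq)
    arr = seq_to_array(seq)
    edges = np.floor(np.arange(n_bins + 1) * n / n_bins).astype(np.int64)
    cg = np.concatenate([[0], np.cumsum(arr == _G)])
    cc = np.concatenate([[0], np.cumsum(arr == _C)])
    g = cg[edges[1:]] - cg[edges[:-1]]
    c = cc[edges[1:]] - cc[edges[:-1]]
    denom = (g + c).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (g - c) / denom, np.nan)


def mean_normalized_track(
    genomes: list[GenomeRecord], n_bins: int = 1000
) -> np.ndarray:
    """Mean ori-anchored GC skew profile across genomes.

    Each chromosome is rotated to its *ori*, binned into ``n_bins``
    non-overlapping windows of 1/n_bins of its length (0.1 % by default),
    then profiles are averaged element-wise; undefined bins are excluded from
    the mean.
    """
    if not genomes:
        raise ValueError("empty genome list")
    tracks = []
    for rec in genomes:
        if rec.chromosome.ori != 1:
            rec = reorient_to_position(rec, rec.chromosome.ori)
        tracks.append(binned_skew(rec.chromosome, n_bins))
    stacked = np.vstack(tracks)
    with np.errstate(invalid="ignore"):
        return np.nanmean(stacked, axis=0)


def _type1_quantile_index(q: float, m: int) -> int:
    """0-based index of the type-1 (order statistic) empirical quantile."""
    return max(0, min(m - 1, math.ceil(q * m) - 1))


def detect_skew_peaks(
    track: SkewTrack, quantile: float = 0.03, local_window: int = 150_000
) -> PeakAnnotation:
    """Call high/low GC-skew positions with sliding local quantiles.

    A track position is flagged ``high`` (``low``) when its value is strictly
    greater (smaller) than the empirical 1-q (q) order-statistic quantile of
    the track values within the ``local_window`` bp window centred on it.
    Adjacent flagged positions are merged into intervals (half a step of slack
    on each side). The call is symmetric in the two replichores and commutes
    with chromosome rotation.
    """
    if not 0 < quantile < 0.5:
        raise ValueError("quantile must be in (0, 0.5)")
    if local_window < track.window:
        raise ValueError("local_window must be >= track window")
    vals = track.values
    m = vals.size
    chrom_len = track.length

    h = int(local_window // (2 * track.step))
    if 2 * h + 1 >= m:
        logger.warning(
            "local window %d bp covers the whole chromosome; using global quantiles",
            local_window,
        )
        pool = np.tile(vals, (m, 1))
    else:
        padded = np.concatenate([vals[-h:], vals, vals[:h]])
        pool = np.lib.stride_tricks.sliding_window_view(padded, 2 * h + 1)

    pool_sorted = np.sort(pool, axis=1)  # NaNs sort last
    n_valid = np.sum(np.isfinite(pool_sorted), axis=1)
    hi_thr = np.full(m, np.nan)
    lo_thr = np.full(m, np.nan)
    ok = n_valid > 0
    hi_idx = np.array([_type1_quantile_index(1 - quantile, k) if k else 0 for k in n_valid])
    lo_idx = np.array([_type1_quantile_index(quantile, k) if k else 0 for k in n_valid])
    rows = np.arange(m)
    hi_thr[ok] = pool_sorted[rows[ok], hi_idx[ok]]
    lo_thr[ok] = pool_sorted[rows[ok], lo_idx[ok]]

    finite = np.isfinite(vals)
    flag_hi = finite & (vals > hi_thr)
    flag_lo = finite & (vals < lo_thr)

    intervals = []
    for flags, side in ((flag_hi, "high"), (flag_lo, "low")):
        intervals.extend(_merge_flagged(track, flags, side, chrom_len))
    return PeakAnnotation(
        chromosome_id=track.chromosome_id,
        intervals=intervals,
        quantile=quantile,
        local_window=local_window,
    )


def _merge_flagged(
    track: SkewTrack, flags: np.ndarray, side: str, chrom_len: int
) -> list[tuple[int, int, str]]:
    """Merge circular runs of flagged track positions into bp intervals."""
    if not flags.any():
        return []
    m = flags.size
    half_lo = track.step // 2
    half_hi = (track.step - 1) // 2
    if flags.all():
        return [(1, chrom_len, side)]
    idx = np.flatnonzero(flags)
    runs = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
        else:
            runs.append((run_start, prev))
            run_start = prev = i
    runs.append((run_start, prev))
    # circular join of first and last run
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == m - 1:
        first = runs.pop(0)
        last = runs.pop()
        runs.append((last[0], first[1]))  # wrapping run
    out = []
    for a, b in runs:
        start = (int(track.positions[a]) - 1 - half_lo) % chrom_len + 1
        end = (int(track.positions[b]) - 1 + half_hi) % chrom_len + 1
        out.append((start, end, side))
    return out


def relative_skew(sample: float, control: float) -> float:
    """(sample - control)/control; NaN (with a warning) when control is 0."""
    if control == 0 or not np.isfinite(control):
        logger.warning("relative skew undefined: control skew is %s", control)
        return float("nan")
    return (sample - control) / control


def per_gene_skew(record: GenomeRecord) -> pd.DataFrame:
    """GC skew and GC content of every gene's chromosomal interval.

    Values are computed on the reference (+) strand for both orientations so
    they are comparable with the replichore-level skew sign.
    """
    rows = []
    for g in record.genes:
        seq = record.region_sequence(g)
        if not seq:
            raise ValueError(f"zero-length gene {g.gene_id}")
        rows.append(
            {
                "gene_id": g.gene_id,
                "gc_skew": gc_skew(seq),
                "gc_content": gc_content(seq),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "gc_skew", "gc_content"]).set_index(
        "gene_id"
    )


def assign_genes_to_peaks(
    record: GenomeRecord, peaks: PeakAnnotation
) -> pd.DataFrame:
    """Label each gene ``peak``/``non_peak`` by circular midpoint membership."""
    if peaks.chromosome_id != record.chromosome.id:
        raise ValueError(
            f"peaks computed for {peaks.chromosome_id!r}, record is "
            f"{record.chromosome.id!r}"
        )
    n = record.chromosome.length
    rows = []
    for g in record.genes:
        side = peaks.contains(g.midpoint(n))
        rows.append(
            {
                "gene_id": g.gene_id,
                "label": "peak" if side else "non_peak",
                "side": side or "",
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "label", "side"]).set_index("gene_id")
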