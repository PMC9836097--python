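"""Synthetic circular genomes with planted, fully known architecture.

Every analysis stage in this package is exercised against data whose ground
truth is known by construction: circular chromosomes with
replichore-dependent GC skew (P(G) - P(C) = +/- the skew amplitude on the
right/left replichore), optional high-skew segments, non-overlapping genes
whose codons are drawn from region-appropriate multinomials (with a
configurable preference for G-skewed codons inside high-skew segments), a
contiguous GTA-like gene cluster, duplicated repeat pairs with controlled
identity, and a GANTC motif density gradient anchored at *ori*.

The motif gradient is realised as a density decaying linearly with the
clockwise distance from *ori* (ratio ``motif_gradient`` between the density
at *ori* and at the far end of the linearised circle). Chance background
occurrences of the motif are first scrubbed from the sequence (one base of
each spontaneous match is mutated) so that the planted gradient is the only
GANTC signal; this is a deliberate idealisation, see the methods note.

All randomness flows from one seed; the same spec and seed reproduce the
emitted files byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._dna import position_in_interval, revcomp
from .codon_usage import CODONS, STOP_CODONS, codon_gc_stats
from .genome_io import CircularChromosome, GeneAnnotation, GenomeRecord, write_genome
from .orthology_core import OrthologueMatrix

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_genome",
    "generate_ortho_matrix",
    "generate_order",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    """Planted parameters of one synthetic chromosome.

    Defaults emulate a mid-sized alphaproteobacterial replicon: 60 % GC,
    skew amplitude 0.1 (the windowed skew deviates well beyond the +/-0.03
    band typical of strongly skewed orders), genes of ~300 codons, a mild
    leading-strand excess, and a 1.5x preference for G-skewed codons inside
    planted high-skew segments.
    """

    length: int = 500_000
    ori: int = 1
    skew_amplitude: float = 0.1
    gc_content: float = 0.60
    peak_segments: list[tuple[int, int, float]] = field(default_factory=list)
    n_genes: int = 0
    gene_length_codons: tuple[float, float] = (300.0, 60.0)
    leading_fraction: float = 0.55
    cluster: tuple[int, int, str] | None = None  # (start position, n genes, strand)
    cluster_gene_codons: int = 300
    peak_codon_bias: float = 1.5
    repeats: list[tuple[int, float, tuple[int, int]]] = field(default_factory=list)
    motif_gradient: float | None = None  # ori:far-end density ratio for GANTC
    motif_density: float = 1.0  # mean planted sites per kb
    chromosome_id: str = "synth"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.skew_amplitude < 1:
            raise ValueError("skew_amplitude must be in (0, 1)")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        for s, e, _ in self.peak_segments:
            if not (1 <= s <= self.length and 1 <= e <= self.length):
                raise ValueError(f"peak segment ({s}, {e}) outside [1, {self.length}]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated chromosome."""

    genes: pd.DataFrame  # gene_id, start, end, strand, replichore, strand_class, in_peak, in_cluster
    peak_segments: list[tuple[int, int, float]]
    repeats: list[dict]
    motif_sites: list[int]
    motif_gradient: float | None
    spec: SyntheticSpec


def _replichore_mask(length: int, ori: int, ter: int) -> np.ndarray:
    """Boolean array (True = right replichore) over 1-based positions."""
    pos = np.arange(1, length + 1)
    if ori < ter:
        return (pos >= ori) & (pos < ter)
    return (pos >= ori) | (pos < ter)


def _effective_skew(spec: SyntheticSpec) -> np.ndarray:
    ter = (spec.ori - 1 + spec.length // 2) % spec.length + 1
    amp = np.where(
        _replichore_mask(spec.length, spec.ori, ter),
        spec.skew_amplitude,
        -spec.skew_amplitude,
    ).astype(float)
    for s, e, extra in spec.peak_segments:
        if s <= e:
            amp[s - 1 : e] += extra
        else:
            amp[s - 1 :] += extra
            amp[:e] += extra
    return np.clip(amp, -0.999, 0.999)


def _sample_background(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-base draw: P(G)-P(C) equals the local effective skew amplitude."""
    amp = _effective_skew(spec)
    gc = spec.gc_content
    p_a = np.full(spec.length, (1 - gc) / 2)
    p_c = gc / 2 * (1 - amp)
    p_g = gc / 2 * (1 + amp)
    u = rng.random(spec.length)
    t1 = p_a
    t2 = p_a + p_c
    t3 = p_a + p_c + p_g
    idx = (u > t1).astype(np.int8) + (u > t2) + (u > t3)  # 0=A 1=C 2=G 3=T
    return np.array(list("ACGT"))[idx]


def _codon_weights(
    p_a: float, p_c: float, p_g: float, p_t: float, g_bias: float
) -> np.ndarray:
    """Codon multinomial from per-base probabilities; no stop codons.

    ``g_bias`` multiplies the weight of codons with positive GC skew
    (more G than C) — the planted peak-region codon preference.
    """
    p = {"A": p_a, "C": p_c, "G": p_g, "T": p_t}
    w = np.array(
        [0.0 if c in STOP_CODONS else p[c[0]] * p[c[1]] * p[c[2]] for c in CODONS]
    )
    if g_bias != 1.0:
        for i, c in enumerate(CODONS):
            skew = codon_gc_stats(c)["gc_skew"]
            if np.isfinite(skew) and skew > 0:
                w[i] *= g_bias
    return w / w.sum()


def _write_circular(arr: np.ndarray, start: int, text: str) -> None:
    """Write ``text`` into the base array at 1-based ``start``, wrapping."""
    n = len(arr)
    s0 = start - 1
    k = len(text)
    chars = np.array(list(text))
    if s0 + k <= n:
        arr[s0 : s0 + k] = chars
    else:
        head = n - s0
        arr[s0:] = chars[:head]
        arr[: k - head] = chars[head:]


def _plan_gene_layout(
    spec: SyntheticSpec, rng: np.random.Generator
) -> list[dict]:
    """Non-overlapping gene intervals: the cluster block plus free genes."""
    length = spec.length
    genes: list[dict] = []
    cluster_span = 0
    if spec.cluster is not None:
        cpos, c_n, c_strand = spec.cluster
        span_each = spec.cluster_gene_codons * 3
        pos = cpos
        for i in range(c_n):
            end = (pos - 1 + span_each - 1) % length + 1
            genes.append(
                {
                    "gene_id": f"{spec.chromosome_id}_gta{i:02d}",
                    "start": pos,
                    "end": end,
                    "strand": c_strand,
                    "in_cluster": True,
                    "n_codons": spec.cluster_gene_codons,
                }
            )
            pos = end % length + 1
        cluster_span = c_n * span_each

    n = spec.n_genes
    if n:
        mean_c, sd_c = spec.gene_length_codons
        n_codons = np.clip(
            np.round(rng.normal(mean_c, sd_c, size=n)).astype(int), 50, None
        )
        spans = n_codons * 3
        free = length - cluster_span
        if spans.sum() > 0.85 * free:
            raise ValueError(
                f"infeasible packing: {spans.sum()} gene bp into {free} free bp"
            )
        total_gap = free - int(spans.sum())
        gaps = rng.multinomial(total_gap, [1.0 / (n + 1)] * (n + 1))
        if spec.cluster is not None:
            cpos, c_n, _ = spec.cluster
            arc_start = (cpos - 1 + cluster_span) % length + 1
        else:
            arc_start = 1
        pos = arc_start
        for i in range(n):
            pos = (pos - 1 + int(gaps[i])) % length + 1
            end = (pos - 1 + int(spans[i]) - 1) % length + 1
            genes.append(
                {
                    "gene_id": f"{spec.chromosome_id}_g{i:04d}",
                    "start": pos,
                    "end": end,
                    "strand": None,  # assigned from leading_fraction below
                    "in_cluster": False,
                    "n_codons": int(n_codons[i]),
                }
            )
            pos = end % length + 1
    return genes


_GANTC_RE = re.compile(r"(?=GA[ACGT]TC)")


def _scrub_motif(arr: np.ndarray, rng: np.random.Generator) -> None:
    """Mutate one base of every spontaneous GANTC match until none remain."""
    n = len(arr)
    for _ in range(20):
        seq = "".join(arr) + "".join(arr[:4])
        hits = [m.start() for m in _GANTC_RE.finditer(seq) if m.start() < n]
        if not hits:
            return
        for h in hits:
            # replace the T (offset 3) with a non-T base
            arr[(h + 3) % n] = rng.choice(np.array(list("ACG")))
    raise RuntimeError("motif scrubbing did not converge")


def _sample_gradient_positions(
    n_sites: int, length: int, ratio: float, rng: np.random.Generator
) -> list[int]:
    """Positions with density linearly decaying clockwise from *ori*."""
    u = rng.random(n_sites)
    if ratio == 1.0:
        x = u
    else:
        r = ratio
        a = (r - 1) / 2.0
        norm = r - a
        x = (r - np.sqrt(r * r - 4 * a * u * norm)) / (2 * a)
    pos = np.unique(np.clip((x * length).astype(int) + 1, 1, length))
    # enforce non-overlap of the 5-mer footprints
    kept, last = [], -10
    for p in sorted(pos):
        if p - last >= 5:
            kept.append(int(p))
            last = p
    return kept


def generate_genome(spec: SyntheticSpec) -> tuple[GenomeRecord, SyntheticTruth]:
    """Generate a chromosome + annotations with planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    length = spec.length
    ter = (spec.ori - 1 + length // 2) % length + 1
    arr = _sample_background(spec, rng)
    amp = _effective_skew(spec)
    right = _replichore_mask(length, spec.ori, ter)

    # --- genes
    layout = _plan_gene_layout(spec, rng)
    gc = spec.gc_content
    annotations: list[GeneAnnotation] = []
    truth_rows = []
    for g in layout:
        mid = (g["start"] - 1 + (g["n_codons"] * 3 - 1) // 2) % length + 1
        on_right = bool(right[mid - 1])
        if g["strand"] is None:
            leading = rng.random() < spec.leading_fraction
            g["strand"] = ("+" if on_right else "-") if leading else ("-" if on_right else "+")
        strand_class = (
            "leading"
            if (on_right and g["strand"] == "+") or (not on_right and g["strand"] == "-")
            else "lagging"
        )
        in_peak = any(
            position_in_interval(mid, s, e) for s, e, _ in spec.peak_segments
        )
        local_amp = float(amp[mid - 1])
        # per-base probabilities on the coding strand of this gene
        p_g_ref = gc / 2 * (1 + local_amp)
        p_c_ref = gc / 2 * (1 - local_amp)
        p_at = (1 - gc) / 2
        if g["strand"] == "+":
            w = _codon_weights(p_at, p_c_ref, p_g_ref, p_at,
                               spec.peak_codon_bias if in_peak else 1.0)
        else:
            w = _codon_weights(p_at, p_g_ref, p_c_ref, p_at,
                               spec.peak_codon_bias if in_peak else 1.0)
        inner = rng.choice(len(CODONS), size=g["n_codons"] - 2, p=w)
        coding = "ATG" + "".join(CODONS[i] for i in inner) + "TGA"
        _write_circular(
            arr, g["start"], coding if g["strand"] == "+" else revcomp(coding)
        )
        annotations.append(
            GeneAnnotation(
                gene_id=g["gene_id"], start=g["start"], end=g["end"], strand=g["strand"]
            )
        )
        truth_rows.append(
            {
                "gene_id": g["gene_id"],
                "start": g["start"],
                "end": g["end"],
                "strand": g["strand"],
                "replichore": "right" if on_right else "left",
                "strand_class": strand_class,
                "in_peak": in_peak,
                "in_cluster": g["in_cluster"],
            }
        )

    # --- repeats: duplicate a source segment with point mutations
    repeat_truth = []
    for rep_len, identity, (pos1, pos2) in spec.repeats:
        src_idx = (np.arange(pos1 - 1, pos1 - 1 + rep_len)) % length
        copy = arr[src_idx].copy()
        n_mut = int(round((1 - identity) * rep_len))
        if n_mut:
            sites = rng.choice(rep_len, size=n_mut, replace=False)
            for s in sites:
                current = copy[s]
                copy[s] = rng.choice(_BASES[_BASES != current])
        _write_circular(arr, pos2, "".join(copy))
        repeat_truth.append(
            {
                "start1": pos1,
                "end1": (pos1 - 1 + rep_len - 1) % length + 1,
                "start2": pos2,
                "end2": (pos2 - 1 + rep_len - 1) % length + 1,
                "length": rep_len,
                "identity": identity,
            }
        )

    # --- motif gradient
    motif_sites: list[int] = []
    if spec.motif_gradient is not None:
        _scrub_motif(arr, rng)
        n_sites = int(round(spec.motif_density * length / 1000))
        positions = _sample_gradient_positions(
            n_sites, length, spec.motif_gradient, rng
        )
        for p in positions:
            _write_circular(arr, p, f"GA{rng.choice(_BASES)}TC")
        motif_sites = positions

    chrom = CircularChromosome(
        id=spec.chromosome_id, sequence="".join(arr), ori=spec.ori, ter=ter
    )
    record = GenomeRecord(
        chromosome=chrom,
        genes=annotations,
        provenance=f"synthetic (seed={spec.seed})",
    )
    truth = SyntheticTruth(
        genes=pd.DataFrame(
            truth_rows,
            columns=[
                "gene_id", "start", "end", "strand", "replichore",
                "strand_class", "in_peak", "in_cluster",
            ],
        ).set_index("gene_id"),
        peak_segments=list(spec.peak_segments),
        repeats=repeat_truth,
        motif_sites=motif_sites,
        motif_gradient=spec.motif_gradient,
        spec=spec,
    )
    return record, truth


def generate_ortho_matrix(
    n_genomes: int,
    n_core: int,
    n_accessory: int,
    presence_prob_accessory: float = 0.5,
    gta_family_ids: tuple[str, ...] = (),
    seed: int = 0,
) -> tuple[OrthologueMatrix, set[str]]:
    """Abstract presence matrix: core in every genome, accessory at random.

    Accessory presence vectors are redrawn in the rare event that one would
    reach the 90 % core-calling threshold, so the planted core/accessory
    dichotomy is unambiguous by construction. Returns the matrix and the
    planted core family set (which also contains any GTA families, present
    in all genomes).
    """
    if min(n_genomes, n_core, n_accessory) < 0 or n_genomes == 0:
        raise ValueError("counts must be non-negative, n_genomes >= 1")
    rng = np.random.default_rng(seed)
    genomes = [f"genome_{i:03d}" for i in range(n_genomes)]
    rows = {}
    core_set = set()
    for j in range(n_core):
        fam = f"core_{j:04d}"
        core_set.add(fam)
        rows[fam] = {g: (f"{g}|{fam}",) for g in genomes}
    for fam in gta_family_ids:
        core_set.add(fam)
        rows[fam] = {g: (f"{g}|{fam}",) for g in genomes}
    core_threshold = math.ceil(0.9 * n_genomes)
    for j in range(n_accessory):
        fam = f"acc_{j:04d}"
        present = rng.random(n_genomes) < presence_prob_accessory
        while present.sum() >= core_threshold:
            present = rng.random(n_genomes) < presence_prob_accessory
        rows[fam] = {
            g: (f"{g}|{fam}",) if present[i] else tuple()
            for i, g in enumerate(genomes)
        }
    membership = pd.DataFrame.from_dict(rows, orient="index", columns=genomes)
    labels = {f: ("gta" if f in gta_family_ids else "core" if f in core_set else "other")
              for f in membership.index}
    return OrthologueMatrix(membership=membership, labels=labels), core_set


def generate_order(
    n_genomes: int,
    template: SyntheticSpec,
    seed: int = 0,
    length_jitter: float = 0.05,
    core_fraction: float = 0.3,
    peak_core_ratio: float = 3.0,
) -> tuple[list[GenomeRecord], OrthologueMatrix, dict[str, SyntheticTruth], set[str]]:
    """A cohort emulating one taxonomic order.

    Genomes share a planted core family set and (when the template defines
    one) a GTA-like cluster; lengths are jittered per genome and planted
    intervals rescaled with them. Core families are allocated to gene slots
    so that the percentage of core genes in planted peak segments versus
    outside them matches ``peak_core_ratio``; every core family occurs
    exactly once per genome, so the core call recovers the planted set.

    Returns (records, matrix, truths by genome id, core family set). The
    core set includes any GTA cluster families: they are present in every
    genome by construction, exactly as the conserved cluster is in the
    orders this emulates.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    rng = np.random.default_rng(seed)
    n_core = int(round(core_fraction * template.n_genes))
    core_fams = [f"core_{j:04d}" for j in range(n_core)]
    n_gta = template.cluster[1] if template.cluster is not None else 0
    gta_fams = [f"gta_{j:02d}" for j in range(n_gta)]

    records: list[GenomeRecord] = []
    truths: dict[str, SyntheticTruth] = {}
    membership: dict[str, dict[str, tuple]] = {
        f: {} for f in core_fams + gta_fams
    }

    for i in range(n_genomes):
        scale = 1 + length_jitter * float(rng.uniform(-1, 1))
        length = int(template.length * scale)

        def _sc(p: int) -> int:
            return min(length, max(1, int(round(p * length / template.length))))

        spec = dataclasses.replace(
            template,
            length=length,
            peak_segments=[(_sc(s), _sc(e), x) for s, e, x in template.peak_segments],
            cluster=None
            if template.cluster is None
            else (_sc(template.cluster[0]), template.cluster[1], template.cluster[2]),
            chromosome_id=f"{template.chromosome_id}_{i:03d}",
            seed=int(rng.integers(2**31)),
        )
        rec, truth = generate_genome(spec)
        gid = rec.chromosome.id

        free = truth.genes[~truth.genes["in_cluster"]]
        peak_slots = list(free.index[free["in_peak"]])
        other_slots = list(free.index[~free["in_peak"]])
        K, M = len(peak_slots), len(other_slots)
        if n_core > K + M:
            raise ValueError("more core families than available gene slots")
        a = peak_core_ratio * n_core / (peak_core_ratio * K + M) if (K or M) else 0
        n_core_peak = int(round(a * K))
        n_core_peak = max(n_core - M, min(n_core_peak, min(K, n_core)))
        def _pick(slots: list[str], k: int) -> list[str]:
            return list(rng.choice(slots, size=k, replace=False)) if k else []

        chosen = _pick(peak_slots, n_core_peak) + _pick(
            other_slots, n_core - n_core_peak
        )
        order = rng.permutation(n_core)
        fam_of_gene: dict[str, str] = {}
        for slot, k in zip(chosen, order):
            fam_of_gene[slot] = core_fams[k]
        cluster_genes = list(truth.genes.index[truth.genes["in_cluster"]])
        for fam, gidx in zip(gta_fams, cluster_genes):
            fam_of_gene[gidx] = fam
        for slot in free.index:
            if slot not in fam_of_gene:
                fam = f"acc_{gid}_{slot}"
                membership.setdefault(fam, {})
                fam_of_gene[slot] = fam
        for gene_id, fam in fam_of_gene.items():
            membership[fam][gid] = (gene_id,)
        for gene in rec.genes:
            gene.family_id = fam_of_gene.get(gene.gene_id)
        truth.genes["family_id"] = [
            fam_of_gene.get(g) for g in truth.genes.index
        ]
        records.append(rec)
        truths[gid] = truth

    genome_ids = [r.chromosome.id for r in records]
    mem_df = pd.DataFrame.from_dict(membership, orient="index", columns=genome_ids)
    mem_df = mem_df.map(lambda c: c if isinstance(c, tuple) else tuple())
    labels = {
        f: ("gta" if f.startswith("gta_") else "core" if f in set(core_fams) else "other")
        for f in mem_df.index
    }
    matrix = OrthologueMatrix(membership=mem_df, labels=labels)
    return records, matrix, truths, set(core_fams) | set(gta_fams)


def write_dataset(
    records: list[GenomeRecord],
    matrix: OrthologueMatrix | None,
    truths: dict[str, SyntheticTruth],
    out_dir: str | Path,
) -> None:
    """Emit FASTA/GFF3 per genome, ori table, matrix TSV, repeat TSVs and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ori_rows = []
    for rec in records:
        gid = rec.chromosome.id
        write_genome(rec, out / f"{gid}.fasta", out / f"{gid}.gff3")
        ori_rows.append({"chromosome_id": gid, "ori_position": rec.chromosome.ori})
        truth = truths.get(gid)
        if truth and truth.repeats:
            pd.DataFrame(truth.repeats).to_csv(
                out / f"{gid}.repeats.tsv", sep="\t", index=False
            )
    pd.DataFrame(ori_rows).to_csv(out / "ori.tsv", sep="\t", index=False)
    if matrix is not None:
        matrix.write_tsv(out / "orthologues.tsv")
    meta = {}
    for gid, truth in truths.items():
        meta[gid] = {
            "seed": truth.spec.seed,
            "spec": {
                k: v
                for k, v in dataclasses.asdict(truth.spec).items()
                if not isinstance(v, pd.DataFrame)
            },
            "peak_segments": truth.peak_segments,
            "repeats": truth.repeats,
            "motif_gradient": truth.motif_gradient,
            "n_motif_sites": len(truth.motif_sites),
            "genes": truth.genes.reset_index().to_dict(orient="records"),
        }
    (out / "truth.json").write_text(json.dumps(meta, indent=1, default=str))
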