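# Methods

## Scope and model

`skewscape` analyses the architecture of closed circular bacterial
chromosomes. The underlying biological model is the standard replichore
picture: bidirectional replication from a single origin (*ori*) to a
terminus (*ter*) splits the circle into a right replichore (*ori*→*ter*
clockwise) and a left one. Mutational asymmetry between the continuously
and discontinuously replicated strands enriches the leading strand in G
over C, so the reference-strand GC skew, (G−C)/(G+C), is typically positive
on the right replichore and negative on the left. Deviations of a gene's
local skew from this pattern are read as evidence of past inversions or
translocations; regions of locally extreme skew ("peaks") are of interest
because conserved core genes — and the phage-derived gene transfer agent
(GTA) clusters of the Alphaproteobacteria — accumulate in them.

## Coordinates and rotation

All coordinates are 1-based inclusive (GFF3); circularity is expressed by
`start > end` for intervals wrapping the linearisation point, and all
arithmetic is modulo the chromosome length. Rotation (`reorient_to_position`)
is a group action on the circle: it preserves length, base multiset, gene
spans, strands and all pairwise circular distances, and composing two
rotations adds their offsets. Gene-anchored rotation uses the gene's
5′ end on its coding strand (start for `+`, end for `−`); the choice of
anchor only shifts profiles by a constant offset. *ori* is always supplied
externally (tabular input or argument); when absent it defaults to 1 with a
warning. *ter* defaults to the antipode of *ori*; a cumulative-skew
extremum estimate is provided for skew-asymmetric chromosomes (on clean
synthetic genomes both agree to within a few percent of the length).

## Skew tracks and peak calling

Tracks are computed in sliding windows (default 10 kb) with a configurable
step (default 1 kb, i.e. 10 % of the window; the window value is anchored
at its centre and windows wrap the origin). Windows with G+C = 0 carry NaN,
never 0, and are excluded from every mean and quantile pool. Cohort
profiles use non-overlapping bins of 0.1 % of each chromosome's length
(1000 bins clockwise from *ori*) averaged element-wise across genomes.

Peak calling flags a track position as *high* (*low*) when its value is
strictly greater (smaller) than the empirical 1−q (q) quantile — type-1
order statistic, no interpolation — of the track values inside the
`local_window` (default 150 kb) centred on it, with defaults q = 0.03.
Strict inequality makes constant regions peak-free; the call is symmetric
under replichore reversal and commutes with rotation. Adjacent flagged
positions are merged into intervals with half a step of slack per side.
Genes are assigned to peaks by circular midpoint membership.

A structural property of this detector worth knowing: within any local
window at most ⌊q·m⌋ of its m values can exceed the upper threshold, so a
*plateau* of elevated skew longer than q × local_window (≈ 4.5 kb at the
defaults) can never be flagged in full — only its locally extreme positions
are. Narrow extrema (the realistic case, and the regime the property tests
exercise) are recovered essentially completely; very long uniform plateaus
are reported as scattered sub-intervals. Users who need full plateau
recovery should raise q or the local window accordingly.

## Architecture classification

A gene's replichore is decided by its circular midpoint (genes spanning
*ori*/*ter* are not split; a midpoint exactly on a boundary goes to the
right replichore with a log note). Leading/lagging follows from replichore
and annotation strand; typicality from replichore and the sign of the
gene's reference-strand skew. Per-gene skew is deliberately computed on the
reference strand for both orientations — typicality is a property of the
chromosomal location, not of the gene's coding strand — so a `−` gene in a
G-rich region is "positive skew" here. Genes with zero or undefined skew
form a third category excluded from typicality percentages. Group
differences in per-genome proportions are tested with the Kruskal–Wallis
rank test (scipy); the degenerate all-identical case is reported as H = 0,
p = 1 with a warning.

## Repeats

Repeat pairs (RepSeek-style tables) are filtered strictly: length > 800 bp
and identity > 0.90. Pairs whose two copies overlap each other are removed —
tandem/self-overlapping repeats are unlikely drivers of large-scale
rearrangement. Gene-to-repeat distance is the number of bases strictly
between the gene interval and the nearest repeat copy along the shorter
arc (0 when overlapping); *far* means more than 1/1000 of the genome
length. With no repeats at all, genes are reported far at the maximal
distance L/2 (logged).

## Codon usage

Codons are counted on the coding strand; genes containing N are skipped and
non-multiple-of-3 remainders dropped with a warning. Per-genome usage is a
within-group *frequency* (counts normalised per group) so genome size does
not dominate cohort medians; this resolves the ambiguity of whether group
means are over raw counts or frequencies in favour of frequencies. Two
relative-usage definitions coexist in practice and both are implemented:
`difference_ratio` (f_peak − f_bg)/f_bg (default) and `ratio` f_peak/f_bg;
the mode is recorded in output metadata. The genetic code is bacterial
table 11; stop codons are retained in counts but excluded from amino-acid
groupings and correlations. Matched-codon groups collect sense codons with
identical amino acid and GC count (> 0), the setting in which a G-over-C
preference is visible as a within-group ordering by codon GC skew.

## Orthology and enrichment

Proteinortho-dialect matrices are parsed with absence as `*` and
co-orthologues as comma lists; any non-empty cell counts as presence. Core
calling uses the ceiling rule: present in ≥ ⌈fraction × n⌉ genomes
(fraction 0.9), which reduces to the nearest-count rule for small cohorts.
Enrichment is the ratio of core percentages among peak versus non-peak
genes; a family is "in peak" in a genome if any member gene there is
peak-labelled. The 16-bin localisation heatmap places each homologue's
midpoint m in bin ⌊16·m/L⌋ (capped at 15).

## Motif profiles

IUPAC motifs are scanned with overlapping matches allowed and wrap-around
matches included (their effect is negligible but the circular contract is
honoured). GANTC is self-reverse-complementary as a pattern, so a
single-strand scan suffices (asserted by test); non-palindromic motifs are
scanned on both strands and deduplicated by footprint start. Sequence N
never matches. Controls for GANTC are its composition-preserving rotations
CGANT and CTGAN. Binned profiles use equal-width bins over positions;
cumulative profiles report counts at 1000 normalised positions.

## The synthetic generator

`generate_genome` draws background bases per position with
P(G) − P(C) = ± the skew amplitude (sign by replichore; planted segments
add extra amplitude), so the expected window skew equals the planted value
exactly. Genes are packed without overlap (cluster block first, then free
genes with multinomial gaps), their ORFs sampled from codon multinomials
derived from the local strand-adjusted base probabilities, with no internal
stops, ATG/TGA termini, and a configurable multiplier (default 1.5×) on
G-skewed codons inside planted segments. Repeats are implanted as
duplicated segments with point mutations at rate 1 − identity.

The GANTC gradient is realised as a site density decaying linearly with
*clockwise distance from ori* (ratio `motif_gradient` between the density
at *ori* and at the far end of the linearised circle), a monotone
idealisation of ori-proximal motif enrichment chosen so that first- versus
last-decile bin counts measure the planted ratio directly. Before planting,
spontaneous GANTC matches in the background are scrubbed (one base of each
match mutated), so the planted sites are the only signal; real chromosomes
obviously carry abundant background sites, so motif tests validate the
profiling machinery, not a realistic site census. Analogously,
`generate_ortho_matrix` redraws the rare accessory presence vector that
would reach the core-calling threshold, keeping the planted core set
unambiguous.

Defaults emulate a mid-size alphaproteobacterial replicon: 60 % GC, skew
amplitude 0.1 (well beyond the ±0.03 deviation band that marks strongly
skewed genomes), genes of 300 ± 60 codons, a 55 % leading-strand fraction,
and a ~15-gene scale cluster option. All randomness flows from a single
seed; identical spec + seed reproduces files byte for byte.

What the generator does **not** emulate: phylogenetic correlation between
genomes, intergenic grammar (promoters, operons), amino-acid level
selection, variable gene density, multi-replicon genomes. Passing
recovery tests therefore demonstrates correctness of the measurement
machinery under the stated forward model, not performance on real NCBI
genomes.

## Problem sizes and numerics

Simulation-based tests use 2 Mb chromosomes for peak-recovery runs and
250–400 kb chromosomes for codon, enrichment and motif cohorts, with
5–100 seeds per question — sizes at which planted effects are measured
with comfortable margins while a full run of the suite and the acceptance
script stays in the minutes range on a single CPU. Quantiles are type-1
order statistics; ties are resolved by the strict-inequality flagging rule;
Kruskal–Wallis, Spearman, chi-square and Kolmogorov–Smirnov statistics come
from scipy.

## Known limitations

- Plateau-style skew segments longer than q × local_window are structurally
  under-recovered by the quantile detector (see above); this is a property
  of the published procedure itself, not of this implementation.
- Replichore assignment ignores that genes spanning *ori*/*ter* belong to
  both arcs; midpoints decide.
- The Proteinortho parser synthesises family identifiers by row order;
  cross-matrix family identity must come from the gene identifiers.
- `ter` inference by cumulative-skew extremum assumes a single dominant
  skew inversion; heavily rearranged chromosomes may need a curated *ter*.
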