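# Methods

This note documents the models and numerical choices behind
`spcpintron`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
convention exists.

## Coordinates and sequence handling

All internal coordinates are 0-based half-open; TSV/GFF3 report output
is 1-based inclusive. IUPAC ambiguity codes are stored verbatim and
never expanded; motif matching interprets them as base sets (two codes
match when their sets intersect). Duplicate FASTA ids are an error
rather than being renamed, because record ids key the genomic/cDNA
pairing. Case is preserved: by convention exons are rendered uppercase
and introns lowercase.

## Intron discovery

A genomic cassette and its spliced cDNA are related by exact excision of
the introns, so detection reduces to finding genomic-only insertions in
a pairwise alignment. The aligner first chains maximal exact k-mer
matches (k = 12) colinearly to locate the single cassette region the
cDNA derives from — this is what makes tandem arrays and long intergenic
flanks cheap, since only the located slice is aligned — and then runs an
affine-gap global alignment (match +2, mismatch −3, gap open −10, gap
extend −0.2) over that slice. The cheap gap extension keeps each intron
one contiguous gap. A pair whose chained exact matches cover fewer than
`min_anchors x k` bases is rejected as unpairable. On inputs up to a few
hundred nt the alignment is verified in the test suite against an
independent hand-written Gotoh dynamic program.

Insertions of at least `min_intron_len` (default 50 nt) become intron
calls; shorter ones are reported as indels. The default separates true
introns (the smallest known sPCP intron is 108 nt) from the 3–12 nt
alanine-codon indels common in the signal-peptide region. When flanking
repeats allow an insertion to slide without changing the spliced
product, every equivalent placement is enumerated and scored against the
dinoflagellate splice consensus — donor intron side `gy` (2 points),
acceptor intron terminus `sag` (3 points), IUPAC-aware — and the
best-scoring placement wins, leftmost on ties. No published rule fixes
this tie-break; leftmost was chosen for determinism. A call whose best
placement scores zero is emitted with a warning flag rather than
suppressed.

Phase is the insertion offset modulo 3; host-codon context is reported
as the interrupted codon's amino acid (phase 1/2) or the flanking pair
(phase 0), with mature-peptide numbering obtained by subtracting the
configured signal+transit leader length.

## Orthology

Two introns are called orthologous when (1) their insertion points map
to the same column of a CDS alignment, (2) donor and acceptor junction
windows each differ at no more than `junction_mismatch_max` positions
(default 1, IUPAC-aware), and (3) a global alignment of the intron
sequences reaches `intron_identity >= identity_threshold` (default
0.5). The two numeric cutoffs have no published values; both are
exposed in configuration and echoed into reports. The bundled
`star_msa` helper builds the CDS alignment when none is supplied; it is
a centre-star aligner adequate for the near-identical CDSs of one gene
family, not a general MSA tool — supply an external alignment for
anything more divergent.

## Proto-splice scoring

At each authentic insertion column, the 4-mer at CDS positions −3..+1
of every intronless taxon is classified by the first matching rule:
exact match to an observed authentic junction, then the MAG↓G
proto-splice motif (`[AC]AGG`), then a cryptic-variant motif list, else
none. The priority order encodes the idea that an exact junction match
is stronger evidence than a generic motif. The cryptic list ships empty
(curated cryptic-splice catalogues exist only for human disease genes)
and is user-editable, one IUPAC 4-mer per line.

## Distances and dN/dS

Closed forms: p-distance; F81 `d = −B ln(1 − p/B)`, `B = 1 − Σπ²` with
empirical frequencies; K80 `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`; gamma-rate
K80 `d = (α/2)[(1−2P−Q)^(−1/α) −1] + (α/4)[(1−2Q)^(−1/α) −1]`. The
gamma shape α has no default and must be supplied. HKY85 has no closed
form; the pairwise distance maximizes the two-sequence likelihood built
from the closed-form HKY transition matrix over branch length with κ
profiled (L-BFGS-B, ftol 1e−12); with equal base frequencies it agrees
with K80 to ~1e−3. Gapped or ambiguous columns are excluded pairwise,
not listwise. Matrix averages are the mean of the upper triangle, with
saturated pairs flagged and excluded from an (then flagged) average.

Percent similarity is identity over mutually ungapped columns — the
simplest reading of a statistic whose original software formula is
undocumented.

dN/dS follows Nei–Gojobori (1986): per-codon synonymous site fractions
(changes to stop codons count as nonsynonymous), substitution counts
averaged with equal weight over all shortest mutation paths that avoid
stop codons (all paths if none avoid them), Jukes–Cantor correction,
undefined above the p = 0.75 ceiling. A pair with substitutions but no
nonsynonymous change reports ratio 0 even where dS itself saturates on
degenerate tiny inputs.

The chimera screen is a deliberate simplification of partial-tree
methods: for each candidate breakpoint the nearest reference
(p-distance) of the 5′ and 3′ fragments is found, and a clone is
chimeric when the fragments choose different parents and the two-parent
fit beats the best single parent by ≥ `threshold` (default 0.04, set
above the nearest-parent noise observed in star-phylogeny simulations
at ~5 % divergence).

## Parsimony and gain/loss accounting

Fitch scoring treats `?` and `-` as missing (compatible with every
state, contributing no changes); it is property-tested against
exhaustive internal-state enumeration on all trees of up to six taxa.
Indel coding follows the simple method: each distinct gap (same start
and end) is one binary character, with taxa whose own gap strictly
contains it scored `?`. Tree search is random-order stepwise addition
polished by nearest-neighbour interchange, repeated over replicates;
NNI (rather than more aggressive rearrangement) is sufficient at the
package's intended scale of ≤ ~15 taxa, where the search is checked
against exhaustive enumeration on seven taxa. Bootstrap support is the
percentage of character-resampled replicates whose best tree(s) contain
each bipartition. A single integer seed drives replicate order and
resampling; identical seeds give identical output.

Gain/loss accounting needs a rooted tree (an outgroup-rooting helper is
provided). Three statistics are computed: `min_gains`, the summed Fitch
length over intron characters; `forced_presence_single_losses`, the
per-intron minimum number of 1→0 edges when the root is fixed present
and re-gain forbidden (linear-time DP); and
`forced_presence_event_losses`, the minimum number of edges carrying a
loss event when one event may delete any subset of the introns still
present — computed exactly by DP over presence subsets, exponential in
the intron count and intended for the ≤ ~8 introns a locus realistically
carries. Multiple introns lost on one edge count as one event only in
this co-loss mode.

## Synthetic-data generator

The generator is the package's test bed: it emulates the statistical
structure of a tandem-array sPCP gene family so that every stage of the
chain can be exercised against known truth.

Substitution model: proposals are drawn per site with transition bias κ,
and accepted always if synonymous, with probability ω if nonsynonymous,
never if stop-creating; branch lengths are expected *neutral*
substitutions per site. Introns and intergenic spacers evolve neutrally
at a configurable rate multiple (default 1.0) with the five junction
bases frozen (splice sites are under selection, and their conservation
is itself one of the orthology criteria being tested). Alanine-codon
indels hit a fixed signal-peptide codon as a Poisson process (default
10 events per unit branch length), shifting all downstream coordinates
by whole codons. Intron gains happen on named branches at configured
proto-splice positions, drawing length uniformly from a configured
range; the exon context of a pending gain is also frozen so the motif
survives until the gain occurs.

The default long-gene configuration encodes the architecture the
package is designed around: a 1098 nt CDS in exons of 127/126/845 nt,
two phase-1 introns (209–264 and 297–412 nt) gained on the stem of a
four-taxon clade of two two-taxon lineages, Lys-Ala codon pairs at
mature positions 42/43 and 205/206, signal+transit leader of 52 aa, and
per-edge branch length 0.0235 with ω = 0.14 and κ = 1.5 — calibrated
once, analytically plus a small pilot simulation, so that
between-lineage cassette percent similarity sits near 93.4, CDS
similarity near 96.6 and the Nei–Gojobori-measured dN/dS near 0.14. κ
matters here: because Nei–Gojobori site counting ignores transition
bias, the NG-measured ratio underestimates the mechanistic ω as κ
grows (~15 % at κ = 2, ~7 % at κ = 1.5). The default short-gene
configuration is a 612 nt CDS in 282/330 nt exons whose single phase-0
intron (108–117 nt) falls between the Lys-Ala pair at mature 42/43 on
one terminal branch of a four-taxon tree.

What the generator does **not** emulate: PCR/cloning artefacts
(chimeras, polymerase slippage), sequencing error, intra-array copy
heterogeneity beyond a small optional per-copy divergence, rate
variation among sites, codon-frequency bias, and selection on intron
bodies. Passing recovery tests therefore demonstrates correctness of
the inference chain under a clean generative model, not robustness to
every artefact of real amplicon data.

## Problem sizes and determinism

Test-suite and acceptance-script problem sizes are desk-scale by
design: four-taxon cassette datasets of ~2.8 kb genomic records,
exhaustive oracles at ≤ 7 taxa, ω recovery at 500 codons over 100–200
replicate seeds, and the splicing invariant over 100 generated pairs.
All randomness flows from named integer seeds (numpy `default_rng` /
`random.Random`); the acceptance script derives every internal seed
from its `--seed` argument, and identical seeds reproduce identical
output files byte for byte.

## Known limitations

- The seed-and-chain aligner assumes the cDNA really is a spliced
  product of the genomic input; it will refuse, not repair, badly
  mismatched pairs.
- `star_msa` is not codon-aware; orthology column mapping across
  frame-shifted alignments should use an external codon-aware MSA.
- HKY85 distances assume stationarity and use pair-specific empirical
  frequencies, so matrices mixing very different compositions are not
  strictly comparable across pairs.
- The event-loss DP is exact but exponential in intron count; beyond
  ~12 characters it refuses rather than approximating.
- The dotplot similarity index is identity- (or BLOSUM62-positive-)
  based with window 16 and stringency 40 %; published SI values from
  legacy GUI tools depend on unpublished parameters and are matched
  only qualitatively.
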