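# spcpintron

Tools for discovering spliceosomal introns in dinoflagellate soluble
peridinin–chlorophyll *a*-protein (sPCP) gene families and dating their
gain on a phylogeny.

Peridinin-containing dinoflagellates carry sPCP light-harvesting genes
in heterogeneous tandem arrays, in a short (~600 bp CDS) and a long
(~1.1 kb CDS) form; the long form arose once, by duplication and fusion
of a short gene. Almost all sPCP genes sequenced to date are intronless,
so an intron found in one lineage poses a dating question: was it gained
recently on that lineage's branch, or is it ancient and repeatedly lost
everywhere else? This package implements the full inference chain for
that question:

- **Intron discovery** — align a genomic cassette against its own
  spliced cDNA; each genomic-only insertion above a length threshold is
  an intron. Boundary ambiguity created by flanking repeats is resolved
  by maximizing the splice-junction consensus (dinoflagellate introns
  begin `gy` and end `sag`, not the canonical `gt..ag`), ties leftmost.
- **Junction analysis** — phase and host-codon context of each
  insertion, junction windows at bases −3..+2 of each boundary, and
  per-column minimal-IUPAC consensus patterns (e.g. donor `MWG|gy`,
  acceptor `sag|GY`).
- **Orthology** — two introns from different taxa are orthologous when
  they occupy the same CDS alignment column, have compatible junctions,
  and their sequences align above an identity threshold.
- **Proto-splice scanning** — score the 4-mer at positions −3..+1 of
  each insertion column in *intronless* relatives against observed
  junctions, the classic MAG↓G proto-splice motif (M = A or C) and a
  user-editable cryptic-variant list; locate the symmetric Lys-Ala
  (AAR)(GCC) codon pairs that flank the short-gene insertion site.
- **Divergence statistics** — closed-form pairwise distances (p, F81,
  K80, gamma-corrected K80) plus a maximum-likelihood HKY85 distance;
  percent similarity; Nei–Gojobori (1986) dN/dS with Jukes–Cantor
  correction; a breakpoint screen for PCR chimeras.
- **Parsimony and gain/loss accounting** — Fitch scoring with gaps as
  missing, simple indel coding, stepwise-addition + NNI tree search with
  bootstrap, and the central statistic: on a rooted tree with an intron
  presence/absence matrix, the minimum number of gains versus the number
  of losses forced by assuming ancestral presence (per intron, and as
  co-loss events when co-resident introns can be deleted together).
- **Domain dotplots** — sliding-window similarity-index diagonals for
  comparing a short sPCP against the N- and C-terminal domains of a long
  one (the duplication–fusion signature).
- **Synthetic data** — a generator that evolves sPCP cassettes on a tree
  (codon model with dN/dS ω and transition bias κ, alanine-codon indels
  in the signal peptide, neutral introns and spacers) and plants introns
  at proto-splice sites on designated branches, with a ground-truth
  table. Its defaults encode the architecture and divergence levels the
  analysis is designed around.

## Worked example

Generate a four-taxon synthetic long-gene dataset, call its introns, and
run the gain/loss accounting on a six-taxon species tree:

```sh
$ spcpintron simulate --kind long --seed 4 --outdir sim
wrote sim (seed=4, taxa=4)

$ spcpintron detect --genomic sim/genomic.fasta --cdna sim/cdna.fasta --out introns.tsv
$ head -5 introns.tsv
taxon   start  end   length  phase  donor   acceptor  cds_insert_pos  host_codon  warning
Dstok28 719    975   257     1      CTG|gt  cag|GT    127             43          0
Dstok28 1102   1489  388     1      CAG|gc  gag|GC    253             85          0
Ap1     719    975   257     1      CTG|gt  cag|GT    127             43          0
Ap1     1102   1489  388     1      CAG|gc  gag|GC    253             85          0
```

Every taxon carries two phase-1 introns (`start`/`end` are 1-based
genomic coordinates; uppercase = exon, lowercase = intron in the
junction columns). Intron 1 interrupts codon 43 at CDS offset 127,
intron 2 codon 85 at offset 253, with donor exon sides `CTG` and `CAG`
— jointly the `MWG|gy` consensus.

With both introns present only in one clade (`CladeB`) of a wider tree,
the accounting contrasts the gain and ancestral-presence scenarios:

```sh
$ spcpintron gainloss --tree tree.nwk --matrix matrix.tsv
{
  "min_gains": 2,
  "forced_presence_single_losses": 6,
  "forced_presence_event_losses": 3
}
```

Two gains on the clade stem suffice; treating the introns as ancestral
would instead force six independent single-intron losses, or three loss
events even when both introns can be dropped together — the parsimony
argument for recent, lineage-specific gain.

`spcpintron run-all --config run.yaml` chains every stage (detection,
consensus, orthology, proto-splice scan, distances, dN/dS, tree search,
gain/loss) and writes per-stage TSV/GFF3 files plus a versioned
`report.json`.

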