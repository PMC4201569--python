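"""Intron discovery from genomic/cDNA pairs and intron orthology calls.

A spliceosomal intron shows up as a genomic-only insertion when a genomic
gene cassette is globally aligned against its own spliced cDNA.  This
module finds those insertions, resolves the boundary ambiguity that
flanking repeats create by maximizing a splice-consensus score (donor
intron side ``gy``, acceptor intron terminus ``sag``; dinoflagellate
introns do not use the canonical GT..AG), classifies intron phase and the
host-codon context, summarizes junction windows into IUPAC consensus
patterns, and decides whether two introns from different taxa are
orthologous by three criteria: same CDS position, compatible junctions,
and intron sequence identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .seqio import (
    CodingAnnotation,
    SequenceRecord,
    iupac_code,
    iupac_compatible,
)

__all__ = [
    "IntronCallParams",
    "PairAlignment",
    "JunctionWindow",
    "IntronCall",
    "CallResult",
    "OrthologyCall",
    "UnpairableError",
    "align_pair",
    "call_introns",
    "phase_and_context",
    "junction_consensus",
    "call_orthology",
    "splice",
    "star_msa",
]


class UnpairableError(ValueError):
    """Genomic and cDNA sequences share no anchor seeds — wrong pairing."""


@dataclass
class IntronCallParams:
    """Tunable knobs for detection and orthology.

    ``min_intron_len`` separates introns from codon-scale indels (the
    tandem alanine-codon indels in sPCP signal peptides are 3-12 nt; the
    smallest known sPCP intron is 108 nt, so 50 is a comfortable divider).
    ``identity_threshold`` and ``junction_mismatch_max`` implement the
    orthology criteria; no published cutoffs exist, so both are exposed.
    """

    min_intron_len: int = 50
    kmer: int = 12
    min_anchors: int = 3
    identity_threshold: float = 0.5
    junction_mismatch_max: int = 1
    match_score: float = 2.0
    mismatch_score: float = -3.0
    open_gap_score: float = -10.0
    extend_gap_score: float = -0.2


@dataclass
class PairAlignment:
    """Global genomic-vs-cDNA alignment over the anchored cassette region.

    ``g_offset`` is the genomic coordinate of the first base of
    ``g_row``: the alignment covers only the genomic slice the anchor
    chain located (flanking spacer and neighbouring tandem copies are
    excluded before alignment rather than soaked up as end gaps).
    """

    genomic: SequenceRecord
    cdna: SequenceRecord
    g_row: str  # gapped genomic row over the anchored slice
    c_row: str  # gapped cDNA row
    score: float
    g_offset: int = 0

    def insertions(self) -> list[tuple[int, int, int]]:
        """Genomic-only blocks as (genomic_start, genomic_end, cdna_pos).

        Leading and trailing cDNA gaps are flanking sequence, not
        insertions, and are excluded.
        """
        first = last = None
        for idx, c in enumerate(self.c_row):
            if c != "-":
                if first is None:
                    first = idx
                last = idx
        if first is None:
            return []
        out = []
        gpos = self.g_offset
        cpos = 0
        run_start = None
        for idx, (g, c) in enumerate(zip(self.g_row, self.c_row)):
            inside = first <= idx <= last
            if inside and c == "-" and g != "-":
                if run_start is None:
                    run_start = gpos
            else:
                if run_start is not None:
                    out.append((run_start, gpos, cpos))
                    run_start = None
            if g != "-":
                gpos += 1
            if c != "-":
                cpos += 1
        if run_start is not None:
            out.append((run_start, gpos, cpos))
        return out

    def identity(self) -> float:
        match = cols = 0
        for g, c in zip(self.g_row, self.c_row):
            if g != "-" and c != "-":
                cols += 1
                if g.upper() == c.upper():
                    match += 1
        return match / cols if cols else 0.0


def _exact_segments(g: str, c: str, k: int, max_occ: int = 64):
    """Maximal exact diagonal matches as (c_start, g_start, length)."""
    index: dict[str, list[int]] = {}
    for i in range(0, len(g) - k + 1):
        index.setdefault(g[i : i + k], []).append(i)
    matches: set[tuple[int, int]] = set()
    for j in range(0, len(c) - k + 1):
        for i in index.get(c[j : j + k], ())[:max_occ]:
            matches.add((j, i))
    segs: list[tuple[int, int, int]] = []
    for j, i in sorted(matches):
        if (j - 1, i - 1) in matches:
            continue  # not the start of a maximal run
        length = k
        while (j + length - k + 1, i + length - k + 1) in matches:
            length += 1
        segs.append((j, i, length))
    return segs


def _chain_segments(segs):
    """Best colinear chain (max total matched length), by quadratic DP."""
    segs = sorted(segs)
    n = len(segs)
    best = [0.0] * n
    back = [-1] * n
    for i, (cj, gi, L) in enumerate(segs):
        best[i] = L
        for j in range(i):
            cj2, gi2, L2 = segs[j]
            # predecessors may overlap slightly (maximal runs share the
            # boundary bases around a splice site); trim the overlap
            if not (cj2 < cj and gi2 < gi and cj2 + L2 < cj + L
                    and gi2 + L2 < gi + L):
                continue
            overlap = max(0, cj2 + L2 - cj, gi2 + L2 - gi)
            cand = best[j] + L - overlap
            if cand > best[i]:
                best[i] = cand
                back[i] = j
    if not segs:
        return []
    end = max(range(n), key=lambda i: best[i])
    chain = []
    while end != -1:
        chain.append(segs[end])
        end = back[end]
    return chain[::-1]


def align_pair(
    genomic: SequenceRecord, cdna: SequenceRecord, params: IntronCallParams | None = None
) -> PairAlignment:
    """Align a genomic cassette to its matched cDNA.

    Exact ``kmer`` seed matches are chained colinearly to locate the one
    cassette region the cDNA derives from (so tandem arrays and long
    flanks are handled without aligning them); that genomic slice is
    then globally aligned to the cDNA with affine gaps, which makes each
    cDNA-absent genomic segment a contiguous insertion.
    """
    params = params or IntronCallParams()
    if genomic.moltype != "dna" or cdna.moltype != "dna":
        raise ValueError("align_pair needs two nucleotide sequences")
    g = genomic.upper
    c = cdna.upper
    chain = _chain_segments(_exact_segments(g, c, params.kmer))
    covered = sum(L for _, _, L in chain)
    if covered < params.min_anchors * params.kmer:
        raise UnpairableError(
            f"no anchor seeds between {genomic.id!r} and {cdna.id!r}; "
            "are these really a genomic/cDNA pair?"
        )
    margin = 32
    c0, g0, _ = chain[0]
    cN, gN, LN = chain[-1]
    lo = max(0, g0 - c0 - margin)
    hi = min(len(g), gN + LN + (len(c) - cN - LN) + margin)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.open_gap_score
    aligner.extend_gap_score = params.extend_gap_score
    aln = aligner.align(g[lo:hi], c)[0]
    return PairAlignment(
        genomic=genomic, cdna=cdna, g_row=str(aln[0]), c_row=str(aln[1]),
        score=aln.score, g_offset=lo,
    )


@dataclass
class JunctionWindow:
    """Five informative bases at one splice boundary.

    ``left3``/``right2`` are positions -3..-1 and +1..+2 of the boundary;
    for a donor the left side is exon and the right intron, for an
    acceptor the left side is intron and the right exon.  Rendered with
    exon bases uppercase and intron bases lowercase, e.g. ``MWG|gy``.
    """

    kind: str  # {"donor", "acceptor"}
    left3: str
    right2: str

    def __post_init__(self) -> None:
        if self.kind not in ("donor", "acceptor"):
            raise ValueError(f"unknown junction kind {self.kind!r}")
        if len(self.left3) != 3 or len(self.right2) != 2:
            raise ValueError("junction window must be 3 nt + 2 nt")
        self.left3 = self.left3.upper()
        self.right2 = self.right2.upper()

    def render(self) -> str:
        if self.kind == "donor":
            return f"{self.left3.upper()}|{self.right2.lower()}"
        return f"{self.left3.lower()}|{self.right2.upper()}"

    @property
    def bases(self) -> str:
        return self.left3 + self.right2


@dataclass
class IntronCall:
    """One detected intron on a genomic sequence."""

    taxon: str
    genomic_start: int
    genomic_end: int
    cds_insert_pos: int
    phase: int
    donor: JunctionWindow
    acceptor: JunctionWindow
    sequence: str
    host_codon_index: int
    host_aa: str | tuple[str, str] | None
    consensus_score: int
    warning: bool = False

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start


@dataclass
class CallResult:
    """Intron calls plus sub-threshold insertions (codon indels)."""

    introns: list[IntronCall]
    indels: list[tuple[int, int]]


_DONOR_PATTERN = "GY"  # intron 5' terminus
_ACCEPTOR_PATTERN = "SAG"  # intron 3' terminus


def _consensus_score(g: str, start: int, end: int) -> int:
    score = 0
    donor = g[start : start + 2]
    if len(donor) == 2:
        score += sum(iupac_compatible(p, b) for p, b in zip(_DONOR_PATTERN, donor))
    acceptor = g[end - 3 : end]
    if len(acceptor) == 3:
        score += sum(
            iupac_compatible(p, b) for p, b in zip(_ACCEPTOR_PATTERN, acceptor)
        )
    return score


def _slide_range(g: str, start: int, end: int) -> list[tuple[int, int]]:
    """All boundary placements that excise the same spliced product."""
    placements = [(start, end)]
    s, e = start, end
    while s > 0 and g[s - 1] == g[e - 1]:
        s -= 1
        e -= 1
        placements.append((s, e))
    s, e = start, end
    while e < len(g) and g[s] == g[e]:
        s += 1
        e += 1
        placements.append((s, e))
    placements.sort()
    return placements


def call_introns(
    alignment: PairAlignment,
    annotation: CodingAnnotation | None = None,
    params: IntronCallParams | None = None,
) -> CallResult:
    """Turn genomic-only insertions into intron calls.

    Each insertion of at least ``min_intron_len`` becomes one
    :class:`IntronCall`; its boundary is slid within the repeat-induced
    ambiguity window to the placement with the best splice-consensus
    score (ties broken leftmost), and a call whose best placement scores
    zero consensus matches is flagged with ``warning``.  Shorter
    insertions are reported as indels.  Because boundary sliding never
    changes the spliced product, excising the returned spans always
    reproduces the same sequence the alignment implied (see
    :func:`splice`).
    """
    params = params or IntronCallParams()
    g = alignment.genomic.upper
    c = alignment.cdna.upper
    cds_start = annotation.cds_start if annotation else 0
    introns: list[IntronCall] = []
    indels: list[tuple[int, int]] = []
    for g_start, g_end, c_pos in alignment.insertions():
        if g_end - g_start < params.min_intron_len:
            indels.append((g_start, g_end))
            continue
        placements = _slide_range(g, g_start, g_end)
        scored = [(-_consensus_score(g, s, e), s, e) for s, e in placements]
        scored.sort()
        neg_score, s, e = scored[0]
        score = -neg_score
        shift = s - g_start
        cpos = c_pos + shift  # sliding moves the insertion point on the cDNA too
        cds_pos = cpos - cds_start
        phase = cds_pos % 3
        donor = JunctionWindow(
            "donor",
            left3=c[max(0, cpos - 3) : cpos].rjust(3, "N"),
            right2=g[s : s + 2].ljust(2, "N"),
        )
        acceptor = JunctionWindow(
            "acceptor",
            left3=g[e - 3 : e].rjust(3, "N"),
            right2=c[cpos : cpos + 2].ljust(2, "N"),
        )
        codon_index = cds_pos // 3
        host_aa = _host_aa(c, cds_start, cds_pos)
        introns.append(
            IntronCall(
                taxon=alignment.genomic.id,
                genomic_start=s,
                genomic_end=e,
                cds_insert_pos=cds_pos,
                phase=phase,
                donor=donor,
                acceptor=acceptor,
                sequence=g[s:e],
                host_codon_index=codon_index,
                host_aa=host_aa,
                consensus_score=score,
                warning=score == 0,
            )
        )
    introns.sort(key=lambda ic: ic.genomic_start)
    return CallResult(introns=introns, indels=indels)


def _host_aa(cdna: str, cds_start: int, cds_pos: int) -> str | tuple[str, str] | None:
    from Bio.Seq import Seq

    def aa_at(codon_index: int) -> str | None:
        s = cds_start + 3 * codon_index
        codon = cdna[s : s + 3]
        if len(codon) != 3:
            return None
        return str(Seq(codon).translate())

    phase = cds_pos % 3
    idx = cds_pos // 3
    if phase == 0:
        prev = aa_at(idx - 1) if idx > 0 else None
        nxt = aa_at(idx)
        return (prev or "", nxt or "")
    return aa_at(idx)


def phase_and_context(
    call: IntronCall, annotation: CodingAnnotation, cds_len: int | None = None
) -> tuple[int, str | tuple[str, str] | None, int | tuple[int, int]]:
    """Phase, host amino acid(s) and 1-based mature-peptide position.

    For a phase-0 intron the insertion sits between two codons, so the
    host amino acids and mature positions come as (preceding, following)
    pairs; otherwise the interrupted codon's amino acid and position are
    returned.
    """
    if call.cds_insert_pos < 0 or (
        cds_len is not None and call.cds_insert_pos > cds_len
    ):
        raise ValueError(
            f"cds_insert_pos {call.cds_insert_pos} outside the CDS"
        )
    leader = annotation.leader_len_aa
    idx1 = call.host_codon_index + 1  # 1-based preprotein codon number
    if call.phase == 0:
        mature = (idx1 - 1 - leader, idx1 - leader)
    else:
        mature = idx1 - leader
    return call.phase, call.host_aa, mature


def junction_consensus(
    windows: list[JunctionWindow],
) -> tuple[str | None, str | None]:
    """Per-column minimal IUPAC consensus of junction windows.

    Returns ``(donor_pattern, acceptor_pattern)`` rendered with exon
    bases uppercase and intron bases lowercase (``None`` for a side with
    no windows).  Idempotent and order-independent.
    """
    if not windows:
        raise ValueError("need at least one junction window")

    def consensus(group: list[JunctionWindow], kind: str) -> str | None:
        if not group:
            return None
        left = "".join(
            iupac_code([w.left3[i] for w in group]) for i in range(3)
        )
        right = "".join(
            iupac_code([w.right2[i] for w in group]) for i in range(2)
        )
        return JunctionWindow(kind, left, right).render()

    donors = [w for w in windows if w.kind == "donor"]
    acceptors = [w for w in windows if w.kind == "acceptor"]
    return consensus(donors, "donor"), consensus(acceptors, "acceptor")


@dataclass
class OrthologyCall:
    """Outcome of the three-criterion intron orthology test."""

    same_position: bool
    junction_compatible: bool
    intron_identity: float
    orthologous: bool = field(init=False)
    identity_threshold: float = 0.5

    def __post_init__(self) -> None:
        self.orthologous = (
            self.same_position
            and self.junction_compatible
            and self.intron_identity >= self.identity_threshold
        )


def _insertion_column(aligned: str, pos: int) -> int:
    """Alignment column of the first CDS base after `pos` ungapped bases."""
    count = 0
    for idx, ch in enumerate(aligned):
        if ch != "-":
            if count == pos:
                return idx
            count += 1
    if count == pos:
        return len(aligned)
    raise ValueError(f"position {pos} beyond ungapped length {count}")


def _window_mismatches(a: JunctionWindow, b: JunctionWindow) -> int:
    return sum(
        not iupac_compatible(x, y) for x, y in zip(a.bases, b.bases)
    )


def _global_identity(a: str, b: str) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a.upper(), b.upper())[0]
    r0, r1 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(r0, r1))
    return matches / len(r0)


def call_orthology(
    a: IntronCall,
    b: IntronCall,
    cds_alignment: dict[str, str],
    params: IntronCallParams | None = None,
) -> OrthologyCall:
    """Are two introns from different taxa copies of one insertion event?

    Criteria: the insertion points map to the same column of the supplied
    CDS alignment; donor and acceptor windows each differ at no more than
    ``junction_mismatch_max`` positions (IUPAC-aware); and the globally
    aligned intron sequences reach ``identity_threshold`` identity.
    """
    params = params or IntronCallParams()
    for call in (a, b):
        if call.taxon not in cds_alignment:
            raise ValueError(f"taxon {call.taxon!r} missing from cds_alignment")
    col_a = _insertion_column(cds_alignment[a.taxon], a.cds_insert_pos)
    col_b = _insertion_column(cds_alignment[b.taxon], b.cds_insert_pos)
    same_pos = col_a == col_b
    junct = (
        _window_mismatches(a.donor, b.donor) <= params.junction_mismatch_max
        and _window_mismatches(a.acceptor, b.acceptor)
        <= params.junction_mismatch_max
    )
    ident = _global_identity(a.sequence, b.sequence)
    return OrthologyCall(
        same_position=same_pos,
        junction_compatible=junct,
        intron_identity=ident,
        identity_threshold=params.identity_threshold,
    )


def splice(genomic: str, calls: list[IntronCall]) -> str:
    """Excise called introns from a genomic sequence."""
    out = []
    prev = 0
    for call in sorted(calls, key=lambda ic: ic.genomic_start):
        out.append(genomic[prev : call.genomic_start])
        prev = call.genomic_end
    out.append(genomic[prev:])
    return "".join(out)


# ---------------------------------------------------------------------------
# Small star-alignment helper for building the CDS MSA the orthology and
# proto-splice scans consume when no external alignment is supplied.  The
# longest sequence is the star centre; insertions relative to it are merged
# column-wise.  Adequate for the near-identical CDSs of one gene family;
# not a general-purpose aligner.


def star_msa(records: list[SequenceRecord]) -> dict[str, str]:
    if len(records) < 2:
        return {r.id: r.residues for r in records}
    centre = max(records, key=lambda r: len(r.residues))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -1.0
    n = len(centre.residues)
    # per-sequence: inserted residues before each centre position (and at end)
    parsed: dict[str, tuple[list[str], list[str]]] = {}
    max_ins = [0] * (n + 1)
    for rec in records:
        if rec.id == centre.id:
            continue
        aln = aligner.align(centre.upper, rec.upper)[0]
        c_row, s_row = str(aln[0]), str(aln[1])
        cells: list[str] = [""] * (n + 1)  # insertions before centre pos i
        body: list[str] = [""] * n  # residue (or '-') at centre pos i
        cpos = 0
        for cc, sc in zip(c_row, s_row):
            if cc == "-":
                cells[cpos] += sc
            else:
                body[cpos] = sc
                cpos += 1
        parsed[rec.id] = (cells, body)
        for i, ins in enumerate(cells):
            max_ins[i] = max(max_ins[i], len(ins))
    out: dict[str, str] = {}
    centre_row = []
    for i in range(n + 1):
        centre_row.append("-" * max_ins[i])
        if i < n:
            centre_row.append(centre.residues[i])
    out[centre.id] = "".join(centre_row)
    for rec in records:
        if rec.id == centre.id:
            continue
        cells, body = parsed[rec.id]
        row = []
        for i in range(n + 1):
            row.append(cells[i].ljust(max_ins[i], "-"))
            if i < n:
                row.append(body[i])
        out[rec.id] = "".join(row)
    return out
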