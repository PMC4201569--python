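"""Proto-splice-site scoring of potential exon junctions.

If spliceosomal introns insert preferentially at pre-existing sequence
contexts (the MAG|G proto-splice site, M = A or C), then intronless
orthologs should still carry junction-like 4-mers at the alignment
columns where related taxa acquired introns.  This module extracts the
4-mer at CDS positions -3..+1 around an insertion point, classifies it
against (in priority order) the authentic junctions observed in the gene
family, the MAG|G motif, and a user-editable list of cryptic splice-site
variants, and scans a CDS alignment across its intronless taxa.  It also
locates the symmetric lysine-alanine codon pairs ((AAG|AAA)(GCC)) that
mark the short-intron context on both sides of the long-gene duplication
axis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .seqio import CodingAnnotation, SequenceRecord, iupac_matches

__all__ = [
    "ProtoSpliceHit",
    "MATCH_CLASSES",
    "extract_fourmer",
    "classify_fourmer",
    "scan_intronless",
    "locate_kala_pairs",
    "load_motif_list",
]

MATCH_CLASSES = (
    "authentic",
    "observed_junction_exact",
    "protosplice_MAGG",
    "cryptic_variant",
    "none",
)

_MAGG = re.compile(r"^[AC]AGG$")
_ACGT = re.compile(r"^[ACGT]+$")


@dataclass
class ProtoSpliceHit:
    """Classification of one taxon's 4-mer at one insertion column."""

    taxon: str
    aln_column: int
    fourmer: str | None
    match_class: str
    gapped: bool = False


def extract_fourmer(cds: SequenceRecord | str, insert_pos: int) -> str:
    """The 4 CDS bases at positions -3..+1 around an insertion point.

    ``insert_pos`` is the 0-based offset of the first base following the
    (real or potential) intron.
    """
    seq = cds.upper if isinstance(cds, SequenceRecord) else cds.upper()
    if insert_pos < 3 or insert_pos > len(seq) - 1:
        raise ValueError(
            f"insertion point {insert_pos} too close to the CDS end "
            f"(need 3 <= pos <= {len(seq) - 1})"
        )
    return seq[insert_pos - 3 : insert_pos + 1]


def classify_fourmer(
    fourmer: str,
    observed_junctions: set[str] = frozenset(),
    cryptic_list: set[str] = frozenset(),
) -> str:
    """Highest-priority junction class a 4-mer satisfies.

    Priority: exact match to an observed authentic junction, then the
    MAG|G proto-splice motif, then the cryptic-variant list (IUPAC
    allowed in list entries), else ``none``.
    """
    fourmer = fourmer.upper()
    if not _ACGT.fullmatch(fourmer) or len(fourmer) != 4:
        raise ValueError(f"not an unambiguous 4-mer: {fourmer!r}")
    if fourmer in {j.upper() for j in observed_junctions}:
        return "observed_junction_exact"
    if _MAGG.fullmatch(fourmer):
        return "protosplice_MAGG"
    for motif in cryptic_list:
        if iupac_matches(motif.upper(), fourmer):
            return "cryptic_variant"
    return "none"


def _fourmer_at_column(aligned: str, column: int) -> tuple[str | None, bool]:
    """-3..+1 4-mer of one row at an alignment column.

    The window must be contiguous in the alignment (no gap inside or at
    the scored position); otherwise the row is flagged gapped.
    """
    if column < 3:
        return None, True
    window = aligned[column - 3 : column + 1]
    if "-" in window:
        return None, True
    return window, False


def scan_intronless(
    cds_alignment: dict[str, str],
    authentic_insertion_columns: dict[int, set[str]],
    observed_junctions: set[str] = frozenset(),
    cryptic_list: set[str] = frozenset(),
) -> list[ProtoSpliceHit]:
    """Score every taxon at every authentic insertion column.

    ``authentic_insertion_columns`` maps an alignment column to the taxa
    that actually carry an intron there; those taxa are labelled
    ``authentic`` and all others are classified by
    :func:`classify_fourmer`.  Rows gapped at or just before the column
    yield ``none`` with the gap flag set.
    """
    length = len(next(iter(cds_alignment.values())))
    hits: list[ProtoSpliceHit] = []
    for column in sorted(authentic_insertion_columns):
        if not (0 <= column < length):
            raise ValueError(f"column {column} outside alignment of width {length}")
        bearers = authentic_insertion_columns[column]
        for taxon in sorted(cds_alignment):
            fourmer, gapped = _fourmer_at_column(cds_alignment[taxon], column)
            if taxon in bearers:
                cls = "authentic"
            elif gapped:
                cls = "none"
            else:
                cls = classify_fourmer(fourmer, observed_junctions, cryptic_list)
            hits.append(
                ProtoSpliceHit(
                    taxon=taxon, aln_column=column, fourmer=fourmer,
                    match_class=cls, gapped=gapped,
                )
            )
    return hits


_KALA = re.compile(r"(?:AAG|AAA)GCC")


def locate_kala_pairs(
    cds: SequenceRecord | str, annotation: CodingAnnotation | None = None
) -> list[int]:
    """Mature-peptide positions (1-based) of adjacent Lys-Ala codon pairs.

    Finds every in-frame (AAG|AAA)(GCC) pair and reports the first
    (lysine) codon's position in mature-peptide numbering when an
    annotation is given, preprotein numbering otherwise.
    """
    seq = cds.upper if isinstance(cds, SequenceRecord) else cds.upper()
    if len(seq) % 3:
        raise ValueError("CDS length not a multiple of 3")
    leader = annotation.leader_len_aa if annotation else 0
    out = []
    for codon_i in range(0, len(seq) // 3 - 1):
        if _KALA.fullmatch(seq[codon_i * 3 : codon_i * 3 + 6]):
            out.append(codon_i + 1 - leader)
    return out


def load_motif_list(path: str | Path | None = None) -> set[str]:
    """Read a motif file (one 4-mer per line, IUPAC allowed, '#' comments).

    Without a path the packaged default cryptic-variant list is loaded;
    it ships empty apart from comments — the junctions observed in one's
    own data enter through ``observed_junctions`` instead — and users may
    extend it.
    """
    if path is None:
        text = (
            resources.files("spcpintron") / "data" / "cryptic_fourmers.txt"
        ).read_text()
    else:
        text = Path(path).read_text()
    out = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip().upper()
        if not line:
            continue
        if len(line) != 4:
            raise ValueError(f"motif {line!r} is not 4 nt")
        out.add(line)
    return out
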