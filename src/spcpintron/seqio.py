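"""Sequence and annotation I/O.

Holds the two basic containers used throughout the package — a named
sequence (:class:`SequenceRecord`) and the coding annotation that maps
between genomic, spliced-CDS, preprotein and mature-peptide coordinates
(:class:`CodingAnnotation`) — plus FASTA round-tripping, translation and
Newick reading.

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open.  Report output (TSV/GFF3)
is 1-based inclusive.  A mature-peptide residue ``m`` (0-based) sits at
preprotein residue ``m + signal_len_aa + transit_len_aa``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "CodingAnnotation",
    "FastaFormatError",
    "TranslationError",
    "read_fasta",
    "write_fasta",
    "translate",
    "read_newick",
    "load_annotations",
    "IUPAC_SETS",
    "iupac_code",
    "iupac_compatible",
    "iupac_matches",
]

_DNA_CHARS = set("ACGTURYSWKMBDHVN")
_PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

#: IUPAC nucleotide codes -> the set of concrete bases each covers.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_SET_TO_CODE = {v: k for k, v in IUPAC_SETS.items() if k != "U"}


def iupac_code(bases: Iterable[str]) -> str:
    """Minimal IUPAC code covering a set of (possibly ambiguous) bases."""
    union: frozenset[str] = frozenset()
    for b in bases:
        union |= IUPAC_SETS[b.upper()]
    return _SET_TO_CODE[union]


def iupac_compatible(a: str, b: str) -> bool:
    """True when two IUPAC codes can denote the same concrete base."""
    return bool(IUPAC_SETS[a.upper()] & IUPAC_SETS[b.upper()])


def iupac_matches(pattern: str, seq: str) -> bool:
    """Position-wise IUPAC compatibility of equal-length strings."""
    if len(pattern) != len(seq):
        return False
    return all(iupac_compatible(p, s) for p, s in zip(pattern, seq))


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


class TranslationError(ValueError):
    """Raised when a CDS cannot be translated cleanly."""


@dataclass
class SequenceRecord:
    """One named nucleotide or protein sequence.

    ``residues`` are stored verbatim — case is preserved (lowercase is used
    by convention for intronic bases in rendered output) and IUPAC
    ambiguity codes are kept, never expanded.
    """

    id: str
    residues: str
    moltype: str = "dna"  # {"dna", "protein"}
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id: {self.id!r}")
        if not self.residues:
            raise ValueError(f"record {self.id}: empty sequence")
        if self.moltype not in ("dna", "protein"):
            raise ValueError(f"record {self.id}: unknown moltype {self.moltype!r}")
        allowed = _DNA_CHARS if self.moltype == "dna" else _PROTEIN_CHARS
        bad = set(self.residues.upper().replace("-", "")) - allowed
        if bad:
            raise ValueError(
                f"record {self.id}: invalid {self.moltype} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def upper(self) -> str:
        return self.residues.upper()


@dataclass
class CodingAnnotation:
    """CDS location plus targeting-peptide lengths for one isolate.

    ``cds_start``/``cds_end`` are 0-based half-open offsets on the sequence
    they annotate (genomic or spliced).  ``signal_len_aa`` and
    ``transit_len_aa`` shift between mature-peptide and preprotein
    numbering: signal and transit peptides are cleaved off the N terminus
    before the mature light-harvesting protein folds.
    """

    cds_start: int
    cds_end: int
    signal_len_aa: int = 0
    transit_len_aa: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end):
            raise ValueError("require 0 <= cds_start < cds_end")
        if self.signal_len_aa < 0 or self.transit_len_aa < 0:
            raise ValueError("peptide lengths must be non-negative")

    @property
    def leader_len_aa(self) -> int:
        return self.signal_len_aa + self.transit_len_aa

    def mature_to_preprotein(self, m: int) -> int:
        return m + self.leader_len_aa

    def preprotein_to_mature(self, p: int) -> int:
        return p - self.leader_len_aa


def read_fasta(path: str | Path, moltype: str = "dna") -> list[SequenceRecord]:
    """Read a multi-FASTA file into :class:`SequenceRecord` objects.

    Order is preserved, whitespace stripped, case preserved.  Duplicate ids
    raise (ids key the genomic/cDNA pairing downstream, so a silent rename
    would corrupt results).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FastaFormatError(f"{path}: empty file (line 1)")
    first = text.lstrip().splitlines()[0]
    if not first.startswith(">"):
        raise FastaFormatError(f"{path}: does not start with a FASTA header (line 1)")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    rec_id: str | None = None
    desc = ""
    chunks: list[str] = []
    header_line = 0

    def _flush() -> None:
        if rec_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaFormatError(
                f"{path}: record {rec_id!r} has no sequence (line {header_line})"
            )
        records.append(SequenceRecord(rec_id, seq, moltype=moltype, description=desc))

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            header = line[1:].strip()
            if not header:
                raise FastaFormatError(f"{path}: empty FASTA header (line {lineno})")
            parts = header.split(None, 1)
            rec_id = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            if rec_id in seen:
                raise FastaFormatError(
                    f"{path}: duplicate id {rec_id!r} (line {lineno})"
                )
            seen.add(rec_id)
            header_line = lineno
            chunks = []
        else:
            if rec_id is None:
                raise FastaFormatError(f"{path}: sequence before header (line {lineno})")
            chunks.append(re.sub(r"\s+", "", line))
    _flush()
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write records as multi-FASTA; round-trips with :func:`read_fasta`."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), line_width):
                fh.write(rec.residues[i : i + line_width] + "\n")


def translate(cds: SequenceRecord) -> SequenceRecord:
    """Translate an in-frame CDS with the standard genetic code.

    A terminal stop codon is dropped; an internal stop raises naming the
    offending codon index (0-based).
    """
    if cds.moltype != "dna":
        raise TranslationError(f"record {cds.id}: not a nucleotide sequence")
    seq = cds.upper.replace("U", "T")
    if len(seq) % 3 != 0:
        raise TranslationError(
            f"record {cds.id}: length {len(seq)} not a multiple of 3"
        )
    aa = str(Seq(seq).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise TranslationError(
            f"record {cds.id}: internal stop at codon {aa.index('*')}"
        )
    if not aa:
        raise TranslationError(f"record {cds.id}: empty translation")
    return SequenceRecord(cds.id, aa, moltype="protein", description=cds.description)


def read_newick(path: str | Path):
    """Read a Newick tree file; returns :class:`spcpintron.phylo.Tree`."""
    from .phylo import Tree

    return Tree.from_newick(Path(path).read_text())


def load_annotations(path: str | Path) -> dict[str, CodingAnnotation]:
    """Load per-isolate coding annotations from a YAML config.

    Expected layout::

        isolates:
          Dstrig102:
            cds_start: 412
            cds_end: 2087
            signal_len_aa: 24
            transit_len_aa: 9
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "isolates" not in doc:
        raise ValueError(f"{path}: expected a top-level 'isolates' mapping")
    out: dict[str, CodingAnnotation] = {}
    for name, fields in doc["isolates"].items():
        out[name] = CodingAnnotation(
            cds_start=int(fields["cds_start"]),
            cds_end=int(fields["cds_end"]),
            signal_len_aa=int(fields.get("signal_len_aa", 0)),
            transit_len_aa=int(fields.get("transit_len_aa", 0)),
        )
    return out
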