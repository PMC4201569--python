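"""Windowed dotplot similarity and short-vs-long sPCP domain comparison.

Long sPCP apoproteins arose by duplication and fusion of a short sPCP
gene, leaving a pseudo-axis of symmetry: a short sPCP should align to
either half of a long one.  A sliding-window dotplot makes that visible
as off-main diagonals; the similarity index (SI) of a diagonal is its
best windowed percent score.  ``compare_short_to_long`` quantifies which
long-protein domain a short protein resembles more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord

__all__ = [
    "Diagonal",
    "DotplotResult",
    "dotplot",
    "compare_short_to_long",
]


@dataclass
class Diagonal:
    """One above-stringency run along a dotplot diagonal.

    ``offset`` is position-in-b minus position-in-a; ``start`` is the run's
    first residue in a; ``length`` counts residues covered (window span of
    the first window through the last).
    """

    offset: int
    start: int
    length: int
    max_si: float


@dataclass
class DotplotResult:
    window: int
    stringency: float
    scoring: str
    diagonals: list[Diagonal] = field(default_factory=list)

    @property
    def max_si(self) -> float:
        return max((d.max_si for d in self.diagonals), default=0.0)

    def best(self) -> Diagonal | None:
        return max(self.diagonals, key=lambda d: (d.max_si, d.length), default=None)


def _window_scores(a: str, b: str, window: int, positive) -> np.ndarray:
    """Percent score of every window along one diagonal pairing a[i+k], b[j+k]."""
    n = min(len(a), len(b))
    hits = np.fromiter(
        (positive(a[k], b[k]) for k in range(n)), dtype=float, count=n
    )
    if n < window:
        return np.empty(0)
    kernel = np.ones(window)
    sums = np.convolve(hits, kernel, mode="valid")
    return 100.0 * sums / window


def dotplot(
    a: SequenceRecord,
    b: SequenceRecord,
    window: int = 16,
    stringency: float = 40.0,
    scoring: str = "identity",
    min_diag_len: int | None = None,
) -> DotplotResult:
    """Sliding-window dotplot of two protein sequences.

    For every diagonal offset the percent score (identity, or BLOSUM62
    positives with ``scoring="similarity"``) of each ``window``-residue
    window is computed; maximal runs of windows at or above
    ``stringency`` are reported with their run length (in residues) and
    best windowed score (the similarity index, SI).
    """
    for rec in (a, b):
        if rec.moltype != "protein":
            raise ValueError(f"{rec.id}: dotplot expects protein sequences")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > min(len(a.residues), len(b.residues)):
        raise ValueError("window longer than the shorter sequence")
    if scoring == "identity":
        positive = lambda x, y: x == y
    elif scoring == "similarity":
        blosum = substitution_matrices.load("BLOSUM62")
        positive = lambda x, y: blosum[x, y] > 0
    else:
        raise ValueError("scoring must be 'identity' or 'similarity'")
    min_diag_len = min_diag_len if min_diag_len is not None else window
    sa, sb = a.upper, b.upper
    result = DotplotResult(window=window, stringency=stringency, scoring=scoring)
    for offset in range(-(len(sa) - 1), len(sb)):
        ai = max(0, -offset)
        bi = ai + offset
        scores = _window_scores(sa[ai:], sb[bi:], window, positive)
        if scores.size == 0:
            continue
        above = scores >= stringency
        k = 0
        while k < above.size:
            if not above[k]:
                k += 1
                continue
            j = k
            while j < above.size and above[j]:
                j += 1
            length = (j - 1 - k) + window
            if length >= min_diag_len:
                result.diagonals.append(
                    Diagonal(
                        offset=offset,
                        start=ai + k,
                        length=length,
                        max_si=float(scores[k:j].max()),
                    )
                )
            k = j
    return result


def _global_identity_pct(a: str, b: str) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a.upper(), b.upper())[0]
    r0, r1 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(r0, r1))
    return 100.0 * matches / len(r0)


def compare_short_to_long(
    short_mature: SequenceRecord,
    long_mature: SequenceRecord,
    domain_boundary: int | None = None,
    window: int = 16,
    stringency: float = 40.0,
    scoring: str = "identity",
) -> dict:
    """Compare a short sPCP against each domain of a long sPCP.

    ``domain_boundary`` splits the long mature peptide into N- and
    C-terminal domains (default: midpoint, the pseudo-axis of symmetry).
    Returns per-domain best-diagonal SI and length plus the full-length
    global percent identity of short vs long.
    """
    n = len(long_mature.residues)
    boundary = domain_boundary if domain_boundary is not None else n // 2
    if not (0 < boundary < n):
        raise ValueError(f"domain boundary {boundary} outside 1..{n - 1}")
    n_dom = SequenceRecord(
        long_mature.id + "_N", long_mature.residues[:boundary], moltype="protein"
    )
    c_dom = SequenceRecord(
        long_mature.id + "_C", long_mature.residues[boundary:], moltype="protein"
    )
    out = {}
    for name, dom in (("N_domain", n_dom), ("C_domain", c_dom)):
        dp = dotplot(short_mature, dom, window=window, stringency=stringency,
                     scoring=scoring)
        best = dp.best()
        out[name] = {
            "max_si": best.max_si if best else 0.0,
            "length": best.length if best else 0,
        }
    out["full_length_identity_pct"] = _global_identity_pct(
        short_mature.residues, long_mature.residues
    )
    return out
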