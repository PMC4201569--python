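"""Pairwise nucleotide distances, dN/dS and a chimera screen.

Closed-form distances under p, F81, K80 and gamma-corrected K80, a
maximum-likelihood HKY85 pairwise distance, matrix averages, percent
similarity over mutually ungapped columns, Nei-Gojobori (1986) counting
of synonymous and nonsynonymous sites and substitutions with
Jukes-Cantor correction, and a simplified breakpoint screen for PCR
chimeras (nearest-parent comparison of 5' and 3' fragments).

All pairwise statistics exclude columns where either sequence has a gap
or an ambiguous base (pairwise deletion, not listwise).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "DistanceResult",
    "DnDsResult",
    "SaturatedDistance",
    "pairwise_distance",
    "average_distance",
    "percent_similarity",
    "global_percent_similarity",
    "nei_gojobori_dnds",
    "chimera_screen",
]

_MODELS = ("p", "F81", "K80", "HKY85", "K80G")
_BASES = "ACGT"
_PURINES = {"A", "G"}

_CODON_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


class SaturatedDistance(ValueError):
    """Raised when a correction formula leaves its domain (saturation)."""


def _comparable(a: str, b: str) -> tuple[str, str]:
    """Strip columns where either sequence is gapped or ambiguous."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    xs, ys = [], []
    for x, y in zip(a.upper(), b.upper()):
        if x in _BASES and y in _BASES:
            xs.append(x)
            ys.append(y)
    return "".join(xs), "".join(ys)


def _pq(a: str, b: str) -> tuple[float, float, int]:
    """Transition (P) and transversion (Q) proportions."""
    n = len(a)
    if n == 0:
        raise ValueError("no comparable columns")
    ts = tv = 0
    for x, y in zip(a, b):
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return ts / n, tv / n, n


def _k80(P: float, Q: float) -> float:
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDistance("K80 correction undefined (saturated pair)")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _k80_gamma(P: float, Q: float, alpha: float) -> float:
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDistance("K80+G correction undefined (saturated pair)")
    return (alpha / 2) * (w1 ** (-1 / alpha) - 1) + (alpha / 4) * (
        w2 ** (-1 / alpha) - 1
    )


def _f81(p: float, freqs: dict[str, float]) -> float:
    B = 1 - sum(f * f for f in freqs.values())
    if B <= 0 or p >= B:
        raise SaturatedDistance("F81 correction undefined (saturated pair)")
    return -B * math.log(1 - p / B)


def _empirical_freqs(a: str, b: str) -> dict[str, float]:
    counts = {base: 1e-9 for base in _BASES}  # tiny pseudocount guards /0
    for c in a + b:
        counts[c] += 1
    total = sum(counts.values())
    return {base: counts[base] / total for base in _BASES}


def _hky_transition_matrix(t: float, kappa: float, freqs: dict[str, float]):
    """Closed-form HKY85 P(t), rows/cols ordered A, C, G, T."""
    pi = np.array([freqs[b] for b in _BASES])
    piY = pi[1] + pi[3]
    piR = pi[0] + pi[2]
    # normalization so branch length is expected substitutions per site
    beta = 1.0 / (
        2 * piR * piY + 2 * kappa * (pi[0] * pi[2] + pi[1] * pi[3])
    )
    e1 = math.exp(-beta * t)
    P = np.empty((4, 4))
    for i, x in enumerate(_BASES):
        for j, y in enumerate(_BASES):
            group = piR if y in _PURINES else piY
            e2 = math.exp(-beta * t * (1 + group * (kappa - 1)))
            same_group = (x in _PURINES) == (y in _PURINES)
            if i == j:
                P[i, j] = (
                    pi[j]
                    + pi[j] * (1 / group - 1) * e1
                    + ((group - pi[j]) / group) * e2
                )
            elif same_group:
                P[i, j] = (
                    pi[j]
                    + pi[j] * (1 / group - 1) * e1
                    - (pi[j] / group) * e2
                )
            else:
                P[i, j] = pi[j] * (1 - e1)
    return P


def _hky_distance(a: str, b: str, kappa: float | None = None) -> float:
    """ML branch length under HKY85 for one pair (kappa profiled if None)."""
    idx = {c: i for i, c in enumerate(_BASES)}
    counts = np.zeros((4, 4))
    for x, y in zip(a, b):
        counts[idx[x], idx[y]] += 1
    freqs = _empirical_freqs(a, b)
    pi = np.array([freqs[c] for c in _BASES])

    def negll(params) -> float:
        t = params[0]
        k = params[1] if kappa is None else kappa
        if t <= 0 or k <= 0:
            return 1e12
        P = _hky_transition_matrix(t, k, freqs)
        with np.errstate(divide="ignore"):
            lp = np.log(np.clip(pi[:, None] * P, 1e-300, None))
        return -float((counts * lp).sum())

    x0 = [0.1] if kappa is not None else [0.1, 2.0]
    bounds = [(1e-9, 50.0)] if kappa is not None else [(1e-9, 50.0), (0.02, 200.0)]
    res = optimize.minimize(
        negll, x0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-12, "gtol": 1e-10},
    )
    return float(res.x[0])


def pairwise_distance(
    a: str,
    b: str,
    model: str = "K80",
    alpha: float | None = None,
    kappa: float | None = None,
) -> float:
    """Distance between two aligned sequences under one substitution model.

    ``model`` is one of ``p`` (raw mismatch proportion), ``F81``, ``K80``,
    ``K80G`` (gamma-rate-corrected K80; requires ``alpha``) or ``HKY85``
    (numerical ML over branch length with ``kappa`` profiled unless
    supplied).  Saturated pairs raise :class:`SaturatedDistance`.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {_MODELS}")
    a, b = _comparable(a, b)
    P, Q, n = _pq(a, b)
    p = P + Q
    if model == "p":
        return p
    if model == "K80":
        return _k80(P, Q)
    if model == "K80G":
        if alpha is None:
            raise ValueError("K80G requires the gamma shape alpha")
        return _k80_gamma(P, Q, alpha)
    if model == "F81":
        return _f81(p, _empirical_freqs(a, b))
    return _hky_distance(a, b, kappa=kappa)


@dataclass
class DistanceResult:
    """Symmetric distance matrix plus its upper-triangle average."""

    model: str
    labels: list[str]
    matrix: np.ndarray
    average: float
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def average_distance(
    records,
    model: str = "K80",
    alpha: float | None = None,
    kappa: float | None = None,
) -> DistanceResult:
    """Full pairwise matrix and mean over the upper triangle."""
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    n = len(records)
    mat = np.zeros((n, n))
    undefined: list[tuple[str, str]] = []
    values = []
    for i, j in itertools.combinations(range(n), 2):
        try:
            d = pairwise_distance(
                records[i].residues, records[j].residues,
                model=model, alpha=alpha, kappa=kappa,
            )
        except SaturatedDistance:
            d = math.nan
            undefined.append((records[i].id, records[j].id))
        mat[i, j] = mat[j, i] = d
        if not math.isnan(d):
            values.append(d)
    avg = float(np.mean(values)) if values and not undefined else math.nan
    return DistanceResult(
        model=model,
        labels=[r.id for r in records],
        matrix=mat,
        average=avg,
        undefined_pairs=undefined,
    )


def percent_similarity(a: str, b: str) -> float:
    """100 x matches / columns where neither sequence has a gap."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    matches = comparable = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x == y:
            matches += 1
    if comparable == 0:
        raise ValueError("no comparable (mutually ungapped) columns")
    return 100.0 * matches / comparable


def global_percent_similarity(a: str, b: str) -> float:
    """Percent similarity of two unaligned sequences (global alignment
    with affine gaps, then :func:`percent_similarity` on the rows)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a.upper(), b.upper())[0]
    return percent_similarity(str(aln[0]), str(aln[1]))


# ---------------------------------------------------------------------------
# Nei-Gojobori dN/dS


def _codon_site_counts(codon: str) -> float:
    """Expected synonymous sites in one codon (changes to stops count as
    nonsynonymous)."""
    aa = _CODON_AA.get(codon)
    if aa is None:
        raise ValueError(f"stop or invalid codon {codon!r} in frame")
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_AA.get(alt) == aa:
                syn += 1
    return syn / 3.0


def _codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous changes over shortest mutation
    paths between two codons (paths through stop codons discarded unless
    none survive)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        syn = non = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
            if _CODON_AA.get(cur) is not None and _CODON_AA.get(nxt) is not None:
                if _CODON_AA[cur] == _CODON_AA[nxt]:
                    syn += 1
                else:
                    non += 1
            else:
                non += 1
            cur = nxt
        paths.append((through_stop, syn, non))
    valid = [(s, n) for stop, s, n in paths if not stop]
    if not valid:
        valid = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


@dataclass
class DnDsResult:
    """Nei-Gojobori site and substitution counts for one CDS pair."""

    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None

    @property
    def ratio(self) -> float | None:
        if self.dN == 0 and self.Sd > 0:
            return 0.0  # no nonsynonymous change at all: ratio is 0
        if self.dS is None or self.dN is None or self.dS == 0:
            return None
        return self.dN / self.dS


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


def nei_gojobori_dnds(a: str, b: str) -> DnDsResult:
    """Nei-Gojobori (1986) pathway-counting dN/dS for one aligned CDS pair.

    Codons containing a gap or ambiguity in either sequence are skipped;
    remaining length must stay in frame.  ``dS``/``dN`` are Jukes-Cantor
    corrected; they are ``None`` when the raw proportion reaches the 0.75
    ceiling, and ``ratio`` is ``None`` when ``dS`` is 0 or undefined.
    """
    if len(a) != len(b):
        raise ValueError("CDS pair must be aligned to equal length")
    if len(a) % 3:
        raise ValueError("aligned CDS length not a multiple of 3")
    a = a.upper()
    b = b.upper()
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(c not in _BASES for c in ca + cb):
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        sa = _codon_site_counts(ca)
        sb = _codon_site_counts(cb)
        S += (sa + sb) / 2
        N += 3 - (sa + sb) / 2
        sd, nd = _codon_path_counts(ca, cb)
        Sd += sd
        Nd += nd
    if S == 0 or N == 0:
        raise ValueError("no comparable codons")
    pS, pN = Sd / S, Nd / N
    return DnDsResult(
        S_sites=S, N_sites=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        dS=_jc_correct(pS), dN=_jc_correct(pN),
    )


# ---------------------------------------------------------------------------
# Chimera screen


@dataclass
class ChimeraCall:
    clone: str
    chimeric: bool
    breakpoint: int | None = None
    parents: tuple[str, str] | None = None
    improvement: float = 0.0


def _p_distance(a: str, b: str) -> float:
    a, b = _comparable(a, b)
    if not a:
        return math.nan
    return sum(x != y for x, y in zip(a, b)) / len(a)


def chimera_screen(
    clones,
    references,
    breakpoints: list[int] | None = None,
    threshold: float = 0.04,
    min_fragment_len: int = 50,
) -> list[ChimeraCall]:
    """Flag clones whose 5' and 3' halves have different nearest parents.

    For every candidate breakpoint the nearest reference (p-distance) of
    each fragment is found; a clone is called chimeric when some
    breakpoint gives the two fragments different nearest parents *and*
    the two-parent model beats the best single parent's summed fragment
    distance by at least ``threshold``.  A simplified stand-in for
    partial-tree chimera detectors used on tandem-array amplicon clones.
    """
    references = list(references)
    if len(references) < 2:
        raise ValueError("need at least two reference sequences")
    out = []
    for clone in clones:
        L = len(clone.residues)
        bps = breakpoints or list(range(min_fragment_len, L - min_fragment_len + 1,
                                        max(1, L // 40)))
        best_call = ChimeraCall(clone=clone.id, chimeric=False)
        for bp in bps:
            if bp < min_fragment_len or L - bp < min_fragment_len:
                continue
            d5 = {r.id: _p_distance(clone.residues[:bp], r.residues[:bp])
                  for r in references}
            d3 = {r.id: _p_distance(clone.residues[bp:], r.residues[bp:])
                  for r in references}
            p5 = min(d5, key=lambda k: (d5[k], k))
            p3 = min(d3, key=lambda k: (d3[k], k))
            if p5 == p3:
                continue
            two_parent = d5[p5] + d3[p3]
            single = min(d5[r.id] + d3[r.id] for r in references)
            gain = single - two_parent
            if gain >= threshold and gain > best_call.improvement:
                best_call = ChimeraCall(
                    clone=clone.id, chimeric=True, breakpoint=bp,
                    parents=(p5, p3), improvement=gain,
                )
        out.append(best_call)
    return out
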