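"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration and
textbook dynamic programming — and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools


def all_rooted_binary_trees(taxa: list[str]):
    """Every rooted binary topology over the given taxa, as nested tuples."""
    if len(taxa) == 1:
        yield taxa[0]
        return
    first, rest = taxa[0], taxa[1:]
    for k in range(1, len(rest) + 1):
        for combo in itertools.combinations(rest, k - 1):
            left_taxa = [first, *combo]
            right_taxa = [t for t in rest if t not in combo]
            if not right_taxa:
                continue
            for left in all_rooted_binary_trees(left_taxa):
                for right in all_rooted_binary_trees(right_taxa):
                    yield (left, right)


def brute_force_parsimony(topology, states: dict[str, str]) -> int:
    """Minimum changes by exhaustive internal-state assignment.

    '?' tips are free to take any observed state.
    """
    observed = sorted({s for s in states.values() if s != "?"})
    if not observed:
        return 0

    internal = []

    def collect(node):
        if isinstance(node, tuple):
            internal.append(node)
            for child in node:
                collect(child)

    collect(topology)
    free_tips = [t for t, s in states.items() if s == "?"]

    best = float("inf")
    for internal_assign in itertools.product(observed, repeat=len(internal)):
        lookup = dict(zip(map(id, internal), internal_assign))
        for tip_assign in itertools.product(observed, repeat=len(free_tips)):
            tip_lookup = dict(zip(free_tips, tip_assign))

            def state_of(node):
                if isinstance(node, tuple):
                    return lookup[id(node)]
                return tip_lookup.get(node, states[node])

            changes = 0

            def walk(node):
                nonlocal changes
                if not isinstance(node, tuple):
                    return
                for child in node:
                    if state_of(child) != state_of(node):
                        changes += 1
                    walk(child)

            walk(topology)
            best = min(best, changes)
    return int(best)


def topology_to_newick(topology) -> str:
    def render(node):
        if isinstance(node, tuple):
            return "(" + ",".join(render(c) for c in node) + ")"
        return node

    return render(topology) + ";"


def gotoh_global(a: str, b: str, match=2.0, mismatch=-3.0,
                 gap_open=-10.0, gap_extend=-0.2,
                 free_a_end_gaps=False) -> float:
    """Affine-gap global alignment score (Gotoh), optionally with free
    end gaps on sequence `a`."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a-only)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b-only)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0 if free_a_end_gaps else gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    finals = [M[n][m], Y[n][m]]
    if free_a_end_gaps:
        finals.append(max(max(M[i][m], Y[i][m]) for i in range(n + 1)))
    else:
        finals.append(X[n][m])
    return max(finals)


def valid_insertion_placements(genomic: str, cdna: str, length: int):
    """All (start, end) spans whose excision turns `genomic` into `cdna`."""
    g, c = genomic.upper(), cdna.upper()
    out = []
    for s in range(0, len(g) - length + 1):
        if g[:s] + g[s + length:] == c:
            out.append((s, s + length))
    return out
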