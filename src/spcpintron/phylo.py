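"""Parsimony machinery and intron gain/loss accounting.

Implements Fitch parsimony on discrete characters (gaps treated as
missing), Simmons–Ochoterena simple indel coding, a heuristic most-
parsimonious tree search (random-order stepwise addition followed by NNI
hill climbing), nonparametric bootstrap support, and the gain-versus-loss
event accounting used to date intron acquisitions: given a rooted species
tree and an intron presence/absence matrix, how many gains does the data
require, and how many losses would be needed instead if the introns were
ancestral?

Loss accounting comes in two flavours.  ``forced_presence_single_losses``
counts, for each intron separately, the minimum number of branches on
which that intron must be lost when the root is constrained to carry it
and re-gain is forbidden (Dollo-style).  ``forced_presence_event_losses``
lets one event on a branch delete any subset of the introns still present
there, so co-resident introns can be lost together; it is computed exactly
by dynamic programming over presence subsets (practical for <= ~8 introns).
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "Node",
    "Tree",
    "CharacterMatrix",
    "GainLossResult",
    "fitch_score",
    "simple_indel_coding",
    "mp_search",
    "bootstrap_support",
    "gain_loss_accounting",
]

MISSING = "?"


class Node:
    """One tree node; leaves carry labels, edges carry optional lengths."""

    __slots__ = ("label", "children", "length", "support")

    def __init__(self, label=None, children=None, length=None, support=None):
        self.label = label
        self.children = children if children is not None else []
        self.length = length
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "Node":
        return Node(
            self.label,
            [c.copy() for c in self.children],
            self.length,
            self.support,
        )


class Tree:
    """Phylogenetic tree with unique tip labels.

    A tree whose root has exactly two children is treated as rooted; a
    basal polytomy is treated as unrooted.  Parsimony scores do not depend
    on root placement, but gain/loss accounting requires a rooted tree.
    """

    def __init__(self, root: Node):
        self.root = root
        labels = self.tip_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels in tree")

    # -- construction / serialization -------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )

        def conv(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label is not None:
                label = dnode.label
            n = Node(label=label, length=dnode.edge.length)
            n.children = [conv(c) for c in dnode.child_nodes()]
            return n

        return cls(conv(dt.seed_node))

    def to_newick(self, lengths: bool = True) -> str:
        def render(n: Node) -> str:
            if n.is_leaf:
                s = n.label or ""
            else:
                s = "(" + ",".join(render(c) for c in n.children) + ")"
                if n.label:
                    s += n.label
            if lengths and n.length is not None:
                s += f":{n.length:g}"
            return s

        return render(self.root) + ";"

    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    # -- queries -----------------------------------------------------------

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    @property
    def n_tips(self) -> int:
        return len(self.root.leaves())

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the smaller-or-canonical tip set."""
        all_tips = frozenset(self.tip_labels())
        splits: set[frozenset[str]] = set()
        for n in self.root.postorder():
            if n is self.root or n.is_leaf:
                continue
            side = frozenset(leaf.label for leaf in n.leaves())
            other = all_tips - side
            if len(side) < 2 or len(other) < 2:
                continue
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return splits

    def canonical_topology(self) -> frozenset[frozenset[str]]:
        """Root-invariant topology fingerprint (the set of splits)."""
        return frozenset(self.bipartitions())

    # -- rooting -----------------------------------------------------------

    def root_on_outgroup(self, outgroup: set[str] | list[str] | str) -> "Tree":
        """Return a rooted copy with the root on the outgroup's pendant edge."""
        if isinstance(outgroup, str):
            outgroup = {outgroup}
        outgroup = set(outgroup)
        tips = set(self.tip_labels())
        missing = outgroup - tips
        if missing:
            raise ValueError(f"outgroup taxa not on tree: {sorted(missing)}")

        # Work on an unrooted view: collapse a two-child root first.
        tree = self.copy()
        root = tree.root
        if len(root.children) == 2:
            a, b = root.children
            keep, merge = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:  # two-tip tree, already as rooted as it gets
                return tree
            keep.children.append(merge)
            root = keep
            root.length = None

        # Find the edge whose child-side tip set equals the outgroup (or its
        # complement); re-root there.
        target = None
        parent_map: dict[Node, Node | None] = {root: None}
        for n in root.postorder():
            for c in n.children:
                parent_map[c] = n
        for n in root.postorder():
            if n is root:
                continue
            side = {leaf.label for leaf in n.leaves()}
            if side == outgroup or (tips - side) == outgroup:
                target = n if side == outgroup else n
                break
        if target is None:
            raise ValueError("outgroup is not a clade on any edge of this tree")

        # Reverse parent pointers from target up to old root.
        path = []
        n = target
        while n is not None:
            path.append(n)
            n = parent_map[n]
        for child, parent in zip(path, path[1:]):
            parent.children.remove(child)
        for child, parent in zip(path, path[1:]):
            child.children.append(parent)
        # target now holds its old subtree plus the rest of the tree hung off
        # it; split its incoming edge with a new root node.
        rest = target.children.pop()  # the reversed parent chain
        half = (target.length or 0.0) / 2 or None
        new_root = Node(children=[target, rest])
        target.length = half
        rest.length = half if rest.length is None else rest.length
        return Tree(new_root)


@dataclass
class CharacterMatrix:
    """Taxon x character state matrix; '?' marks missing data.

    States are single-character tokens.  For intron presence/absence use
    '0' (absent) and '1' (present).
    """

    taxa: list[str]
    characters: list[str]
    states: dict[str, list[str]]  # taxon -> per-character states
    weights: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in matrix")
        for t in self.taxa:
            if t not in self.states:
                raise ValueError(f"no states for taxon {t}")
            if len(self.states[t]) != len(self.characters):
                raise ValueError(f"state row for {t} has wrong length")
        if not self.weights:
            self.weights = [1] * len(self.characters)

    @classmethod
    def from_alignment(cls, records, code_indels: bool = True) -> "CharacterMatrix":
        """Build a matrix from aligned sequences.

        Each column becomes one character with gaps scored missing; indel
        presence/absence characters from simple gap coding are appended.
        """
        taxa = [r.id for r in records]
        length = len(records[0].residues)
        if any(len(r.residues) != length for r in records):
            raise ValueError("alignment rows differ in length")
        chars = [f"c{i}" for i in range(length)]
        states = {
            r.id: [
                (MISSING if c == "-" else c)
                for c in r.residues.upper()
            ]
            for r in records
        }
        m = cls(taxa, chars, states)
        if code_indels:
            indels = simple_indel_coding(records)
            m = m.concat(indels)
        return m

    def concat(self, other: "CharacterMatrix") -> "CharacterMatrix":
        if set(other.taxa) != set(self.taxa):
            raise ValueError("matrices cover different taxa")
        chars = self.characters + other.characters
        states = {
            t: self.states[t] + other.states[t] for t in self.taxa
        }
        return CharacterMatrix(self.taxa, chars, states,
                               self.weights + other.weights)

    def column(self, i: int) -> dict[str, str]:
        return {t: self.states[t][i] for t in self.taxa}

    def compress(self) -> "CharacterMatrix":
        """Collapse identical columns into weighted site patterns."""
        seen: dict[tuple, int] = {}
        order: list[tuple] = []
        weights: list[int] = []
        for i in range(len(self.characters)):
            pat = tuple(self.states[t][i] for t in self.taxa)
            if pat in seen:
                weights[seen[pat]] += self.weights[i]
            else:
                seen[pat] = len(order)
                order.append(pat)
                weights.append(self.weights[i])
        chars = [f"p{i}" for i in range(len(order))]
        states = {
            t: [pat[j] for pat in order] for j, t in enumerate(self.taxa)
        }
        return CharacterMatrix(self.taxa, chars, states, weights)

    def resample_columns(self, rng: random.Random) -> "CharacterMatrix":
        n = len(self.characters)
        idx = [rng.randrange(n) for _ in range(n)]
        chars = [f"b{i}" for i in range(n)]
        states = {t: [self.states[t][i] for i in idx] for t in self.taxa}
        return CharacterMatrix(self.taxa, chars, states,
                               [self.weights[i] for i in idx])


# ---------------------------------------------------------------------------
# Fitch parsimony


def fitch_score(tree: Tree, column: dict[str, str]) -> int:
    """Minimum number of state changes for one character (Fitch two-pass).

    '?' (missing) and '-' states are compatible with every observed state
    and contribute no changes.
    """
    observed = {s for s in column.values() if s not in (MISSING, "-")}
    if not observed:
        return 0
    full = frozenset(observed)

    changes = 0

    def down(n: Node) -> frozenset:
        nonlocal changes
        if n.is_leaf:
            if n.label not in column:
                raise KeyError(f"tip {n.label!r} absent from character column")
            s = column[n.label]
            return full if s in (MISSING, "-") else frozenset((s,))
        sets = [down(c) for c in n.children]
        acc = sets[0]
        for s in sets[1:]:
            inter = acc & s
            if inter:
                acc = inter
            else:
                acc = acc | s
                changes += 1
        return acc

    down(tree.root)
    return changes


def matrix_score(tree: Tree, matrix: CharacterMatrix) -> int:
    return sum(
        w * fitch_score(tree, matrix.column(i))
        for i, w in enumerate(matrix.weights)
    )


# ---------------------------------------------------------------------------
# Simple indel coding


def simple_indel_coding(records) -> CharacterMatrix:
    """Code alignment gaps as binary presence/absence characters.

    Every distinct gap (identical start and end) becomes one character
    scored 1 for taxa bearing exactly that gap and 0 for taxa with
    residues across the region; a taxon whose own gap strictly contains
    the character's gap is scored '?' (its state is unknowable).
    """

    def gaps_of(seq: str) -> list[tuple[int, int]]:
        out = []
        start = None
        for i, c in enumerate(seq + "x"):
            if c == "-":
                if start is None:
                    start = i
            elif start is not None:
                out.append((start, i))
                start = None
        return out

    per_taxon = {r.id: gaps_of(r.residues) for r in records}
    distinct = sorted({g for gs in per_taxon.values() for g in gs})
    taxa = [r.id for r in records]
    chars = [f"indel_{s}_{e}" for s, e in distinct]
    states: dict[str, list[str]] = {t: [] for t in taxa}
    for s, e in distinct:
        for t in taxa:
            own = per_taxon[t]
            if (s, e) in own:
                states[t].append("1")
            elif any(gs <= s and e <= ge and (gs, ge) != (s, e) for gs, ge in own):
                states[t].append(MISSING)
            else:
                states[t].append("0")
    return CharacterMatrix(taxa, chars, states)


# ---------------------------------------------------------------------------
# Heuristic most-parsimonious tree search


def _attachment_edges(root: Node) -> list[Node]:
    """Every node except the root is the child end of an edge."""
    return [n for n in root.postorder() if n is not root]


def _attach(tree_root: Node, edge_child: Node, tip: Node) -> Node:
    """Insert `tip` on the edge above `edge_child`; returns new root."""

    def rebuild(n: Node) -> Node:
        if n is edge_child:
            return Node(children=[n, tip])
        if n.is_leaf:
            return n
        return Node(n.label, [rebuild(c) for c in n.children], n.length, n.support)

    # rebuild shares leaf Nodes; acceptable because search never mutates them
    return rebuild(tree_root)


def _nni_neighbors(tree: Tree) -> list[Tree]:
    """All trees one nearest-neighbour interchange away."""
    out = []
    root = tree.root
    parent_map: dict[Node, Node] = {}
    for n in root.postorder():
        for c in n.children:
            parent_map[c] = n
    for n in root.postorder():
        if n.is_leaf or n is root:
            continue
        parent = parent_map[n]
        siblings = [c for c in parent.children if c is not n]
        if len(n.children) != 2 or not siblings:
            continue
        a, b = n.children
        for swap_child, keep_child in ((a, b), (b, a)):
            for sib in siblings:
                new_root = _swap_subtrees(root, sib, swap_child)
                out.append(Tree(new_root))
    return out


def _swap_subtrees(root: Node, x: Node, y: Node) -> Node:
    def rebuild(n: Node) -> Node:
        if n is x:
            return y.copy()
        if n is y:
            return x.copy()
        if n.is_leaf:
            return Node(n.label, [], n.length, n.support)
        return Node(n.label, [rebuild(c) for c in n.children], n.length, n.support)

    return rebuild(root)


def mp_search(
    matrix: CharacterMatrix, n_replicates: int = 10, seed: int = 0
) -> tuple[list[Tree], int]:
    """Heuristic parsimony search: stepwise addition + NNI hill climbing.

    Runs ``n_replicates`` random-taxon-addition replicates, each polished
    by nearest-neighbour-interchange until no neighbour improves, and
    returns all distinct best topologies with the best score.  Output is
    deterministic for a given seed.
    """
    if len(matrix.taxa) < 4:
        raise ValueError("tree search needs at least 4 taxa")
    matrix = matrix.compress()
    rng = random.Random(seed)
    best_score = math.inf
    best: dict[frozenset, Tree] = {}

    for _ in range(n_replicates):
        order = list(matrix.taxa)
        rng.shuffle(order)
        root = Node(children=[Node(order[0]), Node(order[1])])
        for taxon in order[2:]:
            tip = Node(taxon)
            candidates = []
            for edge_child in _attachment_edges(root):
                cand = _attach(root, edge_child, tip)
                # score over the taxa placed so far only
                placed = {leaf.label for leaf in cand.leaves()}
                sc = sum(
                    w * fitch_score(Tree(cand), {
                        t: matrix.states[t][i] for t in placed
                    })
                    for i, w in enumerate(matrix.weights)
                )
                candidates.append((sc, cand))
            candidates.sort(key=lambda p: p[0])
            root = candidates[0][1]
        tree = Tree(root)
        score = matrix_score(tree, matrix)
        improved = True
        while improved:
            improved = False
            for nb in _nni_neighbors(tree):
                s = matrix_score(nb, matrix)
                if s < score:
                    tree, score = nb, s
                    improved = True
                    break
        if score < best_score:
            best_score = score
            best = {tree.canonical_topology(): tree}
        elif score == best_score:
            best.setdefault(tree.canonical_topology(), tree)

    return list(best.values()), int(best_score)


def bootstrap_support(
    matrix: CharacterMatrix,
    tree: Tree,
    n_boot: int = 100,
    seed: int = 0,
    n_replicates: int = 3,
) -> dict[frozenset[str], float]:
    """Bootstrap proportions (percent) for each internal edge of `tree`.

    Characters are resampled with replacement; each pseudo-replicate is
    analysed with :func:`mp_search` and a bipartition's support is the
    percentage of replicates whose best tree(s) contain it.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = random.Random(seed)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    for b in range(n_boot):
        resampled = matrix.resample_columns(rng)
        best, _ = mp_search(resampled, n_replicates=n_replicates,
                            seed=rng.randrange(2**31))
        found = set()
        for t in best:
            found |= t.bipartitions()
        for bp in target:
            if bp in found:
                counts[bp] += 1
    return {bp: 100.0 * c / n_boot for bp, c in counts.items()}


# ---------------------------------------------------------------------------
# Gain/loss accounting


@dataclass
class GainLossResult:
    """Event counts for intron history scenarios on one rooted tree.

    ``min_gains``: Fitch minimum changes summed over introns when both
    gains and losses are free — on trees where each intron is confined to
    one clade this is the number of independent gains.
    ``forced_presence_single_losses``: total per-intron losses needed if
    every intron was already present at the root and cannot be regained.
    ``forced_presence_event_losses``: branches carrying at least one loss
    event when co-resident introns may be dropped together in one event.
    """

    min_gains: int
    forced_presence_single_losses: int
    forced_presence_event_losses: int | None = None

    def __post_init__(self) -> None:
        if (
            self.forced_presence_event_losses is not None
            and self.forced_presence_event_losses > self.forced_presence_single_losses
        ):
            raise ValueError("event losses cannot exceed single losses")


def _forced_presence_losses(tree: Tree, column: dict[str, str]) -> int:
    """Min 1->0 edges with root fixed present and gains forbidden."""
    INF = math.inf

    def dp(n: Node) -> tuple[float, float]:
        # returns (cost if state 0 at node, cost if state 1 at node)
        if n.is_leaf:
            s = column[n.label]
            if s in (MISSING, "-"):
                return (0.0, 0.0)
            return (0.0, INF) if s == "0" else (INF, 0.0)
        c0 = c1 = 0.0
        for child in n.children:
            z, o = dp(child)
            c0 += z  # absent stays absent, no event counted below a loss
            c1 += min(o, 1 + z)  # keep, or lose on the child's edge
        return (c0, c1)

    _, cost1 = dp(tree.root)
    if math.isinf(cost1):
        raise ValueError("character cannot be explained without gains")
    return int(cost1)


def _forced_presence_event_losses(tree: Tree, matrix: CharacterMatrix) -> int:
    """Min branches with a loss event when one event may drop any subset.

    Exact DP over presence subsets; exponential in intron count, intended
    for the handful of introns a locus realistically carries (<= ~8).
    """
    k = len(matrix.characters)
    if k > 12:
        raise ValueError("subset DP limited to <= 12 characters")
    full = (1 << k) - 1
    INF = math.inf

    def subsets_of(s: int):
        sub = s
        while True:
            yield sub
            if sub == 0:
                break
            sub = (sub - 1) & s

    cache: dict[tuple[int, int], float] = {}
    node_ids: dict[int, Node] = {}

    def dp(n: Node, present: int) -> float:
        key = (id(n), present)
        if key in cache:
            return cache[key]
        if n.is_leaf:
            row = matrix.states[n.label]
            cost = 0.0
            for i in range(k):
                s = row[i]
                has = bool(present >> i & 1)
                if s == "1" and not has:
                    cost = INF
                    break
                if s == "0" and has:
                    cost = INF
                    break
            cache[key] = cost
            return cost
        node_ids[id(n)] = n
        total = 0.0
        for child in n.children:
            best = INF
            for sub in subsets_of(present):
                c = dp(child, sub)
                if math.isinf(c):
                    continue
                cost = c + (0 if sub == present else 1)
                if cost < best:
                    best = cost
            total += best
            if math.isinf(total):
                break
        cache[key] = total
        return total

    ans = dp(tree.root, full)
    if math.isinf(ans):
        raise ValueError("matrix cannot be explained without gains")
    return int(ans)


def gain_loss_accounting(
    tree: Tree, matrix: CharacterMatrix, co_loss: bool = True
) -> GainLossResult:
    """Compare intron-gain and ancestral-presence scenarios on a rooted tree.

    Raises for unrooted input: root first (e.g.
    ``tree.root_on_outgroup({...})``) so that "ancestral presence" is
    well defined.
    """
    if not tree.is_rooted:
        raise ValueError(
            "gain/loss accounting needs a rooted tree; use "
            "Tree.root_on_outgroup(...) to place the root"
        )
    tips = set(tree.tip_labels())
    missing = tips - set(matrix.taxa)
    if missing:
        raise ValueError(f"tree tips missing from matrix: {sorted(missing)}")

    min_gains = sum(
        fitch_score(tree, matrix.column(i)) for i in range(len(matrix.characters))
    )
    single = sum(
        _forced_presence_losses(tree, matrix.column(i))
        for i in range(len(matrix.characters))
    )
    events = _forced_presence_event_losses(tree, matrix) if co_loss else None
    return GainLossResult(
        min_gains=min_gains,
        forced_presence_single_losses=single,
        forced_presence_event_losses=events,
    )
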