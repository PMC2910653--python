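"""Irreversible-character parsimony on rooted trees.

Retroposon presence/absence characters are effectively irreversible: an
insertion can be gained once on a branch and is then inherited by all
descendants, while precise excision is rare enough to ignore.  Scoring
therefore uses gains-only (Camin-Sokal) parsimony: state changes 0 -> 1 are
charged one step on the edge where they occur, changes 1 -> 0 are forbidden,
and the root is fixed in state 0 (the all-absent outgroup attaches there).
Missing and deleted leaf states are free to take either state.

The tree search mirrors standard practice: replicated random-sequence
stepwise addition followed by branch swapping (TBR by default), collecting
every distinct binary topology that attains the best score.  Scoring is a
two-state dynamic program vectorised across characters, and branch swapping
evaluates all reconnections of a bisection from per-edge cost vectors rather
than rescoring whole trees.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .markers import MarkerMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "PhyloTree",
    "SearchConfig",
    "irreversible_parsimony_score",
    "character_scores",
    "consistency_index",
    "heuristic_search",
    "strict_consensus",
    "read_newick",
    "write_newick",
]

INF = np.int64(1) << 30


class Node:
    """A node of a rooted tree; leaves carry labels, edges optional lengths."""

    __slots__ = ("label", "children", "parent", "length")

    def __init__(
        self,
        label: str | None = None,
        children: Iterable["Node"] = (),
        length: float | None = None,
    ) -> None:
        self.label = label
        self.children: list[Node] = list(children)
        self.parent: Node | None = None
        self.length = length
        for c in self.children:
            c.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        self.children.append(child)
        child.parent = self
        return child

    def postorder(self) -> Iterable["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterable["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]


class PhyloTree:
    """A rooted tree with uniquely labeled leaves; polytomies allowed."""

    def __init__(self, root: Node) -> None:
        self.root = root
        labels = [l.label for l in root.leaves()]
        if any(l is None for l in labels):
            raise ValueError("every leaf must be labeled")
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        for n in root.postorder():
            if not n.is_leaf and len(n.children) < 2:
                raise ValueError("internal nodes must have at least 2 children")

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(l.label for l in self.root.leaves())

    def clades(self, include_trivial: bool = False) -> frozenset[frozenset[str]]:
        """Leaf-label sets of internal nodes (proper, non-root clades)."""
        below: dict[int, frozenset[str]] = {}
        for n in self.root.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.label])
            else:
                below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
        all_leaves = below[id(self.root)]
        out = set()
        for n in self.root.postorder():
            s = below[id(n)]
            if include_trivial or (1 < len(s) < len(all_leaves)):
                out.add(s)
        return frozenset(out)

    def canonical_key(self):
        """Order-independent topology fingerprint (labels only)."""

        def key(node: Node):
            if node.is_leaf:
                return str(node.label)
            return tuple(sorted((key(c) for c in node.children), key=repr))

        return key(self.root)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PhyloTree) and \
            self.canonical_key() == other.canonical_key()

    def __hash__(self) -> int:
        return hash(self.canonical_key())

    def __repr__(self) -> str:
        return f"PhyloTree({len(self.leaf_labels)} leaves)"


# ---------------------------------------------------------------------------
# Newick I/O (via dendropy)
# ---------------------------------------------------------------------------


def _from_dendropy(dnode) -> Node:
    node = Node(
        label=dnode.taxon.label if dnode.taxon else dnode.label,
        length=dnode.edge.length,
    )
    for child in dnode.child_nodes():
        node.add(_from_dendropy(child))
    return node


def read_newick(source: str | io.TextIOBase) -> PhyloTree:
    """Parse a Newick string or stream into a rooted :class:`PhyloTree`."""
    text = source.read() if hasattr(source, "read") else source
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    return PhyloTree(_from_dendropy(dtree.seed_node))


def write_newick(tree: PhyloTree) -> str:
    """Serialise a tree as Newick, preserving polytomies and edge lengths."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            base = node.label or ""
        else:
            base = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.length is not None:
            base += f":{node.length:g}"
        return base

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _leaf_costs(matrix: MarkerMatrix) -> dict[str, np.ndarray]:
    """Per-taxon (2, M) DP cost vectors; missing/deleted cost 0 in both states."""
    binary = matrix.to_binary()
    out: dict[str, np.ndarray] = {}
    for i, taxon in enumerate(matrix.taxa):
        c = np.zeros((2, matrix.n_markers), dtype=np.int64)
        c[0, binary[i] == 1] = INF
        c[1, binary[i] == 0] = INF
        out[taxon] = c
    return out


def _hang(down: np.ndarray) -> np.ndarray:
    """Cost of a subtree viewed from its parent: state 0 may gain (+1), a
    parent in state 1 forces the subtree root to state 1."""
    return np.stack([np.minimum(down[0], down[1] + 1), down[1]])


def _down_pass(root: Node, leaf_costs: dict[str, np.ndarray]) -> dict[int, np.ndarray]:
    down: dict[int, np.ndarray] = {}
    for node in root.postorder():
        if node.is_leaf:
            try:
                down[id(node)] = leaf_costs[node.label]
            except KeyError:
                raise ValueError(
                    f"tree leaf {node.label!r} absent from matrix"
                ) from None
        else:
            down[id(node)] = sum(_hang(down[id(c)]) for c in node.children)
    return down


def character_scores(tree: PhyloTree, matrix: MarkerMatrix) -> np.ndarray:
    """Minimum gains per character on the rooted tree (root forced absent)."""
    down = _down_pass(tree.root, _leaf_costs(matrix))
    return np.asarray(down[id(tree.root)][0])


def irreversible_parsimony_score(tree: PhyloTree, matrix: MarkerMatrix) -> int:
    """Total tree length in gains under irreversible-up parsimony."""
    return int(character_scores(tree, matrix).sum())


def min_conceivable_steps(matrix: MarkerMatrix) -> int:
    """Sum over variable characters of their minimum steps (1 per character
    with any scored presence, since a single gain can explain it)."""
    return int((matrix.to_binary() == 1).any(axis=0).sum())


def consistency_index(matrix: MarkerMatrix, tree_length: int) -> float:
    """CI = minimum conceivable steps / realised tree length (1 = no homoplasy)."""
    m = min_conceivable_steps(matrix)
    if tree_length == 0:
        if m > 0:
            raise ValueError("tree length 0 with variable characters")
        return 1.0
    return m / tree_length


# ---------------------------------------------------------------------------
# Heuristic search
# ---------------------------------------------------------------------------


@dataclass
class SearchConfig:
    """Settings for the replicated random-addition + branch-swapping search."""

    n_random_additions: int = 1000
    swap: str = "TBR"
    seed: int = 0
    keep_all_optimal: bool = True

    def __post_init__(self) -> None:
        if self.n_random_additions < 1:
            raise ValueError("need at least one addition replicate")
        if self.swap.upper() not in ("TBR", "SPR", "NNI"):
            raise ValueError(f"unknown swap mode {self.swap!r}")


def _copy_with_map(root: Node) -> tuple[Node, dict[int, Node]]:
    mapping: dict[int, Node] = {}

    def rec(n: Node) -> Node:
        c = Node(label=n.label, children=[rec(ch) for ch in n.children],
                 length=n.length)
        mapping[id(n)] = c
        return c

    return rec(root), mapping


def _context_pass(
    root: Node, down: dict[int, np.ndarray], n_chars: int
) -> dict[int, np.ndarray]:
    """For every non-root node c, the cost vector of the whole tree outside
    the edge (parent(c), c), indexed by the state of a junction node inserted
    on that edge.  The root is fixed in state 0."""
    C: dict[int, np.ndarray] = {}
    u_root = np.stack([
        np.zeros(n_chars, dtype=np.int64),
        np.full(n_chars, INF, dtype=np.int64),
    ])
    U: dict[int, np.ndarray] = {id(root): u_root}
    for node in root.preorder():
        if node.is_leaf:
            continue
        u = U[id(node)]
        hangs = [_hang(down[id(c)]) for c in node.children]
        total = sum(hangs)
        for c, h in zip(node.children, hangs):
            a = u + (total - h)
            vec = np.stack([a[0], np.minimum(a[0] + 1, a[1])])
            C[id(c)] = vec
            U[id(c)] = vec
    return C


def _splice_out(node: Node) -> None:
    """Remove a now-unary internal node, joining its child to its parent."""
    (child,) = node.children
    parent = node.parent
    assert parent is not None
    parent.children[parent.children.index(node)] = child
    child.parent = parent


def _subtree_hang_vectors(
    v: Node, down: dict[int, np.ndarray]
) -> list[tuple[object, np.ndarray]]:
    """All rerootings of the detached subtree ``v`` (TBR), as
    (descriptor, hang-vector) pairs.  Descriptors identify the rerooting edge
    for later materialisation: ('root',) keeps the original orientation,
    ('edge', x) reroots on the edge above node x."""
    if v.is_leaf:
        return [(("root",), _hang(down[id(v)]))]
    out: list[tuple[object, np.ndarray]] = []
    hang_child = {id(n): _hang(down[id(n)]) for n in v.postorder()}
    # original rooting: the unrooted edge between v's two children
    a, b = v.children
    out.append((("root",), _hang(hang_child[id(a)] + hang_child[id(b)])))
    # outward ("rest of subtree") vectors, rooted-edge flips
    rest: dict[int, np.ndarray] = {}
    for node in v.preorder():
        for c in node.children:
            sibs = sum(hang_child[id(w)] for w in node.children if w is not c)
            if node is v:
                rest[id(c)] = sibs
            else:
                d = sibs + rest[id(node)]
                rest[id(c)] = np.stack([np.minimum(d[0], d[1] + 1), d[1]])
            if c.parent is not v:
                out.append((("edge", c), _hang(hang_child[id(c)] + rest[id(c)])))
    return out


def _flip_up(node: Node, exclude: Node, v: Node) -> Node:
    """Rebuild the part of a detached subtree above ``node`` as a subtree
    hanging downward, suppressing the old root ``v``."""
    rest = [c for c in node.children if c is not exclude]
    if node is v:
        (only,) = rest
        return only
    return Node(children=rest + [_flip_up(node.parent, node, v)])


def _materialise(
    r_root: Node,
    attach_child: Node,
    s_root: Node,
    descriptor: object,
) -> PhyloTree:
    """Build the tree obtained by inserting the detached subtree (rerooted
    per ``descriptor``) on the edge above ``attach_child`` in R."""
    r_copy, r_map = _copy_with_map(r_root)
    s_copy, s_map = _copy_with_map(s_root)
    c = r_map[id(attach_child)]
    if descriptor[0] == "root":
        s_attach = s_copy
    else:
        x = s_map[id(descriptor[1])]
        s_attach = Node(children=[x, _flip_up(x.parent, x, s_copy)])
    p = c.parent
    m = Node(children=[c, s_attach])
    p.children[p.children.index(c)] = m
    m.parent = p
    return PhyloTree(r_copy)


def _edge_distance(c: Node, origin: Node | None, max_d: int) -> bool:
    """Whether edge above ``c`` lies within ``max_d`` nodes of ``origin``."""
    if origin is None:
        return True
    seen = {id(origin)}
    frontier = [origin]
    for _ in range(max_d):
        nxt = []
        for n in frontier:
            for nb in ([n.parent] if n.parent else []) + n.children:
                if id(nb) not in seen:
                    seen.add(id(nb))
                    nxt.append(nb)
        frontier = nxt
    return id(c) in seen


class _Searcher:
    """Shared state for one heuristic search run."""

    def __init__(self, matrix: MarkerMatrix, config: SearchConfig) -> None:
        if matrix.outgroup is None:
            raise ValueError("heuristic search requires matrix.outgroup to root the tree")
        if matrix.n_taxa < 4:
            raise ValueError("heuristic search needs at least 4 taxa")
        self.matrix = matrix
        self.config = config
        self.leaf_costs = _leaf_costs(matrix)
        self.n_chars = matrix.n_markers
        self.outgroup = matrix.outgroup
        self.ingroup = [t for t in matrix.taxa if t != matrix.outgroup]
        self.rng = np.random.default_rng(config.seed)
        self.swap = config.swap.upper()

    # -- scoring helpers ---------------------------------------------------

    def tree_score(self, root: Node) -> int:
        down = _down_pass(root, self.leaf_costs)
        return int(down[id(root)][0].sum())

    def _candidate_edges(self, root: Node) -> list[Node]:
        """Edges (as child nodes) where a subtree may be attached; the
        outgroup's pendant edge is excluded to keep the root placement."""
        return [
            n for n in root.postorder()
            if n.parent is not None and n.label != self.outgroup
        ]

    # -- stepwise addition -------------------------------------------------

    def random_addition_tree(self) -> Node:
        order = list(self.rng.permutation(self.ingroup))
        root = Node(children=[Node(label=self.outgroup), Node(label=order[0])])
        for taxon in order[1:]:
            down = _down_pass(root, self.leaf_costs)
            context = _context_pass(root, down, self.n_chars)
            g = _hang(self.leaf_costs[taxon])
            edges = self._candidate_edges(root)
            scores = np.empty(len(edges), dtype=np.int64)
            for i, c in enumerate(edges):
                tot = context[id(c)] + _hang(down[id(c)]) + g
                scores[i] = np.minimum(tot[0], tot[1]).sum()
            best = np.flatnonzero(scores == scores.min())
            choice = edges[int(self.rng.choice(best))]
            p = choice.parent
            m = Node(children=[choice, Node(label=taxon)])
            p.children[p.children.index(choice)] = m
            m.parent = p
        return root

    # -- branch swapping ---------------------------------------------------

    def _bisection_nodes(self, root: Node) -> list[Node]:
        return [
            n for n in root.postorder()
            if n.parent is not None and n.parent.parent is not None
        ]

    def sweep(
        self, root: Node, current: int, collect_equal: bool
    ) -> tuple[PhyloTree | None, list[PhyloTree]]:
        """One branch-swapping pass.  Returns (improved tree, equal-score
        trees found); an improvement aborts the pass immediately."""
        equal: list[PhyloTree] = []
        for v in self._bisection_nodes(root):
            r_root, r_map = _copy_with_map(root)
            v_r = r_map[id(v)]
            p = v_r.parent
            p.children.remove(v_r)
            _splice_out(p)
            down_r = _down_pass(r_root, self.leaf_costs)
            context = _context_pass(r_root, down_r, self.n_chars)
            down_s = _down_pass(v, self.leaf_costs)
            if self.swap == "TBR":
                rerootings = _subtree_hang_vectors(v, down_s)
            else:  # SPR and NNI keep the subtree's original orientation
                rerootings = [(("root",), _hang(down_s[id(v)]))]
            origin = r_map[id(v.parent)] if self.swap == "NNI" else None
            edges = [
                c for c in self._candidate_edges(r_root)
                if self.swap != "NNI" or _edge_distance(c, origin, 3)
            ]
            if not edges:
                continue
            cd = np.stack(
                [context[id(c)] + _hang(down_r[id(c)]) for c in edges]
            )  # (nR, 2, M)
            gv = np.stack([g for _, g in rerootings])  # (nS, 2, M)
            total = cd[:, None] + gv[None, :]
            scores = np.minimum(total[:, :, 0], total[:, :, 1]).sum(axis=2)
            best = int(scores.min())
            if best < current:
                i, j = np.unravel_index(int(scores.argmin()), scores.shape)
                return (
                    _materialise(r_root, edges[i], v, rerootings[j][0]),
                    equal,
                )
            if collect_equal and best == current:
                for i, j in zip(*np.nonzero(scores == current)):
                    equal.append(
                        _materialise(r_root, edges[i], v, rerootings[j][0])
                    )
        return None, equal

    def hill_climb(self, root: Node) -> tuple[Node, int, list[PhyloTree]]:
        score = self.tree_score(root)
        while True:
            improved, equal = self.sweep(
                root, score, collect_equal=self.config.keep_all_optimal
            )
            if improved is None:
                return root, score, equal
            root = improved.root
            score = self.tree_score(root)


def heuristic_search(
    matrix: MarkerMatrix, config: SearchConfig | None = None
) -> tuple[list[PhyloTree], int]:
    """Search tree space for minimum-length trees under irreversible parsimony.

    Each replicate builds a starting tree by stepwise addition in a random
    taxon order (every insertion point chosen to minimise length, ties broken
    uniformly) and then branch-swaps until no rearrangement improves the
    score.  All distinct binary topologies attaining the overall best score
    are returned, deduplicated by canonical form, together with that score.
    Fully reproducible for a fixed ``config.seed``.
    """
    config = config or SearchConfig()
    searcher = _Searcher(matrix, config)
    best_score: int | None = None
    optima: dict[object, PhyloTree] = {}
    for replicate in range(config.n_random_additions):
        root = searcher.random_addition_tree()
        root, score, equal = searcher.hill_climb(root)
        logger.debug("replicate %d: best length %d", replicate + 1, score)
        if best_score is None or score < best_score:
            best_score = score
            optima = {}
        if score == best_score:
            for tree in [PhyloTree(root)] + equal:
                optima.setdefault(tree.canonical_key(), tree)
    assert best_score is not None
    if config.keep_all_optimal:
        # Plateau closure: swap on every stored tree, adding equal-score
        # rearrangements (and restarting from any late improvement) until no
        # new topology appears, so the returned set is the full connected
        # plateau of co-optimal trees, not just the replicate endpoints.
        pending = list(optima.values())
        while pending:
            tree = pending.pop()
            improved, equal = searcher.sweep(tree.root, best_score, True)
            if improved is not None:
                improved_root, score, equal = searcher.hill_climb(improved.root)
                best_score = score
                optima = {}
                pending = []
                candidates = [PhyloTree(improved_root)] + equal
            else:
                candidates = equal
            for cand in candidates:
                key = cand.canonical_key()
                if key not in optima:
                    optima[key] = cand
                    pending.append(cand)
    trees = [optima[k] for k in sorted(optima, key=repr)]
    if not config.keep_all_optimal:
        trees = trees[:1]
    return trees, best_score


# ---------------------------------------------------------------------------
# Branch support / collapsing
# ---------------------------------------------------------------------------


def branch_length_bounds(
    tree: PhyloTree, matrix: MarkerMatrix
) -> dict[frozenset[str], tuple[int, int]]:
    """Minimum and maximum gains per internal branch over all optimal
    reconstructions, keyed by the branch's subtended clade.

    A branch whose maximum is 0 can never carry a gain; one whose minimum is
    0 need not carry one (its support rests on ambiguous placements only).
    """
    down = _down_pass(tree.root, _leaf_costs(matrix))
    char_best = down[id(tree.root)][0]
    n_chars = char_best.shape[0]
    U: dict[int, np.ndarray] = {
        id(tree.root): np.stack([
            np.zeros(n_chars, dtype=np.int64),
            np.full(n_chars, INF, dtype=np.int64),
        ])
    }
    A: dict[int, np.ndarray] = {}
    for node in tree.root.preorder():
        if node.is_leaf:
            continue
        u = U[id(node)]
        hangs = [_hang(down[id(c)]) for c in node.children]
        total = sum(hangs)
        for c, h in zip(node.children, hangs):
            a = u + (total - h)
            A[id(c)] = a
            U[id(c)] = np.stack([a[0], np.minimum(a[0] + 1, a[1])])
    below: dict[int, frozenset[str]] = {}
    for n in tree.root.postorder():
        below[id(n)] = (
            frozenset([n.label]) if n.is_leaf
            else frozenset().union(*(below[id(c)] for c in n.children))
        )
    out: dict[frozenset[str], tuple[int, int]] = {}
    for n in tree.root.postorder():
        if n.is_leaf or n.parent is None:
            continue
        a, d = A[id(n)], down[id(n)]
        gain_possible = (a[0] + 1 + d[1]) == char_best
        gain_avoidable = np.minimum(a[0] + d[0], a[1] + d[1]) == char_best
        out[below[id(n)]] = (
            int((~gain_avoidable).sum()),
            int(gain_possible.sum()),
        )
    return out


def collapse_zero_length_branches(
    tree: PhyloTree, matrix: MarkerMatrix, rule: str = "min"
) -> PhyloTree:
    """Collapse internal branches that carry no gains into polytomies.

    ``rule='min'`` collapses every branch that *can* have zero gains in some
    optimal reconstruction (conservative: only unambiguously supported
    branches survive); ``rule='max'`` collapses only branches that can never
    carry a gain.
    """
    if rule not in ("min", "max"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    bounds = branch_length_bounds(tree, matrix)
    root, _ = _copy_with_map(tree.root)
    below: dict[int, frozenset[str]] = {}
    doomed = []
    for n in root.postorder():
        below[id(n)] = (
            frozenset([n.label]) if n.is_leaf
            else frozenset().union(*(below[id(c)] for c in n.children))
        )
        if n.is_leaf or n.parent is None:
            continue
        lo, hi = bounds[below[id(n)]]
        if (rule == "min" and lo == 0) or (rule == "max" and hi == 0):
            doomed.append(n)
    for n in doomed:
        p = n.parent
        i = p.children.index(n)
        p.children[i: i + 1] = n.children
        for c in n.children:
            c.parent = p
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """The tree containing exactly the clades shared by all input trees."""
    if not trees:
        raise ValueError("need at least one tree")
    leaves = trees[0].leaf_labels
    for t in trees[1:]:
        if t.leaf_labels != leaves:
            raise ValueError("trees must share an identical leaf set")
    common = frozenset.intersection(*(t.clades() for t in trees))
    return build_from_clades(leaves, common)


def build_from_clades(
    leaves: Iterable[str], clades: Iterable[frozenset[str]]
) -> PhyloTree:
    """Assemble a rooted tree from a compatible set of proper clades."""
    leaves = frozenset(leaves)
    ordered = sorted(set(clades) | {leaves}, key=lambda s: (-len(s), sorted(s)))
    nodes = {s: Node() for s in ordered}
    for s in ordered[1:]:
        parent = min(
            (t for t in ordered if s < t), key=len, default=None
        )
        if parent is None:
            raise ValueError("incompatible clade set")
        nodes[parent].add(nodes[s])
    for leaf in leaves:
        parent = min((t for t in ordered if leaf in t), key=len)
        nodes[parent].add(Node(label=leaf))
    return PhyloTree(nodes[leaves])
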