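"""Responder phylogeny: distances, neighbor-joining, bootstrap, compression.

Representative sequences of discriminative OTUs (already aligned) are
turned into a pairwise distance matrix (p-distance or Jukes-Cantor), a
neighbor-joining tree, per-bipartition bootstrap supports from resampled
alignment columns, and finally a display tree in which tight clades are
compressed into single labelled nodes to keep large responder trees
readable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import skbio.io
from skbio import TreeNode

VALID_CHARS = set(b"ACGTN-")
MISSING = frozenset(b"N-")


class UndefinedDistanceError(ValueError):
    """JC69 distance undefined (mismatch fraction >= 3/4) or no shared
    ungapped sites for a pair."""


@dataclass
class AlignmentSet:
    """Aligned sequences over {A,C,G,T,-,N}, equal length, unique ids."""

    ids: list[str]
    matrix: np.ndarray = field(repr=False)  # (n_seqs, n_sites) of uint8 codes

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        m = np.asarray(self.matrix, dtype=np.uint8)
        if m.ndim != 2 or m.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match ids")
        bad = set(m.ravel().tobytes()) - {c for c in VALID_CHARS}
        if bad:
            raise ValueError(f"invalid alignment characters: {sorted(chr(b) for b in bad)}")
        self.matrix = m

    @classmethod
    def from_sequences(cls, ids, seqs) -> "AlignmentSet":
        seqs = [s.upper() for s in seqs]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        m = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
            len(seqs), -1
        )
        return cls(list(ids), m.copy())

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def resample_columns(self, rng: np.random.Generator) -> "AlignmentSet":
        idx = rng.integers(0, self.n_sites, size=self.n_sites)
        return AlignmentSet(list(self.ids), self.matrix[:, idx])


def read_alignment(path: str | Path) -> AlignmentSet:
    """Read an aligned FASTA file."""
    ids, seqs = [], []
    for seq in skbio.io.read(str(path), format="fasta"):
        ids.append(seq.metadata["id"])
        seqs.append(str(seq))
    if not ids:
        raise ValueError(f"no sequences in {path}")
    return AlignmentSet.from_sequences(ids, seqs)


# -- distances -----------------------------------------------------------------


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray = field(repr=False)

    def to_dict(self) -> dict[tuple[str, str], float]:
        return {
            (a, b): float(self.values[i, j])
            for i, a in enumerate(self.ids)
            for j, b in enumerate(self.ids)
        }


def pairwise_distance(a: AlignmentSet, model: str = "JC69") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap/N sites.

    ``p_distance``: mismatches / valid sites.  ``JC69``:
    d = -(3/4) ln(1 - 4p/3), undefined for p >= 3/4.
    """
    if model not in ("p_distance", "JC69"):
        raise ValueError("model must be 'p_distance' or 'JC69'")
    n = len(a.ids)
    m = a.matrix
    valid = ~np.isin(m, np.frombuffer(b"N-", dtype=np.uint8))
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            n_valid = int(both.sum())
            if n_valid == 0:
                raise UndefinedDistanceError(
                    f"no shared ungapped sites between {a.ids[i]!r} and {a.ids[j]!r}"
                )
            p = float(np.sum(m[i, both] != m[j, both])) / n_valid
            if model == "p_distance":
                d = p
            else:
                if p >= 0.75:
                    raise UndefinedDistanceError(
                        f"JC69 undefined for {a.ids[i]!r} vs {a.ids[j]!r} "
                        f"(mismatch fraction {p:.3f} >= 0.75)"
                    )
                d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            out[i, j] = out[j, i] = d
    return DistanceMatrix(list(a.ids), out)


# -- neighbor joining ----------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Ties in the Q-criterion are broken by the lexicographically smallest
    pair of cluster representatives (each cluster represented by its
    smallest leaf id); negative branch-length estimates are clamped to
    zero with a warning stating the clamped amount.  The returned tree is
    unrooted, represented with a trifurcating root when possible.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least two sequences")
    nodes: dict[str, TreeNode] = {i: TreeNode(name=i) for i in dm.ids}
    d = {
        frozenset((a, b)): float(dm.values[i, j])
        for i, a in enumerate(dm.ids)
        for j, b in enumerate(dm.ids)
        if i < j
    }
    active = sorted(dm.ids)
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        rowsum = {a: sum(d[frozenset((a, b))] for b in active if b != a) for a in active}
        best = None
        best_q = math.inf
        for i in range(r):
            for j in range(i + 1, r):
                a, b = active[i], active[j]
                q = (r - 2) * d[frozenset((a, b))] - rowsum[a] - rowsum[b]
                key = tuple(sorted((a, b)))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (best is None or key < best)
                ):
                    best_q = q
                    best = key
        a, b = best
        dab = d[frozenset((a, b))]
        la = 0.5 * dab + (rowsum[a] - rowsum[b]) / (2 * (r - 2))
        lb = dab - la
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length = clamp(la)
        nb.length = clamp(lb)
        new = TreeNode(children=[na, nb])
        rep = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((rep, c))] = 0.5 * (
                d[frozenset((a, c))] + d[frozenset((b, c))] - dab
            )
        active = sorted(set(active) - {a, b} | {rep})
        nodes[rep] = new

    if len(active) == 2:
        a, b = active
        dab = d[frozenset((a, b))]
        na, nb = nodes[a], nodes[b]
        na.length = clamp(dab / 2)
        nb.length = clamp(dab - na.length)
        root = TreeNode(children=[na, nb])
    else:
        a, b, c = active
        dab, dac, dbc = (
            d[frozenset((a, b))],
            d[frozenset((a, c))],
            d[frozenset((b, c))],
        )
        la = (dab + dac - dbc) / 2
        lb = (dab + dbc - dac) / 2
        lc = (dac + dbc - dab) / 2
        for name, ln in ((a, la), (b, lb), (c, lc)):
            nodes[name].length = clamp(ln)
        root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    if deficit > 0:
        warnings.warn(
            f"clamped negative branch lengths (total deficit {deficit:.4g})",
            stacklevel=2,
        )
    return root


def _bipartitions(tree: TreeNode, all_ids: frozenset) -> set[frozenset]:
    """Canonical non-trivial bipartitions (smaller side, ties by sorted
    tuple) of an unrooted tree."""
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_ids - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        parts.add(canon)
    return parts


def bootstrap_tree(
    a: AlignmentSet, n_boot: int = 100, seed: int = 0, model: str = "JC69"
) -> TreeNode:
    """NJ tree with bootstrap supports.

    Alignment columns are resampled with replacement ``n_boot`` times; each
    internal node of the full-data tree gets, as its name, the percent of
    replicate trees containing the same leaf bipartition.  Replicates in
    which a distance is undefined are discarded but keep their place in the
    denominator.
    """
    base = neighbor_joining(pairwise_distance(a, model))
    all_ids = frozenset(a.ids)
    counts: dict[frozenset, int] = {}
    node_keys = {}
    for node in base.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_ids - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        node_keys[id(node)] = canon
        counts[canon] = 0
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_boot):
            rep = a.resample_columns(rng)
            try:
                t = neighbor_joining(pairwise_distance(rep, model))
            except UndefinedDistanceError:
                continue
            parts = _bipartitions(t, all_ids)
            for key in counts:
                if key in parts:
                    counts[key] += 1
    for node in base.non_tips(include_self=False):
        key = node_keys.get(id(node))
        if key is not None:
            node.name = f"{100.0 * counts[key] / n_boot:.0f}"
    return base


# -- branch compression --------------------------------------------------------


def _max_leaf_path(node: TreeNode) -> float:
    if node.is_tip():
        return 0.0
    return max(
        (child.length or 0.0) + _max_leaf_path(child) for child in node.children
    )


def compress_branches(tree: TreeNode, threshold: float) -> TreeNode:
    """Collapse maximal tight clades into single labelled nodes.

    A subtree collapses when every leaf's path length to the subtree root
    is at most ``threshold``; the maximal such subtrees become leaves
    labelled ``"<representative> (+k)"`` with the lexicographically
    smallest member as representative and k = members - 1.  Collapsed
    nodes carry the full member list in their ``members`` attribute, so
    total leaf membership is conserved.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    t = tree.copy()

    def visit(node: TreeNode) -> None:
        for child in list(node.children):
            if child.is_tip():
                child.members = [child.name]
                continue
            if _max_leaf_path(child) <= threshold:
                members = sorted(tip.name for tip in child.tips())
                rep = members[0]
                leaf = TreeNode(
                    name=f"{rep} (+{len(members) - 1})", length=child.length
                )
                leaf.members = members
                node.remove(child)
                node.append(leaf)
            else:
                visit(child)

    if not t.is_tip() and _max_leaf_path(t) <= threshold:
        members = sorted(tip.name for tip in t.tips())
        rep = members[0]
        leaf = TreeNode(name=f"{rep} (+{len(members) - 1})")
        leaf.members = members
        return leaf
    for tip in t.tips():
        tip.members = [tip.name]
    visit(t)
    return t


def member_count(tree: TreeNode) -> int:
    """Total leaf membership of a (possibly compressed) tree."""
    total = 0
    for tip in tree.tips():
        total += len(getattr(tip, "members", [tip.name]))
    if tree.is_tip():
        total = len(getattr(tree, "members", [tree.name]))
    return total


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Midpoint-rooted copy for display."""
    return tree.copy().root_at_midpoint()
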