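"""Kimura two-parameter distances and neighbor-joining tree construction.

The K2P model corrects observed divergence separately for transitions
(purine<->purine, pyrimidine<->pyrimidine) and transversions: with P the
transition proportion and Q the transversion proportion over the compared
sites,

    d = -1/2 * ln( (1 - 2P - Q) * sqrt(1 - 2Q) ).

Sites where either sequence carries N or a gap are excluded pairwise
(pairwise deletion), which maximizes the usable sites of short CDS
alignments.  When the argument of the logarithm is non-positive the
sequences are saturated and no finite distance exists.

Trees are built with the Saitou–Nei neighbor-joining algorithm: at each
step the pair minimizing the Q-criterion is joined, branch lengths follow
the standard formulas, negative lengths are clamped to zero with the
deficit moved onto the sister edge, and ties are broken by lexicographic
taxon-pair order so output is reproducible bit-for-bit.  NJ is exact on
additive matrices.  Trees are held as unrooted :class:`dendropy.Tree`
objects and serialized to newick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import DegenerateStatisticError, ValidationError

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_SKIP = frozenset("N-")


@dataclass(frozen=True)
class AlignedSeqSet:
    """Named, equal-length nucleotide sequences over {A,C,G,T,N,-}."""

    names: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValidationError("names and sequences differ in length")
        if len(self.names) < 2:
            raise ValidationError("an alignment needs at least two sequences")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("duplicate sequence names")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValidationError(f"sequences are not aligned: lengths {sorted(lengths)}")
        for name, seq in zip(self.names, self.sequences):
            bad = set(seq.upper()) - (PURINES | PYRIMIDINES | _SKIP)
            if bad:
                raise ValidationError(f"sequence {name!r}: invalid symbol(s) {sorted(bad)}")
        object.__setattr__(self, "sequences", tuple(s.upper() for s in self.sequences))

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "AlignedSeqSet":
        return cls(tuple(n for n, _ in pairs), tuple(s for _, s in pairs))


@dataclass(frozen=True)
class DistanceMatrix:
    names: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        k = len(self.names)
        if d.shape != (k, k):
            raise ValidationError("distance matrix shape does not match names")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValidationError("distances must be non-negative")


# ---------------------------------------------------------------------------
# K2P distance
# ---------------------------------------------------------------------------

def _site_classes(a: str, b: str) -> tuple[int, int, int]:
    """Return (compared sites, transitions, transversions) with pairwise deletion."""
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x in _SKIP or y in _SKIP:
            continue
        n += 1
        if x == y:
            continue
        same_class = ({x, y} <= PURINES) or ({x, y} <= PYRIMIDINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance between two aligned sequences."""
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValidationError("sequences must be aligned (equal length)")
    n, ts, tv = _site_classes(a, b)
    if n == 0:
        raise DegenerateStatisticError("no comparable sites after pairwise deletion")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise DegenerateStatisticError(
            f"saturated pair (P={P:.3f}, Q={Q:.3f}): K2P distance undefined"
        )
    return float(-0.5 * math.log(w1 * math.sqrt(w2)))


def distance_matrix(seqs: AlignedSeqSet) -> DistanceMatrix:
    """All pairwise K2P distances; errors name the saturated pair."""
    k = len(seqs.names)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                d[i, j] = d[j, i] = k2p_distance(seqs.sequences[i], seqs.sequences[j])
            except DegenerateStatisticError as exc:
                raise DegenerateStatisticError(
                    f"pair ({seqs.names[i]}, {seqs.names[j]}): {exc}"
                ) from None
    return DistanceMatrix(tuple(seqs.names), d)


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------

def neighbor_joining(m: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor-joining on a distance matrix.

    Returns an unrooted tree (the dendropy seed node has degree three for
    four or more taxa).  Deterministic: among pairs tied on the
    Q-criterion the lexicographically smallest name pair is joined.
    """
    k = len(m.names)
    if k < 3:
        raise ValidationError("neighbor-joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for name in m.names:
        node = dendropy.Node(taxon=taxa.new_taxon(name))
        # smallest leaf label under each node, for deterministic tie-breaks
        node._sort_key = name
        nodes.append(node)
    d = m.d.astype(float).copy()
    active = list(range(k))

    while len(active) > 2:
        n_act = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(n_act):
            for aj in range(ai + 1, n_act):
                i, j = active[ai], active[aj]
                q = (n_act - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((nodes[i]._sort_key, nodes[j]._sort_key)))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n_act - 2))
        vj = d[i, j] - vi
        # clamp negatives, moving the deficit to the sister edge
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = vi
        parent.add_child(nodes[j])
        nodes[j].edge.length = vj
        parent._sort_key = min(nodes[i]._sort_key, nodes[j]._sort_key)
        # distances from the new node to the remaining ones
        new_row = np.zeros(d.shape[0])
        for kk in active:
            if kk in (i, j):
                continue
            new_row[kk] = 0.5 * (d[i, kk] + d[j, kk] - d[i, j])
        d[i, :] = new_row
        d[:, i] = new_row
        nodes[i] = parent
        active.remove(j)

    # graft the last lineage onto the other across the final edge, so the
    # seed node is a trifurcation and the tree is genuinely unrooted
    i, j = active
    parent, child = (nodes[i], nodes[j]) if not nodes[i].is_leaf() else (nodes[j], nodes[i])
    parent.add_child(child)
    child.edge.length = max(d[i, j], 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=parent)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# newick serialization
# ---------------------------------------------------------------------------

def to_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths at 6 significant digits."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
    ).strip()


def parse_newick(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise ValidationError(f"malformed newick: {exc}") from None


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix induced by a tree's branch lengths."""
    pdm = tree.phylogenetic_distance_matrix()
    names = tuple(sorted(t.label for t in tree.taxon_namespace))
    taxon = {t.label: t for t in tree.taxon_namespace}
    k = len(names)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxon[names[i]], taxon[names[j]])
    return DistanceMatrix(names, d)
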