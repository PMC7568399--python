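"""Pairwise distances, neighbor-joining, and outgroup rooting.

The distance metric is a p-distance variant tailored to curated protein
alignments: the number of aligned columns where both sequences carry a
residue and the residues differ, divided by the *shorter* sequence's
ungapped length.  It is dimensionless and bounded by [0, 1] on families that
pass :func:`~phyloconsensus.family_io.filter_homologs`.

Neighbor joining follows Saitou & Nei's agglomerative algorithm with the
standard Q-criterion and limb-length formulas.  It is implemented here (not
delegated) so that tie-breaking is deterministic and reproducible: when two
pairs achieve the same minimal Q, the lexicographically smallest index pair
in input order is joined.  Negative limb lengths — a known NJ artifact on
non-additive matrices — are clamped to zero and the clamped deficit is
recorded on the tree wrapper.

Trees are held as :class:`PhyloTree`, a thin wrapper around
``dendropy.Tree`` that adds the invariants this package relies on
(unique leaf labels, non-negative branch lengths, rooted flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import TreeError, UndefinedDistanceError, ValidationError
from .family_io import GAP, AlignedFamily


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def pairwise_distance(a: str, b: str) -> float:
    """Mismatch count over mutually non-gap columns ÷ min ungapped length.

    Columns where either sequence is gapped are ignored in the mismatch
    count; 'X' against anything (including 'X') counts as a mismatch only if
    the letters differ, matching the byte-level reading of "non-identical
    residue pairs".
    """
    if len(a) != len(b):
        raise ValidationError("aligned sequences have different lengths")
    len_a = sum(1 for ch in a if ch != GAP)
    len_b = sum(1 for ch in b if ch != GAP)
    denom = min(len_a, len_b)
    if denom == 0:
        raise UndefinedDistanceError("distance undefined for an all-gap sequence")
    mismatches = sum(
        1 for x, y in zip(a, b) if x != GAP and y != GAP and x != y
    )
    return min(mismatches / denom, 1.0)


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric, zero-diagonal matrix of pairwise distances."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(self.ids))
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValidationError(f"matrix shape {d.shape} does not match {n} ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValidationError("distance matrix has negative entries")

    def __getitem__(self, pair):
        i, j = pair
        if isinstance(i, str):
            i = self.ids.index(i)
        if isinstance(j, str):
            j = self.ids.index(j)
        return float(self.d[i, j])

    def __len__(self):
        return len(self.ids)


def distance_matrix(family: AlignedFamily) -> DistanceMatrix:
    """All-pairs :func:`pairwise_distance` over a family, in record order."""
    seqs = [seq for _, seq in family]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(seqs[i], seqs[j])
    return DistanceMatrix(tuple(family.ids), d)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """A phylogeny with branch lengths; wraps a ``dendropy.Tree``.

    ``clamped_deficit`` records the total magnitude of negative NJ limb
    lengths that were clamped to zero during construction (0.0 for trees
    read from Newick).
    """

    tree: dendropy.Tree
    rooted: bool = False
    clamped_deficit: float = 0.0
    _leaves: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.tree.is_rooted = self.rooted
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate leaf labels in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError("negative branch length")
        self._leaves = {
            lf.taxon.label: lf for lf in self.tree.leaf_node_iter()
        }

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def leaf(self, label: str) -> dendropy.Node:
        try:
            return self._leaves[label]
        except KeyError:
            raise TreeError(f"no leaf labelled '{label}'") from None

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        pdm = self.tree.phylogenetic_distance_matrix()
        return pdm.patristic_distance(self.leaf(a).taxon, self.leaf(b).taxon)

    def path_length_matrix(self, ids: list[str]) -> np.ndarray:
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(ids)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = pdm.patristic_distance(
                    taxa[ids[i]], taxa[ids[j]]
                )
        return out

    # -- Newick IO ---------------------------------------------------------

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=False,
            unquoted_underscores=True,
        ).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(self.as_newick() + "\n")

    @classmethod
    def from_newick(cls, source: str, rooted: bool | None = None) -> "PhyloTree":
        """Parse a Newick string or file path.

        Rooting is taken from the ``[&R]``/``[&U]`` hint when present unless
        overridden by ``rooted``.
        """
        import os

        data = source
        if os.path.exists(str(source)):
            with open(source) as handle:
                data = handle.read()
        tree = dendropy.Tree.get(
            data=data, schema="newick", preserve_underscores=True
        )
        if rooted is None:
            rooted = bool(tree.is_rooted)
        return cls(tree, rooted=rooted)


def tree_splits(phylo: PhyloTree) -> set[frozenset]:
    """Non-trivial bipartitions of the leaf set, for topology comparison.

    Each split is canonicalized to the side that does not contain the
    alphabetically first leaf, so rooted and unrooted representations of
    the same topology compare equal.
    """
    labels = set(phylo.leaf_labels)
    anchor = sorted(labels)[0]
    out = set()
    for node in phylo.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = frozenset(labels - side)
        if 1 < len(side) < len(labels) - 1:
            out.add(side)
    return out


def _new_leaf(ns: dendropy.TaxonNamespace, label: str) -> dendropy.Node:
    node = dendropy.Node()
    node.taxon = ns.require_taxon(label=label)
    return node


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining; returns an unrooted tree.

    Ties in the Q-criterion minimum are broken toward the lowest index pair
    in input order.  Negative limb lengths are clamped to zero; the total
    clamped magnitude is available as ``PhyloTree.clamped_deficit``.
    """
    n = len(dm)
    if n < 2:
        raise ValidationError("neighbor joining needs at least 2 taxa")
    ns = dendropy.TaxonNamespace()
    nodes = [_new_leaf(ns, label) for label in dm.ids]
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    if n == 2:
        root = dendropy.Node()
        a, b = nodes
        root.add_child(a)
        root.add_child(b)
        half = dm.d[0, 1] / 2.0
        a.edge.length = clamp(half)
        b.edge.length = clamp(half)
        tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
        return PhyloTree(tree, rooted=False, clamped_deficit=deficit)

    D = dm.d.copy()
    active = list(range(n))  # indices into `nodes`, in input order
    # `nodes` grows as internal nodes are created; D is re-indexed over `active`.

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) pair among minima, i < j in current (input) order
        qmin = q.min()
        ii, jj = min(
            (int(i), int(j))
            for i, j in np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
            if i < j
        )
        dij = sub[ii, jj]
        limb_i = 0.5 * dij + (r[ii] - r[jj]) / (2.0 * (m - 2))
        limb_j = dij - limb_i
        parent = dendropy.Node()
        child_i, child_j = nodes[active[ii]], nodes[active[jj]]
        parent.add_child(child_i)
        parent.add_child(child_j)
        child_i.edge.length = clamp(limb_i)
        child_j.edge.length = clamp(limb_j)
        # distances from the new node to the remaining taxa
        new_index = len(nodes)
        nodes.append(parent)
        new_row = np.zeros(new_index)
        for kk in range(m):
            if kk in (ii, jj):
                continue
            k = active[kk]
            new_row[k] = 0.5 * (sub[ii, kk] + sub[jj, kk] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new_index, :new_index] = new_row
        D[:new_index, new_index] = new_row
        active = [k for t, k in enumerate(active) if t not in (ii, jj)]
        active.append(new_index)

    # join the last three nodes at a central (unrooted) hub
    a, b, c = active
    hub = dendropy.Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for k, limb in zip((a, b, c), (la, lb, lc)):
        hub.add_child(nodes[k])
        nodes[k].edge.length = clamp(limb)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=hub)
    return PhyloTree(tree, rooted=False, clamped_deficit=deficit)


def root_with_outgroup(
    phylo: PhyloTree, outgroup_id: str, split_fraction: float = 0.5
) -> PhyloTree:
    """Root the tree on the edge leading to the outgroup leaf.

    The root is placed ``split_fraction`` of the way along the outgroup's
    terminal edge measured from the outgroup leaf (0.5 = midpoint).  All
    leaf-to-leaf path lengths are preserved.
    """
    if not (0.0 <= split_fraction <= 1.0):
        raise ValidationError("split_fraction must lie in [0, 1]")
    tree = phylo.tree.clone(depth=1)
    wrapped = PhyloTree(tree, rooted=phylo.rooted,
                        clamped_deficit=phylo.clamped_deficit)
    leaf = wrapped.leaf(outgroup_id)
    edge = leaf.edge
    total = edge.length or 0.0
    tree.reroot_at_edge(
        edge,
        length1=total * (1.0 - split_fraction),  # retained by the non-leaf side
        length2=total * split_fraction,          # retained by the outgroup leaf
        suppress_unifurcations=False,
    )
    tree.is_rooted = True
    return PhyloTree(tree, rooted=True, clamped_deficit=phylo.clamped_deficit)
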