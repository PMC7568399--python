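"""Phylogenetic sequence weights from rooted-tree branch lengths.

A plain (unweighted) consensus over a homolog family is dominated by
whichever subfamily happens to be over-represented in the database.  The
remedy implemented here assigns each sequence a weight derived from the
rooted tree's branch lengths so that closely related sequences share the
credit for the branches they have in common: a subfamily of near-identical
sequences collectively receives roughly the weight a single representative
would, and its weight does not grow with over-sampling.

Two strategies are provided.

``"equal-split"`` (default)
    The length of every edge is divided equally among the *child branches*
    at each node below it.  A leaf's raw weight is the sum over the edges on
    its root-to-leaf path of ``length(e) × ∏ 1/children(v)`` over the
    internal nodes ``v`` strictly below ``e`` on that path.  This makes the
    de-biasing exact: attaching k identical copies of a leaf at zero
    distance leaves the copies' combined weight equal to the original leaf's
    weight, for any k and any internal arrangement of the copies.

``"gsc"``
    The Gerstein–Sonnhammer–Chothia variant: each edge's length is divided
    by the number of leaves below it.  Equivalent to equal-split on strictly
    bifurcating trees with balanced subtrees; its de-biasing property is
    only approximate under duplication.

The outgroup used to root the tree carries no biological signal about the
family and is excluded from the weights (and hence from the consensus).
Weights are normalized to sum to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy

from .errors import TreeError, ValidationError
from .phylogeny import PhyloTree

#: Relative floor for leaves at zero path length, as a fraction of the mean
#: raw weight; keeps every sequence strictly positive without reordering.
ZERO_PATH_EPSILON = 1e-8


@dataclass(frozen=True)
class SequenceWeights:
    """Normalized per-sequence weights; excludes the outgroup."""

    weights: dict[str, float]
    raw: dict[str, float]

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"weights sum to {total}, expected 1")
        if any(w <= 0 for w in self.weights.values()):
            raise ValidationError("weights must be strictly positive")

    def __getitem__(self, sequence_id: str) -> float:
        return self.weights[sequence_id]

    def __iter__(self):
        return iter(self.weights)

    def __len__(self):
        return len(self.weights)

    def items(self):
        return self.weights.items()

    def to_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("sequence_id\traw_weight\tnormalized_weight\n")
            for sid, w in self.weights.items():
                handle.write(f"{sid}\t{self.raw[sid]:.10g}\t{w:.10g}\n")


def _included_leaf_count(node: dendropy.Node, excluded: set) -> int:
    return sum(
        1 for lf in node.leaf_iter() if lf.taxon.label not in excluded
    )


def branch_weights(
    tree: PhyloTree,
    outgroup_id: str | None = None,
    strategy: str = "equal-split",
) -> SequenceWeights:
    """Compute per-sequence weights from a rooted tree.

    Parameters
    ----------
    tree:
        A rooted :class:`~phyloconsensus.phylogeny.PhyloTree`.
    outgroup_id:
        Leaf to exclude from weighting (the rooting outgroup), if any.
    strategy:
        ``"equal-split"`` or ``"gsc"``; see the module docstring.
    """
    if not tree.rooted:
        raise TreeError("branch weights require a rooted tree")
    if strategy not in ("equal-split", "gsc"):
        raise ValidationError(f"unknown weighting strategy '{strategy}'")
    excluded = {outgroup_id} if outgroup_id else set()
    if outgroup_id and outgroup_id not in tree._leaves:
        raise TreeError(f"outgroup '{outgroup_id}' is not a leaf of the tree")
    labels = [l for l in tree.leaf_labels if l not in excluded]
    if len(labels) < 2:
        raise TreeError("need at least 2 non-outgroup leaves")

    raw = {label: 0.0 for label in labels}

    def distribute(node: dendropy.Node, credit: float) -> None:
        """Distribute an edge's length among the included leaves below it."""
        if node.is_leaf():
            raw[node.taxon.label] += credit
            return
        children = [
            ch for ch in node.child_nodes()
            if ch.is_leaf() and ch.taxon.label in raw
            or not ch.is_leaf() and _included_leaf_count(ch, excluded) > 0
        ]
        if strategy == "equal-split":
            for ch in children:
                distribute(ch, credit / len(children))
        else:  # gsc: divide by the number of leaves below the edge
            leaves = [
                lf for lf in node.leaf_iter() if lf.taxon.label not in excluded
            ]
            for lf in leaves:
                raw[lf.taxon.label] += credit / len(leaves)

    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        if node.is_leaf() and node.taxon.label not in raw:
            continue  # outgroup terminal edge
        if not node.is_leaf() and _included_leaf_count(node, excluded) == 0:
            continue
        distribute(node, node.edge.length or 0.0)

    total_raw = sum(raw.values())
    if total_raw <= 0.0:
        warnings.warn(
            "all branch lengths are zero; returning uniform weights",
            stacklevel=2,
        )
        uniform = 1.0 / len(labels)
        return SequenceWeights(
            {label: uniform for label in labels}, dict(raw)
        )
    mean_raw = total_raw / len(labels)
    eps = ZERO_PATH_EPSILON * mean_raw
    adjusted = {k: (v if v > 0 else eps) for k, v in raw.items()}
    total = sum(adjusted.values())
    normalized = {k: v / total for k, v in adjusted.items()}
    return SequenceWeights(normalized, dict(raw))


def uniform_weights(sequence_ids, outgroup_id: str | None = None) -> SequenceWeights:
    """Equal weights over the given ids (minus the outgroup); the unweighted
    baseline that the tree-derived weights are compared against."""
    ids = [s for s in sequence_ids if s != outgroup_id]
    if not ids:
        raise ValidationError("no sequences to weight")
    w = 1.0 / len(ids)
    return SequenceWeights({s: w for s in ids}, {s: 1.0 for s in ids})
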