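"""Ground-truth generators: families evolved along a known tree, biased
(oversampled) families with planted clade substitutions, and assay curves
with known kinetic/thermodynamic parameters.

The family simulator emulates the situation the weighted-consensus method
is designed for: a couple dozen protein homologs (default 24, matching a
typical curated creatinase-family harvest) diverged from a known ancestor,
with one subfamily optionally over-sampled the way redundant database
depositions over-sample popular organisms.  Because the generating tree,
the ancestral sequence, and every substitution event are retained, tests
can ask exact questions — does NJ recover the topology? does the weighted
consensus recover the ancestral residue? — without reference data.

The evolution model is deliberately minimal: site-independent substitution
along each edge with probability ``1 − exp(−rate·length)``, replacement
drawn uniformly from the other 19 residues, and no indels.  Uniformity
gives closed-form expectations (e.g. the expected leaf-vs-ancestor
p-distance) and indel-freedom keeps the bookkeeping exact; neither realism
gap affects what the consensus machinery is being tested for.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace as dc_replace

import dendropy
import numpy as np

from .errors import ConfigError, ValidationError
from .family_io import AMINO_ACIDS, AlignedFamily
from .phylogeny import PhyloTree
from .stability import AssayCurve

#: Branch length used when attaching near-identical duplicate leaves.
DUPLICATE_BRANCH_LENGTH = 1e-4

#: Study-scale defaults: family size and protein length.
DEFAULT_FAMILY_SIZE = 24
DEFAULT_SEQUENCE_LENGTH = 404


@dataclass(frozen=True)
class SimulatedFamily:
    """A family with full provenance: tree, ancestor, and event log."""

    family: AlignedFamily
    true_tree: PhyloTree
    ancestral_sequence: str
    events: tuple[dict, ...]  # {"edge": (parent, child), "site": 1-based, "from", "to"}
    outgroup_id: str | None = None

    def __post_init__(self):
        leaf_set = set(self.true_tree.leaf_labels)
        fam_set = set(self.family.ids)
        if leaf_set != fam_set:
            raise ValidationError("tree leaves and family ids disagree")
        if len(self.ancestral_sequence) != self.family.alignment_length:
            raise ValidationError("ancestral length != alignment length")


def _label_internal_nodes(tree: dendropy.Tree) -> None:
    counter = itertools.count(1)
    for node in tree.preorder_node_iter():
        if node.taxon is None and not getattr(node, "label", None):
            node.label = f"N{next(counter)}"


def _node_name(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon else node.label


def random_ancestor(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def random_tree(
    n_leaves: int,
    seed: int,
    mean_edge_length: float = 0.05,
    labels: list[str] | None = None,
) -> PhyloTree:
    """A random rooted binary tree built by successive random pair-joins
    (a coalescent-style shape).

    Edge lengths are uniform in [0.5, 1.5] × ``mean_edge_length`` — bounded
    away from zero so every split is resolvable in principle, which is what
    topology-recovery properties assume.  Leaves are labelled ``S01..Snn``
    unless ``labels`` is given.
    """
    if n_leaves < 2:
        raise ValidationError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace()
    if labels is None:
        width = len(str(n_leaves))
        labels = [f"S{i + 1:0{width}d}" for i in range(n_leaves)]
    nodes = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = ns.require_taxon(label=label)
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(
                rng.uniform(0.5, 1.5) * mean_edge_length
            )
        nodes = [n for t, n in enumerate(nodes) if t not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=nodes[0])
    return PhyloTree(tree, rooted=True)


def attach_outgroup(
    tree: PhyloTree, label: str = "OUTGROUP", stem_length: float = 0.5
) -> PhyloTree:
    """Return a new rooted tree whose root joins the old root and a distant
    outgroup leaf."""
    inner = tree.tree.clone(depth=1)
    ns = inner.taxon_namespace
    root = dendropy.Node()
    out_leaf = dendropy.Node()
    out_leaf.taxon = ns.require_taxon(label=label)
    old_root = inner.seed_node
    root.add_child(old_root)
    old_root.edge.length = stem_length / 2.0
    root.add_child(out_leaf)
    out_leaf.edge.length = stem_length / 2.0
    new_tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    return PhyloTree(new_tree, rooted=True)


def simulate_family(
    tree: PhyloTree,
    ancestral: str,
    rate: float = 1.0,
    seed: int = 0,
    query_id: str | None = None,
    outgroup_id: str | None = None,
) -> SimulatedFamily:
    """Evolve the ancestral sequence down the tree.

    Along each edge of length ``l`` every site substitutes independently
    with probability ``1 − exp(−rate·l)``; the replacement is uniform over
    the other 19 residues.  Deterministic under ``seed``.
    """
    if rate <= 0:
        raise ValidationError("rate must be positive")
    ancestral = ancestral.upper()
    if any(ch not in AMINO_ACIDS for ch in ancestral):
        raise ValidationError("ancestral sequence must use the 20-letter alphabet")
    rng = np.random.default_rng(seed)
    work = tree.tree.clone(depth=1)
    _label_internal_nodes(work)
    alphabet = np.array(list(AMINO_ACIDS))
    aa_index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    seqs: dict[int, np.ndarray] = {}
    events: list[dict] = []
    anc = np.array([aa_index[ch] for ch in ancestral])
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            seqs[id(node)] = anc.copy()
            continue
        parent_seq = seqs[id(node.parent_node)].copy()
        length = node.edge.length or 0.0
        # exact endpoint distribution of the uniform 19-way jump process:
        # P(state differs from parent) after intensity rate·length
        p_sub = (19.0 / 20.0) * (1.0 - np.exp(-rate * length * 20.0 / 19.0))
        hits = np.flatnonzero(rng.random(len(parent_seq)) < p_sub)
        for site in hits:
            old = parent_seq[site]
            new = (old + 1 + rng.integers(19)) % 20
            parent_seq[site] = new
            events.append(
                {
                    "edge": (_node_name(node.parent_node), _node_name(node)),
                    "site": int(site) + 1,
                    "from": AMINO_ACIDS[old],
                    "to": AMINO_ACIDS[new],
                }
            )
        seqs[id(node)] = parent_seq
    records = []
    for leaf in work.leaf_node_iter():
        records.append(
            (leaf.taxon.label, "".join(alphabet[seqs[id(leaf)]]))
        )
    if query_id is None:
        query_id = next(
            sid for sid, _ in records if sid != outgroup_id
        )
    family = AlignedFamily(tuple(records), query_id)
    return SimulatedFamily(
        family=family,
        true_tree=PhyloTree(work, rooted=tree.rooted),
        ancestral_sequence=ancestral,
        events=tuple(events),
        outgroup_id=outgroup_id,
    )


def _find_clade(tree: dendropy.Tree, clade) -> dendropy.Node:
    """Resolve a clade given as an internal-node label, a leaf label, or a
    collection of leaf labels (→ their MRCA)."""
    if isinstance(clade, str):
        for node in tree.preorder_node_iter():
            if _node_name(node) == clade:
                return node
        raise ConfigError(f"no node named '{clade}'")
    taxa = [t for t in tree.taxon_namespace if t.label in set(clade)]
    if len(taxa) != len(set(clade)):
        raise ConfigError("unknown leaf label in clade spec")
    return tree.mrca(taxa=taxa)


def clade_leaf_labels(sim: SimulatedFamily, clade) -> list[str]:
    node = _find_clade(sim.true_tree.tree, clade)
    return [lf.taxon.label for lf in node.leaf_iter()]


def plant_clade_substitution(
    sim: SimulatedFamily,
    clade,
    seed: int = 0,
    site: int | None = None,
) -> tuple[SimulatedFamily, int, str, str]:
    """Force a clade-specific substitution at a conserved site.

    Picks a site (1-based) where every leaf still carries the ancestral
    residue, chooses a different residue, and rewrites the clade's leaves to
    carry it.  Returns ``(new_sim, site, ancestral_residue, planted_residue)``.
    This is the controlled construction behind the de-biasing tests: the
    clade now contradicts the ancestor at a known position.
    """
    rng = np.random.default_rng(seed)
    tree = sim.true_tree.tree
    node = _find_clade(tree, clade)
    clade_ids = {lf.taxon.label for lf in node.leaf_iter()}
    if not clade_ids or clade_ids == set(sim.true_tree.leaf_labels):
        raise ConfigError("clade must be a proper subset of the leaves")
    seqs = dict(sim.family.records)
    if site is None:
        conserved = [
            p for p in range(1, len(sim.ancestral_sequence) + 1)
            if all(seqs[sid][p - 1] == sim.ancestral_sequence[p - 1]
                   for sid in seqs)
        ]
        if not conserved:
            raise ConfigError("no fully conserved site available for planting")
        site = int(conserved[int(rng.integers(len(conserved)))])
    old = sim.ancestral_sequence[site - 1]
    choices = [aa for aa in AMINO_ACIDS if aa != old]
    new = choices[int(rng.integers(len(choices)))]
    records = []
    events = list(sim.events)
    for sid, seq in sim.family.records:
        if sid in clade_ids:
            seq = seq[: site - 1] + new + seq[site:]
            events.append(
                {"edge": ("planted", sid), "site": site, "from": old, "to": new}
            )
        records.append((sid, seq))
    family = AlignedFamily(tuple(records), sim.family.query_id)
    return (
        dc_replace(sim, family=family, events=tuple(events)),
        site,
        old,
        new,
    )


def bias_family(
    sim: SimulatedFamily,
    clade,
    extra_copies: int,
    seed: int = 0,
    rate: float = 1.0,
) -> SimulatedFamily:
    """Over-sample a clade with near-identical duplicate leaves.

    ``extra_copies`` new leaves are attached, cycling over the clade's
    existing leaves; each duplicate hangs from its source leaf's position at
    branch length 1e-4 and is re-simulated along that tiny edge, so
    duplicates are near-identical to their source — the database-redundancy
    scenario that biases an unweighted consensus.  ``extra_copies == 0`` is
    a no-op.  The clade may not be the whole tree.
    """
    if extra_copies == 0:
        return sim
    if extra_copies < 0:
        raise ConfigError("extra_copies must be non-negative")
    rng = np.random.default_rng(seed)
    tree = sim.true_tree.tree.clone(depth=1)
    _label_internal_nodes(tree)
    node = _find_clade(tree, clade)
    if node is tree.seed_node:
        raise ConfigError("cannot oversample the whole tree (clade = root)")
    source_leaves = [lf for lf in node.leaf_iter()]
    seqs = dict(sim.family.records)
    ns = tree.taxon_namespace
    events = list(sim.events)
    new_records: dict[str, str] = {}
    alphabet = list(AMINO_ACIDS)
    # convert each source leaf used into an internal hub whose children are
    # the original leaf plus its duplicates, all at tiny branch length
    hubs: dict[str, dendropy.Node] = {}
    counters: dict[str, int] = {}
    for c in range(extra_copies):
        src = source_leaves[c % len(source_leaves)]
        label = src.taxon.label
        if label not in hubs:
            hub = dendropy.Node()
            parent = src.parent_node
            hub.edge.length = src.edge.length
            parent.remove_child(src)
            parent.add_child(hub)
            hub.add_child(src)
            src.edge.length = DUPLICATE_BRANCH_LENGTH
            hubs[label] = hub
        counters[label] = counters.get(label, 0) + 1
        dup_label = f"{label}_dup{counters[label]}"
        dup = dendropy.Node()
        dup.taxon = ns.require_taxon(label=dup_label)
        hubs[label].add_child(dup)
        dup.edge.length = DUPLICATE_BRANCH_LENGTH
        # re-simulate the duplicate along its tiny edge
        src_seq = list(seqs[label])
        p_sub = (19.0 / 20.0) * (
            1.0 - np.exp(-rate * DUPLICATE_BRANCH_LENGTH * 20.0 / 19.0)
        )
        hits = np.flatnonzero(rng.random(len(src_seq)) < p_sub)
        for site in hits:
            old = src_seq[site]
            others = [aa for aa in alphabet if aa != old]
            new = others[int(rng.integers(19))]
            src_seq[site] = new
            events.append(
                {"edge": (label, dup_label), "site": int(site) + 1,
                 "from": old, "to": new}
            )
        new_records[dup_label] = "".join(src_seq)
    records = list(sim.family.records) + sorted(new_records.items())
    family = AlignedFamily(tuple(records), sim.family.query_id)
    return dc_replace(
        sim,
        family=family,
        true_tree=PhyloTree(tree, rooted=sim.true_tree.rooted),
        events=tuple(events),
    )


@dataclass(frozen=True)
class OversampledFamily:
    """A biased family with one planted, clade-specific substitution.

    ``sim`` holds the oversampled family (clade duplicated to ``oversample``
    times its original size); at query position ``planted_site`` every clade
    member carries ``planted_residue`` while the ancestor (and the query)
    carry ``ancestral_residue``.  An unweighted consensus is arranged to be
    dominated by the clade at that site; a correctly de-biased consensus is
    not.
    """

    sim: SimulatedFamily
    planted_site: int
    ancestral_residue: str
    planted_residue: str
    clade_ids: tuple[str, ...]
    query_id: str
    outgroup_id: str


def oversampled_family(
    seed: int,
    n_ingroup: int = 8,
    length: int = 200,
    rate: float = 1.0,
    mean_edge_length: float = 0.04,
    oversample: int = 5,
    outgroup_stem: float = 0.6,
) -> OversampledFamily:
    """Construct the database-bias scenario with known ground truth.

    A random ingroup tree plus a distant outgroup is simulated; a cherry
    (two-leaf clade) is given a planted substitution at a previously
    conserved site and then duplicated to ``oversample``× its size.  The
    clade ends up holding the absolute majority of sequences, so a uniform
    consensus at the planted site calls the clade's residue, while the
    ancestral residue is retained by any weighting that de-biases the
    duplicated branches.  The query is a non-clade ingroup leaf.
    """
    ingroup = random_tree(n_ingroup, seed, mean_edge_length)
    full = attach_outgroup(ingroup, "OUTGROUP", stem_length=outgroup_stem)
    # find a cherry (internal node with exactly two leaf children)
    cherry = None
    for node in full.tree.postorder_node_iter():
        children = node.child_nodes()
        if len(children) == 2 and all(c.is_leaf() for c in children):
            labels = {c.taxon.label for c in children}
            if "OUTGROUP" not in labels:
                cherry = sorted(labels)
                break
    if cherry is None:  # cannot happen for a binary tree, kept as a guard
        raise ConfigError("no cherry found in the ingroup tree")
    query_id = next(
        lbl for lbl in full.leaf_labels
        if lbl not in cherry and lbl != "OUTGROUP"
    )
    sim = simulate_family(
        full, random_ancestor(length, seed), rate=rate, seed=seed,
        query_id=query_id, outgroup_id="OUTGROUP",
    )
    sim, site, old, new = plant_clade_substitution(sim, cherry, seed=seed)
    extra = (oversample - 1) * len(cherry)
    sim = bias_family(sim, cherry, extra_copies=extra, seed=seed, rate=rate)
    clade_ids = tuple(clade_leaf_labels(sim, cherry))
    return OversampledFamily(
        sim=sim,
        planted_site=site,
        ancestral_residue=old,
        planted_residue=new,
        clade_ids=clade_ids,
        query_id=query_id,
        outgroup_id="OUTGROUP",
    )


# ---------------------------------------------------------------------------
# Assay-curve generators
# ---------------------------------------------------------------------------

def simulate_decay(
    k: float,
    times,
    noise_sigma: float = 0.0,
    seed: int = 0,
    variant: str = "",
    assay_temperature: float | None = None,
) -> AssayCurve:
    """First-order inactivation: y(t) = 100·exp(k·t)·(1 + ε), ε ~ N(0, σ)."""
    if k >= 0:
        raise ValidationError("decay requires k < 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(list(times), float)
    y = 100.0 * np.exp(k * t)
    if noise_sigma > 0:
        y = y * (1.0 + rng.normal(0.0, noise_sigma, size=len(t)))
    y = np.clip(y, 0.0, 120.0)
    return AssayCurve(
        "decay", tuple(t), tuple(y), variant=variant,
        assay_temperature=assay_temperature,
    )


def simulate_t50(
    t50: float,
    dT: float = 2.0,
    temperatures=None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    variant: str = "",
) -> AssayCurve:
    """Boltzmann inactivation ladder (default 35–70 °C in 2.5 °C steps)."""
    if temperatures is None:
        temperatures = np.arange(35.0, 70.0 + 1e-9, 2.5)
    rng = np.random.default_rng(seed)
    T = np.asarray(list(temperatures), float)
    y = 100.0 / (1.0 + np.exp((T - t50) / dT))
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=len(T))
    y = np.clip(y, 0.0, 120.0)
    return AssayCurve("t50", tuple(T), tuple(y), variant=variant)


def simulate_melt(
    midpoint: float,
    width: float = 1.5,
    baselines: tuple[float, float, float, float] = (0.85, 0.0, 1.05, 0.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
    temperatures=None,
    variant: str = "",
) -> AssayCurve:
    """nanoDSF-style 350/330 ratio over a thermal ramp (default 20–95 °C,
    1 °C steps).

    ``baselines`` is ``(folded_intercept, folded_slope, unfolded_intercept,
    unfolded_slope)``; with equal slopes the derivative maximum of the
    noise-free curve sits exactly at ``midpoint``.
    """
    if not (20.0 <= midpoint <= 95.0):
        raise ValidationError("midpoint must lie within the 20–95 °C ramp")
    if temperatures is None:
        temperatures = np.arange(20.0, 95.0 + 1e-9, 1.0)
    rng = np.random.default_rng(seed)
    T = np.asarray(list(temperatures), float)
    b1, m1, b2, m2 = baselines
    theta = 1.0 / (1.0 + np.exp(-(T - midpoint) / width))
    y = (b1 + m1 * T) * (1.0 - theta) + (b2 + m2 * T) * theta
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=len(T))
    return AssayCurve("melt", tuple(T), tuple(y), variant=variant)


def expected_p_distance(rate: float, length: float) -> float:
    """Closed-form expected leaf-vs-ancestor p-distance for the uniform
    19-way replacement model along a single branch.

    With total substitution intensity ``rate·length`` the probability that
    a site ends in a non-ancestral state is
    ``(19/20)·(1 − exp(−rate·length·20/19))``.
    """
    return (19.0 / 20.0) * (1.0 - np.exp(-rate * length * 20.0 / 19.0))
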