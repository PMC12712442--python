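"""Phylogeny handling: Newick I/O, genus grafting, pruning, Brownian covariance.

Trees are :class:`dendropy.Tree` objects throughout; tip labels are species
binomials ("Genus epithet").  The Brownian-motion covariance matrix C has
``C[i, j]`` equal to the shared root-to-MRCA path length of tips i and j and
``C[i, i]`` equal to the root-to-tip depth, i.e. the expected trait
(co)variance per unit rate under Brownian motion.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import scipy.linalg as sla

__all__ = [
    "PhyloCovariance",
    "read_newick",
    "write_newick",
    "graft_species_to_genus",
    "prune_to_overlap",
    "vcv",
    "lambda_transform",
    "phylo_weighted_mean",
]


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian covariance matrix C aligned to an explicit species order."""

    species: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        C = np.asarray(self.matrix, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("covariance matrix must be square")
        if C.shape[0] != len(self.species):
            raise ValueError("species order and matrix dimension disagree")
        if not np.allclose(C, C.T, atol=1e-8):
            raise ValueError("covariance matrix must be symmetric")
        object.__setattr__(self, "matrix", C)

    @property
    def n(self) -> int:
        return len(self.species)

    def align(self, species: list[str] | tuple[str, ...]) -> "PhyloCovariance":
        """Reorder (or subset) the matrix to match ``species``."""
        index = {s: i for i, s in enumerate(self.species)}
        missing = [s for s in species if s not in index]
        if missing:
            raise KeyError(f"species not in covariance: {missing[:5]}")
        idx = np.array([index[s] for s in species])
        return PhyloCovariance(tuple(species), self.matrix[np.ix_(idx, idx)])

    def standardized(self) -> "PhyloCovariance":
        """C scaled to unit maximum diagonal (tree height)."""
        d = float(np.max(np.diag(self.matrix)))
        if d <= 0:
            raise ValueError("tree has zero height; cannot standardize")
        return PhyloCovariance(self.species, self.matrix / d)


def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string (or path ending in .nwk/.tre) into a rooted tree.

    Raises ``ValueError`` on parse failure or duplicate tip labels.
    """
    try:
        if source.strip().startswith("(") or source.strip().startswith(";"):
            stream = io.StringIO(source)
            tree = dendropy.Tree.get(file=stream, schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=source, schema="newick",
                                     preserve_underscores=True)
    except Exception as err:  # dendropy raises schema-specific subclasses
        raise ValueError(f"Newick parse error: {err}") from err
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    # labels with spaces (binomials) are quoted rather than rewritten with
    # underscores, so they survive a read_newick round-trip unchanged
    return tree.as_string(schema="newick", suppress_rooting=True,
                          preserve_spaces=True).strip()


def mrca_node(tree: dendropy.Tree, nodes: list) -> "dendropy.Node":
    """Most recent common ancestor by ancestor-path intersection.

    Unlike dendropy's bitmask-based lookup this stays correct after tips
    have been added to the tree in place.
    """
    paths = []
    for node in nodes:
        path = []
        nd = node
        while nd is not None:
            path.append(nd)
            nd = nd.parent_node
        paths.append(path[::-1])
    mrca = None
    for level in zip(*paths):
        if all(nd is level[0] for nd in level):
            mrca = level[0]
        else:
            break
    return mrca


def _tip_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        length = node.edge.length or 0.0
        depths[node] = (depths[parent] + length) if parent is not None else 0.0
    return depths


def vcv(tree: dendropy.Tree) -> PhyloCovariance:
    """Brownian covariance matrix of the tree's tips (O(n^2))."""
    leaves = list(tree.leaf_node_iter())
    labels = tuple(leaf.taxon.label for leaf in leaves)
    index = {leaf: i for i, leaf in enumerate(leaves)}
    depths = _tip_depths(tree)
    n = len(leaves)
    C = np.zeros((n, n))
    # Postorder: each internal node sets the covariance for tip pairs whose
    # MRCA it is (pairs drawn from distinct child subtrees).
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node]
            tipsets[node] = [i]
            C[i, i] = depths[node]
            continue
        groups = [tipsets.pop(child) for child in node.child_nodes()]
        d = depths[node]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia = np.asarray(groups[a])
                ib = np.asarray(groups[b])
                C[np.ix_(ia, ib)] = d
                C[np.ix_(ib, ia)] = d
        tipsets[node] = [i for g in groups for i in g]
    return PhyloCovariance(labels, C)


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda transform: multiply off-diagonals by ``lam``."""
    if not (0.0 <= lam <= 1.0 + 1e-9):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    M = C.matrix * lam
    np.fill_diagonal(M, np.diag(C.matrix))
    return PhyloCovariance(C.species, M)


def _chol_solve(C: np.ndarray, B: np.ndarray):
    """Cholesky solve with a small diagonal jitter retry on failure."""
    try:
        cf = sla.cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * float(np.mean(np.diag(C)))
        try:
            cf = sla.cho_factor(C + jitter * np.eye(C.shape[0]), lower=True)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "covariance matrix is singular; consider adding jitter to "
                "branch lengths") from err
    return sla.cho_solve(cf, B)


def phylo_weighted_mean(x: np.ndarray, C: PhyloCovariance) -> float:
    """GLS estimate of the root state: (1'C^-1 1)^-1 1'C^-1 x."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != C.n:
        raise ValueError("trait vector and covariance dimension disagree")
    ones = np.ones(C.n)
    w = _chol_solve(C.matrix, ones)
    return float(w @ x / (w @ ones))


def graft_species_to_genus(
    tree: dendropy.Tree,
    species: list[str],
    seed: int,
) -> tuple[dendropy.Tree, list[str]]:
    """Graft missing species as new tips at random positions within their genus.

    For each species (binomial), its genus clade is the MRCA of all tips whose
    first name token matches; an edge within the clade is chosen uniformly by
    count, the attachment point uniformly along it, and the new tip's branch is
    extended so the clade's (mean) tip depth is preserved.  Species whose genus
    has no tips are returned in the skip list, unchanged.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    tree = tree.clone(depth=1)
    skipped: list[str] = []
    for binomial in species:
        genus = binomial.split()[0]
        depths = _tip_depths(tree)
        genus_tips = [lf for lf in tree.leaf_node_iter()
                      if lf.taxon.label.split()[0] == genus]
        if not genus_tips:
            skipped.append(binomial)
            continue
        if any(lf.taxon.label == binomial for lf in tree.leaf_node_iter()):
            skipped.append(binomial)
            continue
        target_depth = float(np.mean([depths[lf] for lf in genus_tips]))
        if len(genus_tips) == 1:
            candidate_nodes = genus_tips  # the single tip's own edge
        else:
            mrca = mrca_node(tree, genus_tips)
            candidate_nodes = [nd for nd in mrca.preorder_iter() if nd is not mrca]
        # choose the edge above this node, uniform by count
        node = candidate_nodes[int(rng.integers(len(candidate_nodes)))]
        edge_len = node.edge.length or 0.0
        t = float(rng.uniform(0.0, edge_len)) if edge_len > 0 else 0.0
        parent = node.parent_node
        attach_depth = depths[node] - (edge_len - t)
        # split the edge: parent -> split -> node
        split = parent.new_child(edge_length=t)
        parent.remove_child(node)
        split.add_child(node)
        node.edge.length = edge_len - t
        taxon = dendropy.Taxon(label=binomial)
        tree.taxon_namespace.add_taxon(taxon)
        split.new_child(taxon=taxon,
                        edge_length=max(target_depth - attach_depth, 0.0))
    return tree, skipped


def prune_to_overlap(
    tree: dendropy.Tree, species: set[str] | list[str]
) -> tuple[dendropy.Tree, list[str]]:
    """Prune the tree to tips present in ``species``.

    Returns the pruned tree and its tip labels in tree order.  Degree-2
    interior nodes are suppressed with branch lengths summed, so pairwise path
    distances among retained tips are preserved.  Raises on empty overlap.
    """
    keep = {lbl for lbl in species} & {lf.taxon.label
                                       for lf in tree.leaf_node_iter()}
    if not keep:
        raise ValueError("no overlap between tree tips and species table")
    pruned = tree.extract_tree_with_taxa_labels(keep)
    pruned.is_rooted = True
    # Suppress degree-2 interiors by summing branch lengths.  The root's stem
    # chain is collapsed into a single edge below the seed node (not dropped),
    # so root-to-MRCA shared path lengths — hence the covariance matrix — are
    # preserved exactly for the retained tips.
    for node in list(pruned.postorder_node_iter()):
        if node is pruned.seed_node or node.is_leaf():
            continue
        children = node.child_nodes()
        if len(children) == 1:
            child = children[0]
            child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
            parent = node.parent_node
            parent.remove_child(node)
            parent.add_child(child)
    return pruned, [lf.taxon.label for lf in pruned.leaf_node_iter()]
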