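"""Phylogenetic correlation structure from a species tree.

Under a Brownian-motion model of trait evolution on an ultrametric tree of
depth T, the correlation between two tips equals the fraction of the
root-to-tip path they share: ``corr(i, j) = (T - h(mrca(i, j))) / T`` where
``h`` is node height measured from the root.  This species-by-species
matrix scales the phylogenetically structured random effect in the
meta-analytic model.

Topology-only trees (no branch lengths, e.g. taxonomy-derived) are first
made ultrametric with Grafen's method: each internal node is assigned a
height equal to its number of descendant tips minus one (rho = 1), then all
heights are divided by the root height so the tree has unit depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .dataio import DataError, normalize_species

__all__ = ["PhyloCorrelation", "grafen_lengths", "correlation_matrix"]

ULTRAMETRIC_RTOL = 1e-6


@dataclass(frozen=True)
class PhyloCorrelation:
    """Symmetric unit-diagonal species correlation matrix with a fixed order."""

    species_order: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.species_order),) * 2:
            raise DataError("matrix shape does not match species order")
        if not np.allclose(m, m.T, atol=1e-12):
            raise DataError("phylogenetic correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise DataError("phylogenetic correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise DataError("phylogenetic correlation matrix is not positive semi-definite")

    def to_frame(self) -> pd.DataFrame:
        idx = list(self.species_order)
        return pd.DataFrame(self.matrix, index=idx, columns=idx)

    def reorder(self, species: Sequence[str]) -> "PhyloCorrelation":
        """Submatrix in the requested species order (all must be present)."""
        pos = {sp: i for i, sp in enumerate(self.species_order)}
        missing = [sp for sp in species if sp not in pos]
        if missing:
            raise DataError(f"species absent from the correlation matrix: {missing}")
        idx = np.array([pos[sp] for sp in species])
        return PhyloCorrelation(tuple(species), self.matrix[np.ix_(idx, idx)])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def grafen_lengths(tree: dendropy.Tree, rho: float = 1.0) -> dendropy.Tree:
    """Assign Grafen branch lengths to a topology-only rooted tree.

    Node height = (number of descendant tips - 1) ** rho, normalized by the
    root height so the returned tree is ultrametric with depth 1.  The input
    tree is not modified.
    """
    if tree.seed_node is None:
        raise DataError("tree has no root")
    work = tree.clone(depth=1)
    heights: dict[dendropy.Node, float] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            n_tips = sum(1 for _ in node.leaf_iter())
            heights[node] = float(n_tips - 1) ** rho
    root_height = heights[work.seed_node]
    if root_height <= 0:
        raise DataError("Grafen heights degenerate: root height is zero")
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
            continue
        node.edge.length = (heights[node.parent_node] - heights[node]) / root_height
        if node.edge.length < 0:
            raise DataError("negative Grafen branch length (non-nested clade sizes?)")
    work.topology_only = False
    return work


def _tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[normalize_species(leaf.taxon.label)] = d
    return depths


def correlation_matrix(
    tree: dendropy.Tree,
    species_order: Optional[Sequence[str]] = None,
) -> PhyloCorrelation:
    """Brownian-motion tip correlation matrix of an ultrametric tree.

    Entry (i, j) is the shared root-to-MRCA path length divided by the tree
    depth; the diagonal is 1.  Trees that are not ultrametric within a
    relative tolerance of 1e-6 are rejected, naming the worst tip pair.
    Topology-only trees are Grafen-ultrametricized first.
    """
    if getattr(tree, "topology_only", False):
        tree = grafen_lengths(tree)
    depths = _tip_depths(tree)
    labels = list(depths)
    depth_vals = np.array([depths[l] for l in labels])
    depth = float(depth_vals.mean())
    if depth <= 0:
        raise DataError("tree depth is zero; cannot form correlations")
    worst = np.argsort(depth_vals)
    lo, hi = labels[worst[0]], labels[worst[-1]]
    if (depth_vals.max() - depth_vals.min()) / depth > ULTRAMETRIC_RTOL:
        raise DataError(
            "tree is not ultrametric: tip depths differ beyond tolerance "
            f"(worst pair {lo!r} at {depth_vals.min():.6g} vs {hi!r} at {depth_vals.max():.6g})"
        )

    # node height above root for every node, then MRCA heights per tip pair
    node_depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_depth[node] = 0.0
        else:
            node_depth[node] = node_depth[node.parent_node] + (node.edge.length or 0.0)

    leaves = {normalize_species(l.taxon.label): l for l in tree.leaf_node_iter()}
    order = [normalize_species(s) for s in species_order] if species_order else sorted(labels)
    missing = [s for s in order if s not in leaves]
    if missing:
        raise DataError(f"species absent from the tree: {missing}")

    # ancestor sets once per tip; shared path = depth of deepest common ancestor
    anc: dict[str, list[dendropy.Node]] = {}
    for name in order:
        chain = []
        node = leaves[name]
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc[name] = chain

    k = len(order)
    mat = np.eye(k)
    for i in range(k):
        set_i = set(id(n) for n in anc[order[i]])
        for j in range(i + 1, k):
            mrca = next(n for n in anc[order[j]] if id(n) in set_i)
            mat[i, j] = mat[j, i] = node_depth[mrca] / depth
    return PhyloCorrelation(tuple(order), mat)
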