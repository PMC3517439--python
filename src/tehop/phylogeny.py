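"""Neighbor-joining phylogenies from K2P distances, with bootstrap support.

The tree-building route mirrors the classic distance workflow: pairwise
K2P distances with pairwise deletion of incomparable columns, the
Saitou-Nei neighbor-joining agglomeration using the Studier-Keppler
criterion

    Q(i,j) = (n - 2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)

and nonparametric (column-resampling) bootstrap support on the internal
edges of the full-data tree. Ties in Q are broken by lexicographic label
pair and negative branch lengths are clamped to zero with the deficit
moved to the sister branch, so output is deterministic across platforms
and taxon orderings.
"""

from __future__ import annotations

import logging
from typing import Optional

import dendropy
import numpy as np

from .core_io import Alignment, DistanceMatrix, Sequence, tree_bipartitions
from .family_stats import (
    NoComparableSitesError,
    SaturatedDistanceError,
    k2p_distance,
)

logger = logging.getLogger(__name__)

__all__ = ["distance_matrix", "neighbor_joining", "bootstrap_support"]


def distance_matrix(aln: Alignment, allow_missing: bool = False) -> DistanceMatrix:
    """Pairwise K2P distance matrix over an alignment (pairwise deletion).

    Saturated or incomparable pairs become NaN; unless ``allow_missing``
    is set, any NaN raises an error listing the offending pairs, since
    neighbor joining needs a complete matrix.
    """
    if len(aln) < 3:
        raise ValueError("distance matrix needs >=3 sequences")
    n = len(aln)
    vals = np.zeros((n, n))
    members = aln.members
    for i in range(n):
        for j in range(i + 1, n):
            try:
                vals[i, j] = vals[j, i] = k2p_distance(members[i], members[j]).d
            except (SaturatedDistanceError, NoComparableSitesError):
                vals[i, j] = vals[j, i] = np.nan
    dm = DistanceMatrix([s.id for s in members], vals)
    if not allow_missing and dm.missing:
        pairs = ", ".join(f"{a}/{b}" for a, b in dm.missing)
        raise ValueError(f"distance matrix has missing entries: {pairs}")
    return dm


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree.

    Branch lengths come from the standard two-point formulas; a negative
    length is clamped to 0 and the deficit is added to its sister branch
    (logged). The final three clusters are joined to one central node
    with the three-point formulas.
    """
    if dm.missing:
        raise ValueError("matrix has missing entries")
    labels = list(dm.taxa)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs >=3 taxa")

    taxon_ns = dendropy.TaxonNamespace(labels)
    nodes: dict[str, dendropy.Node] = {}
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxon_ns.get_taxon(lab)
        nodes[lab] = node

    d = {frozenset((a, b)): float(dm[(a, b)]) for a in labels for b in labels if a != b}
    active = list(labels)
    next_id = 0

    def dist(a: str, b: str) -> float:
        return 0.0 if a == b else d[frozenset((a, b))]

    while len(active) > 3:
        m = len(active)
        row_sums = {a: sum(dist(a, b) for b in active) for a in active}
        best = None
        best_pair = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * dist(a, b) - row_sums[a] - row_sums[b]
                key = tuple(sorted((a, b)))
                if best is None or q < best - 1e-12 or (abs(q - best) <= 1e-12 and key < best_pair):
                    best, best_pair = q, key
        a, b = best_pair
        dab = dist(a, b)
        la = 0.5 * dab + (row_sums[a] - row_sums[b]) / (2.0 * (m - 2))
        lb = dab - la
        # clamp-and-transfer for negative branch lengths
        if la < 0:
            lb += -la
            la = 0.0
            logger.debug("clamped negative branch at %s", a)
        if lb < 0:
            la += -lb
            lb = 0.0
            logger.debug("clamped negative branch at %s", b)
        new_label = f"__internal_{next_id}"
        next_id += 1
        parent = dendropy.Node()
        ca, cb = nodes.pop(a), nodes.pop(b)
        parent.add_child(ca)
        parent.add_child(cb)
        ca.edge.length = la
        cb.edge.length = lb
        nodes[new_label] = parent
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new_label, c))] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = sorted(set(active) - {a, b} | {new_label})

    # join the last three clusters at a central node (unrooted resolution)
    x, y, z = active
    lx = 0.5 * (dist(x, y) + dist(x, z) - dist(y, z))
    ly = 0.5 * (dist(x, y) + dist(y, z) - dist(x, z))
    lz = 0.5 * (dist(x, z) + dist(y, z) - dist(x, y))
    lens = {x: lx, y: ly, z: lz}
    for lab in (x, y, z):
        if lens[lab] < 0:
            deficit = -lens[lab]
            lens[lab] = 0.0
            for other in (x, y, z):
                if other != lab:
                    lens[other] += deficit / 2.0
            logger.debug("clamped negative terminal branch at %s", lab)
    center = dendropy.Node()
    for lab in (x, y, z):
        child = nodes.pop(lab)
        center.add_child(child)
        child.edge.length = lens[lab]

    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def bootstrap_support(
    aln: Alignment,
    replicates: int = 1000,
    seed: int = 0,
) -> dendropy.Tree:
    """Felsenstein bootstrap on the full-data NJ tree.

    Columns are resampled with replacement per replicate; replicates
    whose matrix has saturated/incomparable pairs are dropped and
    counted. Support for each internal edge of the full-data tree is the
    percentage (integer) of retained replicates containing that
    bipartition, stored as the internal node's label. More than 50%
    dropped replicates aborts with an error. An alignment with no
    internal structure (e.g. all-identical sequences) yields the
    zero-length NJ tree with supports on whatever internal edges exist.
    """
    if len(aln) < 4:
        raise ValueError("bootstrap needs >=4 sequences")
    full_dm = distance_matrix(aln)
    full_tree = neighbor_joining(full_dm)
    target = {bp: 0 for bp in tree_bipartitions(full_tree)}

    rng = np.random.default_rng(seed)
    kept = 0
    dropped = 0
    for _ in range(replicates):
        idx = rng.integers(0, aln.length, size=aln.length)
        rep = aln.take_columns(idx)
        try:
            dm = distance_matrix(rep)
        except (ValueError, SaturatedDistanceError):
            dropped += 1
            continue
        kept += 1
        rep_bps = tree_bipartitions(neighbor_joining(dm))
        for bp in target:
            if bp in rep_bps:
                target[bp] += 1
    if dropped > replicates / 2:
        raise ValueError("alignment too saturated for bootstrap")
    if dropped:
        logger.warning("dropped %d/%d saturated bootstrap replicates", dropped, replicates)

    all_leaves = frozenset(lf.taxon.label for lf in full_tree.leaf_node_iter())
    for node in full_tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        bp = frozenset((side, all_leaves - side))
        if bp in target and kept > 0:
            node.label = str(int(round(100.0 * target[bp] / kept)))
    return full_tree
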