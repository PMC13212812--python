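"""Desk-scale phylogenetic stage: gap trimming, distances, NJ, bootstrap.

The published column-trimming rule (drop alignment sites with > 25% gaps) is
implemented exactly. Tree inference here is distance-based — p or Poisson-
corrected distances under pairwise gap deletion, followed by Saitou–Nei
neighbor joining with nonparametric site-resampling bootstrap — a documented
desk-scale substitute for maximum-likelihood inference with model selection
and ultrafast bootstrap, which this package deliberately does not
re-implement. On an additive distance matrix NJ recovers the unique additive
tree exactly; join ties are broken by the lexicographically lowest label
pair, and negative branch-length estimates are clamped to zero.

Trees are dendropy objects; bootstrap supports are stored as integer
percentage labels on internal nodes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .io_formats import Msa

__all__ = [
    "DistanceMatrix",
    "EmptyAlignmentError",
    "UndefinedDistanceError",
    "trim_columns",
    "pairwise_distances",
    "neighbor_joining",
    "bootstrap_support",
    "tree_bipartitions",
]

logger = logging.getLogger("esmscreen.phylo")


class EmptyAlignmentError(ValueError):
    """All alignment columns were removed by trimming."""


class UndefinedDistanceError(ValueError):
    """A pairwise distance cannot be computed (saturation or no shared sites)."""


@dataclass
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances (substitutions per site)."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < -1e-12):
            raise ValueError("distances must be non-negative")


# ---------------------------------------------------------------------------
# Column trimming

def trim_columns(
    msa: Msa, max_gap_fraction: float = 0.25
) -> tuple[Msa, list[int]]:
    """Remove alignment columns whose gap fraction exceeds the threshold.

    A column is kept iff gaps / sequences <= ``max_gap_fraction`` — the rule
    is strictly greater-than for removal, so a column at exactly the
    threshold survives. Returns the trimmed alignment and the kept column
    indices (1-based).
    """
    matrix = np.array([list(seq) for _, seq in msa.records])
    gap_fraction = (matrix == "-").mean(axis=0)
    keep = gap_fraction <= max_gap_fraction
    kept_indices = [int(i) + 1 for i in np.flatnonzero(keep)]
    if not kept_indices:
        raise EmptyAlignmentError(
            f"every column has > {max_gap_fraction:.0%} gaps; "
            "relax max_gap_fraction"
        )
    trimmed = [
        (rid, "".join(matrix[i, keep])) for i, (rid, _) in enumerate(msa.records)
    ]
    return Msa(records=trimmed), kept_indices


# ---------------------------------------------------------------------------
# Distances

def _distance_from_arrays(
    a: np.ndarray, b: np.ndarray, model: str, label_a: str, label_b: str
) -> float:
    shared = (a != b"-"[0]) & (b != b"-"[0])
    n_sites = int(shared.sum())
    if n_sites == 0:
        raise UndefinedDistanceError(
            f"no comparable (gap-free) sites between {label_a!r} and {label_b!r}"
        )
    p = float((a[shared] != b[shared]).sum()) / n_sites
    if model == "p":
        return p
    if p >= 1.0:
        raise UndefinedDistanceError(
            f"saturated pair {label_a!r}/{label_b!r}: p = {p} has no "
            "Poisson-corrected distance"
        )
    return -math.log(1.0 - p)


def _msa_to_bytes(msa: Msa) -> np.ndarray:
    return np.array(
        [np.frombuffer(seq.encode("ascii"), dtype=np.uint8) for _, seq in msa.records]
    )


def pairwise_distances(msa: Msa, model: str = "p") -> DistanceMatrix:
    """All-pairs distances under pairwise gap deletion.

    ``p``: observed mismatch proportion over gap-free site pairs.
    ``poisson``: -ln(1 - p), the Poisson multiple-hit correction, in
    substitutions per site.
    """
    if model not in {"p", "poisson"}:
        raise ValueError(f"unknown distance model {model!r}")
    matrix = _msa_to_bytes(msa)
    labels = msa.ids
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _distance_from_arrays(
                matrix[i], matrix[j], model, labels[i], labels[j]
            )
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# Neighbor joining

def _clamp(length: float, context: str) -> float:
    if length < 0.0:
        logger.debug("clamped negative branch length %.6g at %s", length, context)
        return 0.0
    return length


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining, exact on additive matrices.

    Joins minimise the Q criterion; ties are broken by the lexicographically
    lowest (sorted) pair of cluster representative labels, where a cluster is
    represented by its smallest tip label. Negative branch-length estimates
    are clamped to zero. The result is unrooted: internal nodes have degree
    three (for > 3 taxa), with a single central multifurcation for 3 taxa and
    a two-child seed node splitting the sole edge for 2 taxa.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    reps: list[str] = []  # smallest tip label per active cluster
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
        reps.append(label)
    d = dm.d.astype(float).copy()

    if n == 2:
        half = dm.d[0, 1] / 2.0
        for node in nodes:
            node.edge.length = half
            tree.seed_node.add_child(node)
        tree.is_rooted = False
        return tree

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for bj in range(ai + 1, m):
                i, j = active[ai], active[bj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((reps[i], reps[j])))
                if best is None or (q, pair_key) < best[:2]:
                    best = (q, pair_key, i, j)
        _, _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        parent = dendropy.Node()
        nodes[i].edge.length = _clamp(vi, f"join({reps[i]},{reps[j]})")
        nodes[j].edge.length = _clamp(vj, f"join({reps[i]},{reps[j]})")
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node to every other active cluster
        new_index = i
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[new_index, k] = d[k, new_index] = dk
        nodes[new_index] = parent
        reps[new_index] = min(reps[i], reps[j])
        active.remove(j)

    # final three clusters joined at the unrooted central node
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].edge.length = _clamp(length, "final-join")
        tree.seed_node.add_child(nodes[idx])
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap

def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, as canonical tip sets.

    Each internal edge splits the tips in two; the side not containing the
    lexicographically smallest tip label is the canonical representative.
    """
    all_tips = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    anchor = min(all_tips)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        canonical = side if anchor not in side else all_tips - side
        if 1 < len(canonical) < len(all_tips) - 1 or (
            1 < len(side) < len(all_tips) - 1
        ):
            splits.add(canonical)
    return splits


def _resample_columns(matrix: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n_cols = matrix.shape[1]
    cols = rng.integers(0, n_cols, size=n_cols)
    return matrix[:, cols]


def _distances_from_matrix(
    matrix: np.ndarray, labels: list[str], model: str
) -> DistanceMatrix:
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _distance_from_arrays(
                matrix[i], matrix[j], model, labels[i], labels[j]
            )
    return DistanceMatrix(labels=labels, d=d)


def bootstrap_support(
    msa: Msa,
    model: str = "p",
    n_replicates: int = 1000,
    seed: int | None = None,
    max_redraws_per_replicate: int = 100,
) -> dendropy.Tree:
    """NJ tree with nonparametric bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement per replicate; the
    support of each internal edge of the point-estimate tree is the
    percentage of replicate trees containing the same bipartition, rounded
    to the nearest integer and stored as the node label. A replicate whose
    resample yields an undefined distance is redrawn, up to a logged cap.
    Identical seeds give identical output.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    point_tree = neighbor_joining(pairwise_distances(msa, model))
    target_splits = tree_bipartitions(point_tree)
    matrix = _msa_to_bytes(msa)
    labels = msa.ids
    rng = np.random.default_rng(seed)
    counts = {split: 0 for split in target_splits}
    for _ in range(n_replicates):
        for attempt in range(max_redraws_per_replicate + 1):
            try:
                dm = _distances_from_matrix(
                    _resample_columns(matrix, rng), labels, model
                )
                break
            except UndefinedDistanceError:
                logger.warning(
                    "bootstrap replicate redrawn (attempt %d): undefined distance",
                    attempt + 1,
                )
        else:
            raise UndefinedDistanceError(
                f"replicate still undefined after {max_redraws_per_replicate} redraws"
            )
        rep_splits = tree_bipartitions(neighbor_joining(dm))
        for split in target_splits & rep_splits:
            counts[split] += 1
    for node in point_tree.preorder_node_iter():
        if node is point_tree.seed_node or node.is_leaf():
            continue
        all_tips = frozenset(
            leaf.taxon.label for leaf in point_tree.leaf_node_iter()
        )
        anchor = min(all_tips)
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        canonical = side if anchor not in side else all_tips - side
        if canonical in counts:
            node.label = str(round(100.0 * counts[canonical] / n_replicates))
    return point_tree
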