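"""Family classification of element copies.

Copies covering at least one-third of the family coding sequence are
grouped by pairwise anchored p-distance into nested subfamily / family /
group partitions (single linkage at three distance cuts), and summarised as
a neighbor-joining tree.  This is a deterministic classification analogue;
likelihood phylogenetics with branch support is out of scope.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .capture_detector import allelic_divergence

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "FamilyAssignment",
    "inclusion_filter",
    "pairwise_distances",
    "cluster_families",
    "neighbor_joining",
]

SUBFAMILY_CUT = 0.10  # copies 90% identical share a subfamily
FAMILY_CUT = 0.25
GROUP_CUT = 0.45
INCLUSION_NUMERATOR, INCLUSION_DENOMINATOR = 1, 3


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    unanchorable: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.matrix = m


@dataclass
class FamilyAssignment:
    assignments: dict[str, tuple[str, str, str]]  # label -> (group, family, subfamily)
    included_in_tree: dict[str, bool] = field(default_factory=dict)


def inclusion_filter(
    copies: list[tuple[int, int]], reference_orf_len: int
) -> list[tuple[int, int]]:
    """Copies (as covered intervals on the family reference) spanning at
    least one-third of the reference coding sequence; the threshold is
    closed (exactly 1/3 is included), computed in integer arithmetic."""
    if reference_orf_len <= 0:
        raise ValueError("reference_orf_len must be positive")
    return [
        (a, b)
        for a, b in copies
        if INCLUSION_DENOMINATOR * (b - a) >= INCLUSION_NUMERATOR * reference_orf_len
    ]


def pairwise_distances(
    seqs: list[str], k: int = 12, labels: list[str] | None = None
) -> DistanceMatrix:
    """Anchored-identity p-distance matrix; an unanchorable pair gets
    distance 1.0 and is flagged."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    labels = labels if labels is not None else [f"seq{i}" for i in range(len(seqs))]
    n = len(seqs)
    m = np.zeros((n, n))
    unanch: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            d = allelic_divergence(seqs[i], seqs[j], anchor_k=k)
            if d is None:
                d = 1.0
                unanch.append((labels[i], labels[j]))
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m, unanch)


def _named_partition(labels: list[str], ids: np.ndarray, prefix: str) -> dict[str, str]:
    # deterministic, input-order-invariant names: clusters ordered by their
    # lexicographically smallest member
    clusters: dict[int, list[str]] = {}
    for lab, cid in zip(labels, ids):
        clusters.setdefault(int(cid), []).append(lab)
    ordered = sorted(clusters.values(), key=lambda members: min(members))
    out: dict[str, str] = {}
    for rank, members in enumerate(ordered, start=1):
        for lab in members:
            out[lab] = f"{prefix}{rank}"
    return out


def cluster_families(
    dm: DistanceMatrix,
    subfamily_cut: float = SUBFAMILY_CUT,
    family_cut: float = FAMILY_CUT,
    group_cut: float = GROUP_CUT,
) -> FamilyAssignment:
    """Single-linkage clustering at three nested distance cuts.

    Cuts are closed (a pair at exactly the cut distance is merged), and the
    partitions nest by construction of the linkage hierarchy."""
    if not subfamily_cut < family_cut < group_cut:
        raise ValueError("cuts must satisfy subfamily < family < group")
    labels = dm.labels
    if len(labels) == 1:
        return FamilyAssignment({labels[0]: ("G1", "F1", "S1")})
    z = linkage(squareform(dm.matrix, checks=False), method="single")
    parts = {}
    for prefix, cut in (("G", group_cut), ("F", family_cut), ("S", subfamily_cut)):
        ids = fcluster(z, t=cut, criterion="distance")
        parts[prefix] = _named_partition(labels, ids, prefix)
    assignments = {
        lab: (parts["G"][lab], parts["F"][lab], parts["S"][lab]) for lab in labels
    }
    return FamilyAssignment(assignments)


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree of the distance matrix as a newick string.

    Taxa are canonicalised to label order so ties break deterministically;
    negative branch lengths are clamped to zero (and logged)."""
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    order = sorted(range(len(dm.labels)), key=lambda i: dm.labels[i])
    labels = [dm.labels[i] for i in order]
    matrix = dm.matrix[np.ix_(order, order)]
    tree = nj(SkbioDM(matrix, ids=labels))
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        logger.info("neighbor_joining: clamped %d negative branch lengths", clamped)
    return str(tree).strip()
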