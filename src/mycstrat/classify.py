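"""Consensus MYC-activity calling from signature-restricted hierarchical clustering.

For each MYC-target signature the expression matrix is restricted to the
signature genes, each gene row is scaled to zero mean / unit variance, and
samples are clustered by Ward-linkage agglomerative clustering on Euclidean
distance (the ward.D2 criterion). The cluster with the highest mean scaled
signature expression is the MYC-high cluster; an optional secondary rule also
admits further clusters whose mean scaled expression exceeds a threshold
(covering the "incomplete high-expression cluster" situation). Samples called
high by every signature form the consensus MYC-high set.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .dataio import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "MycCallSet",
    "scale_rows",
    "cluster_by_signature",
    "call_high_cluster",
    "consensus_calls",
]


@dataclass
class ClusterAssignment:
    signature_name: str
    sample_ids: list[str]
    cluster_id: np.ndarray  # int per sample, in [0, k)
    k: int
    linkage_height_cut: float

    def members(self, cid: int) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.cluster_id) if c == cid]


@dataclass
class MycCallSet:
    """Per-signature and consensus MYC-high calls.

    consensus_high is the intersection of the per-signature high sets (the
    secondary-inclusion rule, if enabled, has already been folded into each
    per-signature set). venn_counts maps frozensets of signature names to the
    number of samples called high by exactly that combination.
    """

    per_signature_high: dict[str, set[str]]
    consensus_high: set[str]
    secondary_included: set[str] = field(default_factory=set)
    provenance: dict = field(default_factory=dict)
    venn_counts: dict[frozenset, int] = field(default_factory=dict)


def scale_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each row to zero mean, unit variance (sample SD, ddof=1).

    Returns (scaled, keep_mask); zero-variance rows are excluded from the
    mask rather than divided by zero.
    """
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    scaled = np.zeros_like(values)
    scaled[keep] = (values[keep] - mu[keep]) / sd[keep]
    return scaled[keep], keep


def _scaled_signature_matrix(
    matrix: ExpressionMatrix, signature: GeneSet, case_fold: bool = False
) -> np.ndarray:
    sub = matrix.subset_genes(signature.genes, case_fold=case_fold)
    n_missing = len(signature.genes) - sub.n_genes
    if n_missing:
        logger.info("%s: %d signature genes absent from matrix", signature.name, n_missing)
    scaled, keep = scale_rows(sub.values)
    n_const = sub.n_genes - int(keep.sum())
    if n_const:
        warnings.warn(
            f"{signature.name}: dropped {n_const} zero-variance gene rows", stacklevel=3
        )
    if scaled.shape[0] < 2:
        raise ValueError(
            f"{signature.name}: fewer than 2 usable signature genes in matrix"
        )
    return scaled


def cluster_by_signature(
    matrix: ExpressionMatrix,
    signature: GeneSet,
    k: int = 2,
    scale: bool = True,
    case_fold: bool = False,
) -> ClusterAssignment:
    """Cluster samples on a signature's genes (Euclidean distance, Ward linkage).

    Gene rows are variance-scaled before distance computation unless
    ``scale=False``. The tree is cut into ``k`` clusters; output is
    deterministic for a given input order.
    """
    if k > matrix.n_samples:
        raise ValueError(f"k={k} exceeds n_samples={matrix.n_samples}")
    if scale:
        X = _scaled_signature_matrix(matrix, signature, case_fold=case_fold)
    else:
        sub = matrix.subset_genes(signature.genes, case_fold=case_fold)
        if sub.n_genes < 2:
            raise ValueError(f"{signature.name}: fewer than 2 usable signature genes")
        X = sub.values
    Z = linkage(X.T, method="ward")  # ward.D2: Euclidean, squared-distance objective
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    # height of the cut: between the (n-k)th and (n-k+1)th merge
    heights = Z[:, 2]
    cut = float(heights[-k]) if k > 1 and k <= len(heights) else float("inf")
    return ClusterAssignment(signature.name, list(matrix.sample_ids), labels, int(labels.max() + 1), cut)


def call_high_cluster(
    assignment: ClusterAssignment,
    matrix: ExpressionMatrix,
    signature: GeneSet,
    secondary_rule: float | None = None,
    case_fold: bool = False,
) -> tuple[set[str], set[str]]:
    """Identify the MYC-high cluster(s) for one signature.

    The high cluster is the one with the largest mean of row-scaled signature
    expression. With ``secondary_rule=t`` any *other* cluster whose mean
    scaled expression exceeds ``t`` is also included (this generalizes the
    manual inclusion of a cluster with incompletely elevated target genes);
    ``secondary_rule=None`` disables the rule. Returns
    ``(high_sample_ids, secondarily_included_sample_ids)``.
    """
    X = _scaled_signature_matrix(matrix, signature, case_fold=case_fold)
    means = np.array([
        X[:, assignment.cluster_id == c].mean() for c in range(assignment.k)
    ])
    top = np.flatnonzero(means == means.max())
    if len(top) > 1:
        # exact tie: deterministic break to the cluster holding the smallest sample ID
        warnings.warn("exact tie in cluster means; breaking by smallest sample ID", stacklevel=2)
        best = min(top, key=lambda c: min(assignment.members(int(c))))
    else:
        best = int(top[0])
    high = set(assignment.members(best))
    secondary: set[str] = set()
    if secondary_rule is not None:
        for c in range(assignment.k):
            if c != best and means[c] > secondary_rule:
                secondary |= set(assignment.members(c))
    return high | secondary, secondary


def consensus_calls(per_signature_high: dict[str, set[str]]) -> MycCallSet:
    """Intersect per-signature high calls into the consensus MYC-high set.

    Also tabulates Venn-style overlap counts (samples high under exactly each
    combination of signatures) for reporting. An empty consensus is valid and
    only warns.
    """
    if not per_signature_high:
        raise ValueError("need at least one signature")
    names = list(per_signature_high)
    consensus = set.intersection(*(set(v) for v in per_signature_high.values()))
    if not consensus:
        warnings.warn("consensus MYC-high set is empty", stacklevel=2)
    venn: dict[frozenset, int] = {}
    universe = set().union(*per_signature_high.values())
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            exactly = set(universe)
            for n in names:
                if n in combo:
                    exactly &= per_signature_high[n]
                else:
                    exactly -= per_signature_high[n]
            venn[frozenset(combo)] = len(exactly)
    return MycCallSet(
        per_signature_high={k: set(v) for k, v in per_signature_high.items()},
        consensus_high=consensus,
        venn_counts=venn,
        provenance={"signatures": names},
    )
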