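"""Functional similarity of lncRNAs and Gaussian interaction-profile kernels.

Functional similarity follows the best-match-average scheme: each disease in
one lncRNA's disease set is matched to its most semantically similar disease
in the other set, and the matched scores are averaged over both directions.

The interaction-profile kernel treats each entity's row (diseases) or column
(lncRNAs) of the binary association matrix as a profile and applies a
Gaussian kernel whose bandwidth is normalized by the mean squared profile
norm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from lncboost.data_io import InteractionMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class GipConfig:
    """Bandwidth scale mu' (default 0.5) and the normalization rule.

    'divide' sets mu = mu' / mean(||profile||^2) (scale-free bandwidth);
    'multiply_as_printed' sets mu = mu' * mean(||profile||^2).
    """

    mu_prime: float = 0.5
    bandwidth_rule: str = "divide"

    def __post_init__(self) -> None:
        if self.mu_prime <= 0:
            raise ValueError("mu_prime must be > 0")
        if self.bandwidth_rule not in ("divide", "multiply_as_printed"):
            raise ValueError("bandwidth_rule must be 'divide' or 'multiply_as_printed'")


def disease_sets(matrix: InteractionMatrix) -> dict[str, list[str]]:
    """Map each lncRNA to the diseases it is associated with (may be empty)."""
    diseases = matrix.index.diseases
    return {
        lnc: [diseases[i] for i in np.nonzero(matrix.values[:, j])[0]]
        for j, lnc in enumerate(matrix.index.lncrnas)
    }


def ls_best_match(disease: str, target_set: list[str], semantic: SimilarityMatrix) -> float:
    """Best semantic match of ``disease`` against a non-empty disease set."""
    if not target_set:
        raise ValueError("empty target disease set")
    pos = {d: i for i, d in enumerate(semantic.labels)}
    i = pos[disease]
    return max(semantic.values[i, pos[d]] for d in target_set)


def lncfs_pair(
    p: str,
    q: str,
    sets: dict[str, list[str]],
    semantic: SimilarityMatrix,
) -> float:
    """Best-match-average functional similarity between two lncRNAs.

    Returns 0 (flagged upstream) when either disease set is empty.
    """
    dp, dq = sets.get(p, []), sets.get(q, [])
    if not dp or not dq:
        return 0.0
    pos = {d: i for i, d in enumerate(semantic.labels)}
    sub = semantic.values[np.ix_([pos[d] for d in dp], [pos[d] for d in dq])]
    return (sub.max(axis=1).sum() + sub.max(axis=0).sum()) / (len(dp) + len(dq))


def lncfs_matrix(
    sets: dict[str, list[str]],
    semantic: SimilarityMatrix,
    lncrnas: list[str],
    kind: str = "LNCFS1",
) -> SimilarityMatrix:
    """Functional similarity over all lncRNAs (zero rows for empty disease sets)."""
    pos = {d: i for i, d in enumerate(semantic.labels)}
    idx_sets = [np.array([pos[d] for d in sets.get(l, [])], dtype=int) for l in lncrnas]
    n = len(lncrnas)
    out = np.zeros((n, n))
    for a in range(n):
        ia = idx_sets[a]
        if ia.size == 0:
            continue
        for b in range(a, n):
            ib = idx_sets[b]
            if ib.size == 0:
                continue
            sub = semantic.values[np.ix_(ia, ib)]
            out[a, b] = out[b, a] = (sub.max(axis=1).sum() + sub.max(axis=0).sum()) / (
                ia.size + ib.size
            )
    n_empty = sum(1 for s in idx_sets if s.size == 0)
    if n_empty:
        logger.info("lncfs_matrix: %d lncRNAs with empty disease sets", n_empty)
    return SimilarityMatrix(values=out, labels=list(lncrnas), kind=kind)


def gip_similarity(
    matrix: InteractionMatrix, axis: str, config: GipConfig | None = None
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over diseases or lncRNAs.

    ``axis='diseases'`` uses matrix rows as profiles; ``axis='lncrnas'`` uses
    columns. sim(u, v) = exp(-mu * ||u - v||^2) with mu set by the bandwidth
    rule. An all-zero matrix has undefined bandwidth under the 'divide' rule.
    """
    config = config or GipConfig()
    if axis == "diseases":
        profiles = matrix.values.astype(float)
        labels, kind = matrix.index.diseases, "DISGS"
    elif axis == "lncrnas":
        profiles = matrix.values.T.astype(float)
        labels, kind = matrix.index.lncrnas, "LNCGS"
    else:
        raise ValueError("axis must be 'diseases' or 'lncrnas'")
    mean_sq = float(np.mean(np.sum(profiles**2, axis=1)))
    if config.bandwidth_rule == "divide":
        if mean_sq == 0.0:
            raise ValueError("bandwidth undefined: all interaction profiles are zero")
        mu = config.mu_prime / mean_sq
    else:
        mu = config.mu_prime * mean_sq
        if mean_sq == 0.0:
            logger.warning("gip_similarity: zero profiles give a degenerate all-ones kernel")
    if profiles.shape[0] > 1:
        sq = squareform(pdist(profiles, metric="sqeuclidean"))
    else:
        sq = np.zeros((1, 1))
    values = np.exp(-mu * sq)
    return SimilarityMatrix(values=values, labels=list(labels), kind=kind)
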