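"""Synthetic hierarchies and planted lncRNA-disease association structure.

The generator encodes the biological assumption driving the method: lncRNAs
related to the same or semantically close diseases tend to share function.
Diseases and lncRNAs are partitioned into clusters; same-cluster diseases
are placed under a common subtree of a random rooted hierarchy (so semantic
similarity carries real signal), and associations are Bernoulli with a high
within-cluster probability p_in against a low background p_out, plus
optional label noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lncboost.data_io import EntityIndex, HierarchyRecordSet, InteractionMatrix


@dataclass
class SyntheticSpec:
    """Study conditions of the synthetic benchmark (defaults are the ones used
    throughout the test suite and the reproduction script)."""

    n_diseases: int = 60
    n_lncrnas: int = 120
    n_clusters: int = 10
    p_in: float = 0.5
    p_out: float = 0.01
    branching: int = 3
    depth: int = 4
    noise: float = 0.0
    seed: int = 7

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.n_clusters > min(self.n_diseases, self.n_lncrnas):
            raise ValueError("more clusters than diseases or lncRNAs")
        if min(self.n_diseases, self.n_lncrnas, self.n_clusters, self.branching, self.depth) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be in [0, 1]")


@dataclass
class SyntheticBundle:
    hierarchy: HierarchyRecordSet
    interaction: InteractionMatrix
    disease_clusters: np.ndarray = field(default=None)
    lncrna_clusters: np.ndarray = field(default=None)


def _cluster_assignment(n_items: int, n_clusters: int) -> np.ndarray:
    """Contiguous, near-equal cluster blocks."""
    return np.repeat(np.arange(n_clusters), -(-n_items // n_clusters))[:n_items]


def generate_hierarchy(spec: SyntheticSpec) -> HierarchyRecordSet:
    """Random rooted hierarchy with one subtree per cluster.

    Disease ``i`` of cluster ``c`` receives a tree code
    ``T<c>.<seg>...<leaf>`` of total length ``depth``. Cluster members fill
    consecutive leaves of the cluster subtree, so they share not only the
    depth-1 cluster root but typically low-level parents as well (the compact
    disease-category subtrees that real hierarchies exhibit, and the layout
    that makes semantic similarity genuinely informative about cluster
    membership). Different clusters share no node at all. Errors out if the
    subtree cannot host the cluster.
    """
    clusters = _cluster_assignment(spec.n_diseases, spec.n_clusters)
    max_leaves = spec.branching ** (spec.depth - 1)
    counts = np.bincount(clusters, minlength=spec.n_clusters)
    if counts.max() > max_leaves:
        raise ValueError(
            f"cluster of {counts.max()} diseases exceeds the {max_leaves} leaves "
            f"of a branching-{spec.branching} depth-{spec.depth} subtree"
        )
    records: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    next_leaf = np.zeros(spec.n_clusters, dtype=int)
    for i in range(spec.n_diseases):
        c = int(clusters[i])
        leaf, next_leaf[c] = next_leaf[c], next_leaf[c] + 1
        segs = []
        for level in range(spec.depth - 2, -1, -1):
            segs.append((leaf // spec.branching**level) % spec.branching)
        code = f"T{c:02d}" + "".join(f".{s:d}" for s in segs)
        name = f"disease_{i:03d}"
        records[name] = {code}
        term_names[code] = name
    return HierarchyRecordSet(records=records, term_names=term_names)


def generate_planted_associations(
    spec: SyntheticSpec, hierarchy: HierarchyRecordSet
) -> SyntheticBundle:
    """Bernoulli association matrix with planted block structure.

    P(association) = p_in within a (disease cluster, lncRNA cluster) match,
    p_out elsewhere; label-noise flips are applied last. Errors out when the
    expected positive count is zero.
    """
    rng = np.random.default_rng(spec.seed + 1)
    d_clusters = _cluster_assignment(spec.n_diseases, spec.n_clusters)
    l_clusters = _cluster_assignment(spec.n_lncrnas, spec.n_clusters)
    same = d_clusters[:, None] == l_clusters[None, :]
    probs = np.where(same, spec.p_in, spec.p_out)
    if probs.sum() == 0:
        raise ValueError("spec yields zero expected positives")
    values = (rng.random(probs.shape) < probs).astype(np.int8)
    if spec.noise > 0:
        flips = rng.random(values.shape) < spec.noise
        values = np.where(flips, 1 - values, values).astype(np.int8)
    index = EntityIndex(
        diseases=[f"disease_{i:03d}" for i in range(spec.n_diseases)],
        lncrnas=[f"lnc_{j:03d}" for j in range(spec.n_lncrnas)],
    )
    return SyntheticBundle(
        hierarchy=hierarchy,
        interaction=InteractionMatrix(values=values, index=index),
        disease_clusters=d_clusters,
        lncrna_clusters=l_clusters,
    )


def generate_bundle(spec: SyntheticSpec | None = None) -> SyntheticBundle:
    """Hierarchy plus planted association matrix, fully determined by the seed."""
    spec = spec or SyntheticSpec()
    return generate_planted_associations(spec, generate_hierarchy(spec))
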