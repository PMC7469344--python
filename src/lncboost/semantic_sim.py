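"""Disease semantic similarity from hierarchy DAGs.

Two complementary scores are computed over the ancestor DAG of each disease:

* a decay-based score (``DISSS1``): the target term contributes 1 and every
  ancestor contributes ``delta`` times the best contribution among its
  children inside the DAG (so a term's contribution is ``delta**h`` for its
  shortest hop distance ``h`` to the target);
* a frequency-based score (``DISSS2``): every term contributes its corpus
  information content ``-log(n_term / N_d)``, where ``n_term`` counts the
  disease DAGs containing the term.

Pairwise similarity is the shared-ancestor contribution mass normalized by
the two per-disease totals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from lncboost.data_io import EntityIndex, HierarchyRecordSet, SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class SemanticConfig:
    """Knobs of the two semantic scores.

    delta:        contribution decay per hierarchy edge, in (0, 1).
    disss2_sign:  'negative_log' (information content, default) or
                  'as_printed' (literal log, negative values; audit only).
    log_base:     base of the frequency logarithm (natural by default).
    include_target_term: whether the target term's own frequency weight
                  enters its total in the frequency-based score.
    """

    delta: float = 0.5
    disss2_sign: str = "negative_log"
    log_base: float = math.e
    include_target_term: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must be in (0, 1)")
        if self.disss2_sign not in ("negative_log", "as_printed"):
            raise ValueError("disss2_sign must be 'negative_log' or 'as_printed'")


@dataclass
class DiseaseDAG:
    """A disease term plus all of its hierarchy ancestors.

    ``children`` holds parent -> children edges restricted to the node set;
    every non-target node lies on a directed path down to the target.
    """

    target: str
    nodes: frozenset[str]
    children: Mapping[str, frozenset[str]] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not self.nodes


@dataclass
class ContributionMap:
    """Per-node semantic contributions and their total for one disease."""

    values: dict[str, float]
    total: float


def build_disease_dag(disease: str, records: HierarchyRecordSet) -> DiseaseDAG:
    """Union of the prefix chains of all tree codes of ``disease``.

    Each dot-delimited code contributes the chain of its prefixes; a prefix is
    named by the disease owning it as a full code, else by the code string.
    A disease with no hierarchy record yields an empty DAG (logged).
    """
    codes = records.codes_for(disease)
    if not codes:
        logger.warning("build_disease_dag: no hierarchy record for %r", disease)
        return DiseaseDAG(target=disease, nodes=frozenset(), children={})

    def term_of(code: str) -> str:
        return records.term_names.get(code, code)

    nodes: set[str] = {disease}
    children: dict[str, set[str]] = {}
    for code in codes:
        segs = code.split(".")
        chain = [".".join(segs[: i + 1]) for i in range(len(segs))]
        terms = [term_of(c) for c in chain]
        terms[-1] = disease  # full code is the target itself
        for t in terms:
            nodes.add(t)
        for parent, child in zip(terms, terms[1:]):
            if parent != child:
                children.setdefault(parent, set()).add(child)
    return DiseaseDAG(
        target=disease,
        nodes=frozenset(nodes),
        children={p: frozenset(cs) for p, cs in children.items()},
    )


def local_contributions(dag: DiseaseDAG, config: SemanticConfig | None = None) -> ContributionMap:
    """Decay-based contribution of every DAG node to the target.

    The target scores 1; any other node scores ``delta`` times the maximum
    over its children within the DAG, i.e. ``delta**h`` for shortest hop
    distance ``h`` to the target (the max picks the shortest path in
    multi-path DAGs).
    """
    config = config or SemanticConfig()
    if dag.is_empty:
        raise ValueError(f"no semantic record for {dag.target!r}")
    # max over children of delta*DS1 == delta**(shortest hop distance to the
    # target), computed by BFS over reversed edges; iterative, so hierarchies
    # where one disease's code nests inside another's (which can fold the
    # term graph into a cycle) still terminate
    parents: dict[str, set[str]] = {}
    for p, kids in dag.children.items():
        for k in kids:
            parents.setdefault(k, set()).add(p)
    dist = {dag.target: 0}
    frontier = [dag.target]
    while frontier:
        nxt = []
        for node in frontier:
            for par in parents.get(node, ()):
                if par not in dist:
                    dist[par] = dist[node] + 1
                    nxt.append(par)
        frontier = nxt
    missing = dag.nodes - dist.keys()
    if missing:
        raise ValueError(f"nodes with no path to target {dag.target!r}: {sorted(missing)}")
    values = {k: config.delta ** d for k, d in dist.items()}
    return ContributionMap(values=values, total=sum(values.values()))


def disss1_pair(
    dag_i: DiseaseDAG, dag_j: DiseaseDAG, config: SemanticConfig | None = None
) -> float:
    """Decay-based semantic similarity of two diseases (0 if either DAG is empty)."""
    if dag_i.is_empty or dag_j.is_empty:
        return 0.0
    ci = local_contributions(dag_i, config)
    cj = local_contributions(dag_j, config)
    shared = dag_i.nodes & dag_j.nodes
    num = sum(ci.values[k] + cj.values[k] for k in shared)
    return num / (ci.total + cj.total)


def term_frequencies(all_dags: Iterable[DiseaseDAG]) -> dict[str, int]:
    """Number of disease DAGs containing each term."""
    counts: dict[str, int] = {}
    for dag in all_dags:
        for t in dag.nodes:
            counts[t] = counts.get(t, 0) + 1
    return counts


def global_contribution(
    term: str,
    frequencies: Mapping[str, int],
    n_diseases: int,
    config: SemanticConfig | None = None,
) -> float:
    """Frequency-based contribution of a term: -log(n_term / N_d) by default."""
    config = config or SemanticConfig()
    if term not in frequencies:
        raise ValueError(f"term {term!r} appears in no disease DAG")
    ratio = frequencies[term] / n_diseases
    value = math.log(ratio) / math.log(config.log_base)
    return value if config.disss2_sign == "as_printed" else -value


def _global_totals(
    dag: DiseaseDAG,
    frequencies: Mapping[str, int],
    n_diseases: int,
    config: SemanticConfig,
) -> ContributionMap:
    values = {
        k: global_contribution(k, frequencies, n_diseases, config)
        for k in dag.nodes
        if config.include_target_term or k != dag.target
    }
    return ContributionMap(values=values, total=sum(values.values()))


def disss2_pair(
    dag_i: DiseaseDAG,
    dag_j: DiseaseDAG,
    frequencies: Mapping[str, int],
    n_diseases: int,
    config: SemanticConfig | None = None,
) -> float:
    """Frequency-based semantic similarity of two diseases.

    A term shared by every disease carries zero information and contributes
    nothing. When both totals vanish (degenerate corpus) the score is 1 for
    i = j and 0 otherwise, logged.
    """
    config = config or SemanticConfig()
    if dag_i.is_empty or dag_j.is_empty:
        return 0.0
    ci = _global_totals(dag_i, frequencies, n_diseases, config)
    cj = _global_totals(dag_j, frequencies, n_diseases, config)
    denom = ci.total + cj.total
    if denom == 0.0:
        logger.warning("disss2_pair: zero information totals for %r/%r", dag_i.target, dag_j.target)
        return 1.0 if dag_i.target == dag_j.target else 0.0
    shared = dag_i.nodes & dag_j.nodes
    num = sum(ci.values.get(k, 0.0) + cj.values.get(k, 0.0) for k in shared)
    return num / denom


def semantic_similarity_matrices(
    records: HierarchyRecordSet,
    index: EntityIndex,
    config: SemanticConfig | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Both semantic similarity matrices over the diseases of ``index``.

    Rows/columns of diseases with no hierarchy record are all zero (their
    diagonal included, so downstream fusion falls back to the interaction
    kernel for them).
    """
    config = config or SemanticConfig()
    diseases = index.diseases
    n = len(diseases)
    dags = [build_disease_dag(d, records) for d in diseases]
    freqs = term_frequencies(d for d in dags if not d.is_empty)
    s1 = np.zeros((n, n))
    s2 = np.zeros((n, n))
    locals_ = [None if d.is_empty else local_contributions(d, config) for d in dags]
    globals_ = [None if d.is_empty else _global_totals(d, freqs, n, config) for d in dags]
    for i in range(n):
        if dags[i].is_empty:
            continue
        for j in range(i, n):
            if dags[j].is_empty:
                continue
            shared = dags[i].nodes & dags[j].nodes
            ci, cj = locals_[i], locals_[j]
            s1[i, j] = s1[j, i] = sum(
                ci.values[k] + cj.values[k] for k in shared
            ) / (ci.total + cj.total)
            gi, gj = globals_[i], globals_[j]
            denom = gi.total + gj.total
            if denom == 0.0:
                s2[i, j] = s2[j, i] = 1.0 if i == j else 0.0
            else:
                s2[i, j] = s2[j, i] = sum(
                    gi.values.get(k, 0.0) + gj.values.get(k, 0.0) for k in shared
                ) / denom
    n_unmapped = sum(d.is_empty for d in dags)
    if n_unmapped:
        logger.warning("semantic_similarity_matrices: %d diseases without records", n_unmapped)
    return (
        SimilarityMatrix(values=s1, labels=list(diseases), kind="DISSS1"),
        SimilarityMatrix(values=s2, labels=list(diseases), kind="DISSS2"),
    )
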