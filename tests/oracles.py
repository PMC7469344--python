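"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's recursive/memoized code paths: DAG
node sets and edges are re-derived directly from the tree codes, decay
contributions are computed by explicit enumeration of every directed path to
the target, and frequency contributions by explicit corpus counting.
"""

from __future__ import annotations

import math

import numpy as np

from lncboost.data_io import HierarchyRecordSet


def _term_of(code: str, records: HierarchyRecordSet) -> str:
    return records.term_names.get(code, code)


def dag_nodes_edges(disease: str, records: HierarchyRecordSet):
    """Node set and parent->child edge set straight from the prefix chains."""
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for code in records.codes_for(disease):
        segs = code.split(".")
        chain = [".".join(segs[: i + 1]) for i in range(len(segs))]
        terms = [_term_of(c, records) for c in chain]
        terms[-1] = disease
        nodes.update(terms)
        for a, b in zip(terms, terms[1:]):
            if a != b:
                edges.add((a, b))
    return nodes, edges


def _all_path_lengths(start: str, target: str, edges: set[tuple[str, str]]) -> list[int]:
    """Lengths of every simple directed path start -> target."""
    if start == target:
        return [0]
    out = []
    children = {}
    for a, b in edges:
        children.setdefault(a, []).append(b)
    stack = [(start, 0, {start})]
    while stack:
        node, depth, seen = stack.pop()
        for kid in children.get(node, []):
            if kid == target:
                out.append(depth + 1)
            elif kid not in seen:
                stack.append((kid, depth + 1, seen | {kid}))
    return out


def ds1_oracle(disease: str, records: HierarchyRecordSet, delta: float) -> dict[str, float]:
    """Decay contribution of every DAG node, by explicit path enumeration."""
    nodes, edges = dag_nodes_edges(disease, records)
    out = {}
    for k in nodes:
        lengths = _all_path_lengths(k, disease, edges)
        assert lengths, f"node {k} has no path to target {disease}"
        out[k] = max(delta**L for L in lengths)
    return out


def disss1_oracle(di: str, dj: str, records: HierarchyRecordSet, delta: float) -> float:
    ci = ds1_oracle(di, records, delta)
    cj = ds1_oracle(dj, records, delta)
    shared = set(ci) & set(cj)
    return sum(ci[k] + cj[k] for k in shared) / (sum(ci.values()) + sum(cj.values()))


def disss2_oracle(di: str, dj: str, diseases: list[str], records: HierarchyRecordSet) -> float:
    """Frequency-based similarity with -log information content, by counting."""
    node_sets = {d: dag_nodes_edges(d, records)[0] for d in diseases}
    n_d = len(diseases)

    def ic(term: str) -> float:
        count = sum(1 for s in node_sets.values() if term in s)
        return -math.log(count / n_d)

    ti, tj = node_sets[di], node_sets[dj]
    d2i = sum(ic(k) for k in ti)
    d2j = sum(ic(k) for k in tj)
    if d2i + d2j == 0:
        return 1.0 if di == dj else 0.0
    return sum(2 * ic(k) for k in ti & tj) / (d2i + d2j)


def random_hierarchy(rng: np.random.Generator, n_diseases: int, max_depth: int = 4):
    """Random record set over a small segment alphabet (shared ancestors likely)."""
    records: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    used: set[str] = set()
    for i in range(n_diseases):
        name = f"dis{i}"
        n_codes = 1 + int(rng.random() < 0.3)
        codes: set[str] = set()
        while len(codes) < n_codes:
            depth = int(rng.integers(1, max_depth + 1))
            code = ".".join(str(rng.integers(3)) for _ in range(depth))
            if code not in used:
                codes.add(code)
                used.add(code)
        records[name] = codes
        for c in codes:
            term_names[c] = name
    return HierarchyRecordSet(records=records, term_names=term_names)


def auc_concordance_oracle(scores, labels) -> float:
    """Mann-Whitney concordance probability with ties counted one half."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))
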