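"""Greedy model alignment from precalculated element similarities.

An alignment arranges elements from two or more models into disjoint,
type-homogeneous tuples (at most one element per model per tuple; singletons
allowed).  The greedy matcher repeatedly takes the highest remaining positive
similarity pair; a pair whose merge would place two elements of one model in
the same tuple is discarded, which keeps the matching non-ambiguous and, for
three or more models, transitive by construction.  The alignment score is the
sum of pairwise similarities inside tuples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model_io import NetworkModel
from .propagation import (
    PropagationWeights,
    build_pair_graph,
    build_propagation_matrix,
    feature_propagate,
    similarity_propagate,
)
from .semantic_features import (
    ConceptSimilarity,
    ConceptSpace,
    build_concept_space,
    featurize,
    pairwise_similarity,
)

MEASURES = ("direct", "fp", "sp")

#: similarities at or below this are numerical dust, never matched
SCORE_EPS = 1e-12

Node = tuple[str, str]  # (model_id, element_id)


@dataclass
class SimilarityTable:
    """Pairwise similarities psi between same-type elements of two models."""

    model_m: str
    model_n: str
    scores: dict[tuple[str, str], float]
    measure: str = "direct"

    def get(self, eid_m: str, eid_n: str) -> float:
        return self.scores.get((eid_m, eid_n), 0.0)


@dataclass
class Alignment:
    """Disjoint typed element tuples across models, plus the total score."""

    tuples: list[frozenset[Node]]
    score: float = 0.0

    def matched_pairs(self) -> set[frozenset[Node]]:
        """All cross-model pairs implied by the tuples (transitively closed)."""
        pairs: set[frozenset[Node]] = set()
        for tup in self.tuples:
            members = sorted(tup)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs.add(frozenset((members[i], members[j])))
        return pairs


def compute_similarity_table(
    model_m: NetworkModel,
    model_n: NetworkModel,
    measure: str = "direct",
    *,
    space: ConceptSpace | None = None,
    S: ConceptSimilarity | None = None,
    weights: PropagationWeights | None = None,
    lam: float | None = None,
    max_steps: int | None = None,
) -> SimilarityTable:
    """Compute direct, FP or SP similarities between two models.

    Only same-type pairs are scored; cross-type similarities are fixed to 0 by
    omission.  ``lam``/``max_steps`` override the spectral-radius lambda and
    the full fixed-point solve (used e.g. to reproduce single-step propagation
    closed forms).
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    weights = weights or PropagationWeights()
    if space is None:
        space = build_concept_space([model_m, model_n])
    Vm = featurize(model_m, space)
    Vn = featurize(model_n, space)
    types_m = model_m.element_types()
    types_n = model_n.element_types()

    if measure in ("direct", "fp"):
        if measure == "fp":
            Rm = build_propagation_matrix(model_m, weights)
            Rn = build_propagation_matrix(model_n, weights)
            Vm = feature_propagate(Vm, Rm, lam, lambda_fraction=weights.lambda_fraction,
                                   max_steps=max_steps)
            Vn = feature_propagate(Vn, Rn, lam, lambda_fraction=weights.lambda_fraction,
                                   max_steps=max_steps)
        psi = pairwise_similarity(Vm, Vn, S)
        scores = {
            (xid, yid): float(psi[i, j])
            for i, xid in enumerate(Vm.element_ids)
            for j, yid in enumerate(Vn.element_ids)
            if types_m[xid] == types_n[yid] and psi[i, j] > SCORE_EPS
        }
        return SimilarityTable(model_m.model_id, model_n.model_id, scores, measure)

    # similarity propagation on the pair graph
    Rm = build_propagation_matrix(model_m, weights)
    Rn = build_propagation_matrix(model_n, weights)
    Q = build_pair_graph(Rm, Rn, types_m, types_n)
    sigma_full = pairwise_similarity(Vm, Vn, S)
    row = {eid: i for i, eid in enumerate(Vm.element_ids)}
    col = {eid: j for j, eid in enumerate(Vn.element_ids)}
    sigma = np.array([sigma_full[row[x], col[y]] for x, y in Q.pair_ids])
    psi_vec = similarity_propagate(sigma, Q, lam, lambda_fraction=weights.lambda_fraction,
                                   max_steps=max_steps)
    scores = {
        pair: float(v) for pair, v in zip(Q.pair_ids, psi_vec) if v > SCORE_EPS
    }
    return SimilarityTable(model_m.model_id, model_n.model_id, scores, measure)


class _TupleSet:
    """Union-find over (model_id, element_id) nodes with the one-element-per-
    model constraint enforced at merge time."""

    def __init__(self) -> None:
        self.parent: dict[Node, Node] = {}
        self.members: dict[Node, set[Node]] = {}

    def add(self, node: Node) -> None:
        if node not in self.parent:
            self.parent[node] = node
            self.members[node] = {node}

    def find(self, node: Node) -> Node:
        root = node
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[node] != root:
            self.parent[node], node = root, self.parent[node]
        return root

    def can_merge(self, a: Node, b: Node) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        models_a = {m for m, _ in self.members[ra]}
        models_b = {m for m, _ in self.members[rb]}
        return not (models_a & models_b)

    def merge(self, a: Node, b: Node) -> None:
        ra, rb = self.find(a), self.find(b)
        if len(self.members[ra]) < len(self.members[rb]):
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.members[ra] |= self.members.pop(rb)

    def groups(self) -> list[frozenset[Node]]:
        return [frozenset(group) for group in self.members.values()]


def greedy_align(
    tables: Mapping[tuple[str, str], SimilarityTable] | Sequence[SimilarityTable],
    models: Sequence[NetworkModel],
) -> Alignment:
    """Greedy score-maximising matching over two or more models.

    Candidate pairs from all model pairs go into one priority queue ordered by
    descending similarity, ties broken lexicographically by the (model_id,
    element_id) node labels so the result is deterministic.  A candidate whose
    merge would collide two elements of one model is discarded; otherwise the
    two tuples are merged, which also merges all previously matched partners
    (transitivity).  The final score sums the table similarities over every
    cross-model pair inside the resulting tuples.
    """
    if len(models) < 2:
        raise ValueError("alignment needs at least 2 models")
    if isinstance(tables, Mapping):
        table_list = list(tables.values())
    else:
        table_list = list(tables)
    by_pair: dict[frozenset[str], SimilarityTable] = {}
    for t in table_list:
        by_pair[frozenset((t.model_m, t.model_n))] = t
    model_ids = [m.model_id for m in models]
    for i in range(len(model_ids)):
        for j in range(i + 1, len(model_ids)):
            if frozenset((model_ids[i], model_ids[j])) not in by_pair:
                raise ValueError(
                    f"missing similarity table for model pair "
                    f"({model_ids[i]!r}, {model_ids[j]!r})"
                )

    types: dict[Node, str] = {}
    tuples = _TupleSet()
    for model in models:
        for eid, el in model.elements.items():
            node = (model.model_id, eid)
            tuples.add(node)
            types[node] = el.element_type

    # one global candidate heap across all model pairs
    heap: list[tuple[float, Node, Node]] = []
    for t in table_list:
        for (xid, yid), psi in t.scores.items():
            if psi > SCORE_EPS:
                a, b = sorted([(t.model_m, xid), (t.model_n, yid)])
                heap.append((-psi, a, b))
    heap.sort()  # deterministic total order: score desc, then lexicographic nodes

    for neg_psi, a, b in heap:
        if types[a] != types[b]:
            continue  # cross-type candidates are never admissible
        if tuples.can_merge(a, b):
            tuples.merge(a, b)

    result = Alignment(sorted(tuples.groups(), key=lambda g: sorted(g)))
    lookup = {
        frozenset((t.model_m, t.model_n)): t for t in table_list
    }
    score = 0.0
    for pair in result.matched_pairs():
        (ma, ea), (mb, eb) = sorted(pair)
        table = lookup.get(frozenset((ma, mb)))
        if table is None:
            continue
        if table.model_m == ma:
            score += table.get(ea, eb)
        else:
            score += table.get(eb, ea)
    result.score = score
    _check_alignment(result, models)
    return result


def _check_alignment(alignment: Alignment, models: Sequence[NetworkModel]) -> None:
    seen: set[Node] = set()
    types = {
        (m.model_id, eid): el.element_type
        for m in models
        for eid, el in m.elements.items()
    }
    for tup in alignment.tuples:
        model_ids = [m for m, _ in tup]
        if len(model_ids) != len(set(model_ids)):
            raise AssertionError("tuple holds two elements of one model")
        if len({types[node] for node in tup}) != 1:
            raise AssertionError("tuple mixes element types")
        if tup & seen:
            raise AssertionError("tuples are not disjoint")
        seen |= tup


def evaluate_alignment(predicted: Alignment, reference: Alignment) -> tuple[float, float]:
    """Precision and recall of matched pairs against a reference alignment.

    Pairs are counted inside tuples (singletons contribute nothing).  With no
    predicted pairs precision is 1 by convention; with no reference pairs
    recall is 1.
    """
    pred = predicted.matched_pairs()
    ref = reference.matched_pairs()
    correct = len(pred & ref)
    precision = correct / len(pred) if pred else 1.0
    recall = correct / len(ref) if ref else 1.0
    return precision, recall


def identity_alignment(
    model_m: NetworkModel,
    model_n: NetworkModel,
    element_types: Iterable[str] = ("species", "reaction"),
) -> Alignment:
    """Reference alignment matching equal element ids across two models."""
    types = set(element_types)
    tuples = []
    matched_m: set[str] = set()
    for eid, el in model_m.elements.items():
        other = model_n.elements.get(eid)
        if el.element_type in types and other is not None and other.element_type == el.element_type:
            tuples.append(frozenset({(model_m.model_id, eid), (model_n.model_id, eid)}))
            matched_m.add(eid)
    return Alignment(sorted(tuples, key=lambda g: sorted(g)))


def write_alignment(alignment: Alignment, path: str | Path,
                    tables: Sequence[SimilarityTable] | None = None) -> None:
    """Write an alignment as TSV: one tuple per line (model:element columns),
    the tuple's internal score, then a trailing total-score summary line."""
    lookup = {}
    if tables:
        lookup = {frozenset((t.model_m, t.model_n)): t for t in tables}
    lines = []
    for tup in alignment.tuples:
        members = sorted(tup)
        tup_score = 0.0
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                (ma, ea), (mb, eb) = members[i], members[j]
                table = lookup.get(frozenset((ma, mb)))
                if table is not None:
                    tup_score += table.get(ea, eb) if table.model_m == ma else table.get(eb, ea)
        cols = "\t".join(f"{m}:{e}" for m, e in members)
        lines.append(f"{cols}\t{tup_score:.6g}")
    lines.append(f"# total_score\t{alignment.score:.6g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
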