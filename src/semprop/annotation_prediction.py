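"""Annotation prediction from a leave-one-feature-out collection.

A corpus of annotated models stands in for a large curated pathway map.  Every
corpus element contributes one collection entry per annotation concept: the
element's propagated feature vector with that concept's own component zeroed,
tagged with the concept and its provenance.  A query element's propagated
vector is then compared (cosine) against all entries; the concepts of the most
similar entries are ranked suggestions.

Prediction uses a deliberately restricted propagation: transfer only between
reactions and their reactants/products, weight 1/2 in both directions, and a
single propagation step (the series is truncated at k = 1 with lambda = 1).
This keeps suggestion lists short -- an element inherits only from its direct
neighbours -- and makes the single-hidden-annotation case exactly recoverable:
the query vector then equals the held-out entry's vector, so the hidden
concept scores cosine 1 and ranks first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .model_io import ModelElement, NetworkModel
from .propagation import PropagationMatrix, PropagationWeights, _cofactor_element_ids
from .semantic_features import ConceptSpace, FeatureMatrix, featurize

logger = logging.getLogger(__name__)

#: reaction <-> reactant/product transfer weight in prediction mode
PREDICTION_RHO = 0.5


@dataclass
class AnnotationCollection:
    """Indexed (concept, propagated-vector, provenance) entries."""

    space: ConceptSpace
    concepts: list[str] = field(default_factory=list)
    vectors: np.ndarray | None = None  # entries x dimension, rows non-negative
    provenance: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.concepts)


def prediction_propagation_matrix(
    model: NetworkModel, weights: PropagationWeights | None = None, rho: float = PREDICTION_RHO
) -> PropagationMatrix:
    """Prediction-mode transfer matrix: rho between reaction and
    reactant/product species (both directions), all other roles zero.
    Cofactor blocking still applies."""
    weights = weights or PropagationWeights()
    element_ids = tuple(model.element_ids)
    index = {eid: i for i, eid in enumerate(element_ids)}
    blocked = _cofactor_element_ids(model, weights.cofactor_ids)
    mat = sp.dok_matrix((len(element_ids), len(element_ids)))
    for ref in model.references:
        if ref.role not in ("reactant", "product"):
            continue
        if ref.source_id in blocked or ref.target_id in blocked:
            continue
        i, j = index[ref.source_id], index[ref.target_id]
        mat[i, j] = rho
        mat[j, i] = rho
    return PropagationMatrix(element_ids, mat.tocsr())


def prediction_propagate(
    model: NetworkModel,
    space: ConceptSpace,
    weights: PropagationWeights | None = None,
    rho: float = PREDICTION_RHO,
) -> FeatureMatrix:
    """One-step propagated features W = V + rho * A V with A the
    reaction-reactant/product adjacency (lambda = 1, series truncated at 1)."""
    V = featurize(model, space)
    R = prediction_propagation_matrix(model, weights, rho)
    W = V.values + R.matrix @ V.values
    return FeatureMatrix(space, V.element_ids, W)


def build_collection(
    corpus: Sequence[NetworkModel],
    space: ConceptSpace,
    weights: PropagationWeights | None = None,
) -> AnnotationCollection:
    """Leave-one-feature-out collection over a corpus.

    For each element x and each of its annotation concepts i, add the entry
    (i, w_x with component i set to 0, (model_id, element_id)).  Elements
    without annotations contribute nothing.
    """
    concepts: list[str] = []
    vectors: list[np.ndarray] = []
    provenance: list[tuple[str, str]] = []
    index = {key: i for i, key in enumerate(space.concepts)}
    for model in corpus:
        W = prediction_propagate(model, space, weights)
        V = featurize(model, space)
        for row, eid in enumerate(W.element_ids):
            own = np.nonzero(V.values[row])[0]
            for col in own:
                vec = W.values[row].copy()
                vec[col] = 0.0
                concepts.append(space.concepts[col])
                vectors.append(vec)
                provenance.append((model.model_id, eid))
    stacked = (
        np.vstack(vectors) if vectors else np.zeros((0, space.dimension))
    )
    return AnnotationCollection(space, concepts, stacked, provenance)


def predict_annotations(
    element: ModelElement | str,
    model: NetworkModel,
    collection: AnnotationCollection,
    top_n: int = 10,
    weights: PropagationWeights | None = None,
    query_features: FeatureMatrix | None = None,
) -> list[tuple[str, float]]:
    """Rank candidate concepts for one element of a (partially annotated) model.

    The element's prediction-mode propagated vector is compared by cosine
    against every collection entry; concepts are de-duplicated keeping the
    best score and truncated to ``top_n``.  A zero query vector (no own and no
    neighbouring annotations) yields an empty list.  ``query_features`` may
    pass a precomputed :func:`prediction_propagate` result for the model.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    eid = element.element_id if isinstance(element, ModelElement) else element
    if eid not in model.elements:
        raise KeyError(f"element {eid!r} not in model {model.model_id!r}")
    W = query_features or prediction_propagate(model, collection.space, weights)
    query = W.row(eid)
    qnorm = np.linalg.norm(query)
    if qnorm < 1e-15:
        logger.info("element %s has an empty propagated vector; no predictions", eid)
        return []
    if len(collection) == 0:
        return []
    vecs = collection.vectors
    norms = np.linalg.norm(vecs, axis=1)
    ok = norms > 1e-15
    sims = np.zeros(len(collection))
    sims[ok] = (vecs[ok] @ query) / (norms[ok] * qnorm)
    best: dict[str, float] = {}
    for concept, s in zip(collection.concepts, sims):
        if s > best.get(concept, -1.0):
            best[concept] = float(s)
    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


def predict_for_model(
    model: NetworkModel,
    collection: AnnotationCollection,
    top_n: int = 10,
    weights: PropagationWeights | None = None,
    only_unannotated: bool = True,
) -> dict[str, list[tuple[str, float]]]:
    """Predictions for every (by default non-annotated) element of a model."""
    out: dict[str, list[tuple[str, float]]] = {}
    W = prediction_propagate(model, collection.space, weights)
    for eid, el in model.elements.items():
        if only_unannotated and el.annotations:
            continue
        ranked = predict_annotations(eid, model, collection, top_n, weights, query_features=W)
        if ranked:
            out[eid] = ranked
    return out


def concept_to_annotation_key(concept: str) -> tuple[str, str]:
    """Split a default-form concept key ``resource:identifier`` back into its
    (resource, identifier) pair; equivalence-class keys split at the first colon."""
    resource, _, identifier = concept.partition(":")
    return resource, identifier or concept
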