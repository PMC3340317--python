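"""Concept spaces, feature vectors and the direct semantic similarity.

Each model element is described by a feature vector over a shared space of
*biological concepts*.  A concept groups database entries that mean the same
thing (e.g. a ChEBI and a KEGG Compound entry for the same sugar) via an
optional equivalence table; without equivalences each distinct
(resource, identifier) pair is its own concept.

The direct similarity between two elements is a normalised quadratic form

    sigma(x, y) = v_x' S v_y / sqrt((v_x' S v_x)(v_y' S v_y))

over their direct feature vectors, with sigma = 0 whenever either vector is
zero (non-annotated elements carry no information).  With S = identity this is
the plain cosine similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .model_io import Annotation, NetworkModel

logger = logging.getLogger(__name__)

#: denominators below this are treated as zero vectors -> similarity 0
ZERO_NORM_TOL = 1e-15


@dataclass(frozen=True)
class ConceptSpace:
    """Ordered list of concept keys plus the (resource, identifier) -> key map."""

    concepts: tuple[str, ...]
    equivalence_map: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.concepts)) != len(self.concepts):
            raise ValueError("concept keys must be unique")
        index = set(self.concepts)
        for key in self.equivalence_map.values():
            if key not in index:
                raise ValueError(f"equivalence target {key!r} is not a listed concept")

    @property
    def dimension(self) -> int:
        return len(self.concepts)

    def index_of(self, concept: str) -> int:
        try:
            return self.concepts.index(concept)
        except ValueError:
            raise KeyError(f"unknown concept {concept!r}") from None

    def concept_for(self, annotation: Annotation | tuple[str, str]) -> str:
        key = annotation.key if isinstance(annotation, Annotation) else tuple(annotation)
        return self.equivalence_map.get(key, f"{key[0]}:{key[1]}")


@dataclass
class FeatureMatrix:
    """Per-element feature vectors (rows) over a concept space (columns)."""

    space: ConceptSpace
    element_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.element_ids), self.space.dimension):
            raise ValueError("feature matrix shape does not match ids x concepts")
        if self.values.size and self.values.min() < 0:
            raise ValueError("feature values must be non-negative")

    def row(self, element_id: str) -> np.ndarray:
        return self.values[self.element_ids.index(element_id)]


@dataclass
class ConceptSimilarity:
    """Symmetric PSD concept-concept similarity matrix S with unit diagonal."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("S must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("S must be symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=1e-12):
            raise ValueError("S must have unit diagonal")

    @classmethod
    def identity(cls, dimension: int) -> "ConceptSimilarity":
        return cls(np.eye(dimension))


def build_concept_space(
    models: Iterable[NetworkModel],
    equivalences: Mapping[tuple[str, str], str] | None = None,
) -> ConceptSpace:
    """Collect all concepts annotated anywhere in ``models``.

    Synonym groups declared in ``equivalences`` collapse to a single concept.
    Concepts are sorted by key, so the space is deterministic.
    """
    equivalences = dict(equivalences or {})
    keys: set[str] = set()
    for model in models:
        for element in model.elements.values():
            for ann in element.annotations:
                keys.add(equivalences.get(ann.key, f"{ann.resource}:{ann.identifier}"))
    keys.update(equivalences.values())
    return ConceptSpace(tuple(sorted(keys)), equivalences)


def featurize(model: NetworkModel, space: ConceptSpace) -> FeatureMatrix:
    """Binary direct feature vectors: entry (x, i) = 1 iff element x carries an
    annotation mapping to concept i.  Non-annotated elements get zero rows."""
    index = {key: i for i, key in enumerate(space.concepts)}
    element_ids = tuple(model.element_ids)
    values = np.zeros((len(element_ids), space.dimension))
    for row, eid in enumerate(element_ids):
        for ann in model.elements[eid].annotations:
            concept = space.concept_for(ann)
            col = index.get(concept)
            if col is None:
                logger.warning(
                    "annotation %s:%s on %s maps to no concept in space; dropped",
                    ann.resource,
                    ann.identifier,
                    eid,
                )
                continue
            values[row, col] = 1.0
    return FeatureMatrix(space, element_ids, values)


def direct_similarity(
    vx: np.ndarray, vy: np.ndarray, S: ConceptSimilarity | None = None
) -> float:
    """Normalised quadratic-form similarity between two feature vectors.

    Returns 0 if either vector is (numerically) zero in the S norm.  With the
    default S = identity this is the cosine similarity.
    """
    vx = np.asarray(vx, dtype=float)
    vy = np.asarray(vy, dtype=float)
    if vx.shape != vy.shape:
        raise ValueError(f"dimension mismatch: {vx.shape} vs {vy.shape}")
    if S is None:
        num = float(vx @ vy)
        nx = float(vx @ vx)
        ny = float(vy @ vy)
    else:
        if S.matrix.shape[0] != vx.shape[0]:
            raise ValueError("S dimension does not match vectors")
        Svy = S.matrix @ vy
        num = float(vx @ Svy)
        nx = float(vx @ (S.matrix @ vx))
        ny = float(vy @ Svy)
    denom = np.sqrt(nx * ny)
    if denom < ZERO_NORM_TOL:
        return 0.0
    return num / denom


def pairwise_similarity(
    fm_x: FeatureMatrix, fm_y: FeatureMatrix, S: ConceptSimilarity | None = None
) -> np.ndarray:
    """Similarity of every row of ``fm_x`` against every row of ``fm_y``.

    Vectorised version of :func:`direct_similarity`; rows with zero S-norm get
    similarity 0 everywhere.
    """
    X, Y = fm_x.values, fm_y.values
    M = S.matrix if S is not None else None
    G = X @ (M @ Y.T) if M is not None else X @ Y.T
    nx = np.einsum("ij,ij->i", X, X @ M.T if M is not None else X)
    ny = np.einsum("ij,ij->i", Y, Y @ M.T if M is not None else Y)
    sx = np.sqrt(np.maximum(nx, 0.0))
    sy = np.sqrt(np.maximum(ny, 0.0))
    denom = np.outer(sx, sy)
    out = np.zeros_like(G)
    ok = denom >= ZERO_NORM_TOL
    out[ok] = G[ok] / denom[ok]
    return out


def read_equivalence_table(path: str | Path) -> dict[tuple[str, str], str]:
    """Read a synonym table (TSV: resource, identifier, concept_key)."""
    mapping: dict[tuple[str, str], str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "resource":  # header
            continue
        if len(parts) != 3:
            raise ValueError(f"bad equivalence row: {line!r}")
        mapping[(parts[0].lower(), parts[1])] = parts[2]
    return mapping


def read_concept_similarity(path: str | Path, space: ConceptSpace) -> ConceptSimilarity:
    """Read a whitespace-separated S matrix with a header row of concept keys.

    The matrix is re-ordered to the given space; concepts absent from the file
    get identity rows.
    """
    lines = [l for l in Path(path).read_text(encoding="utf-8").splitlines() if l.strip()]
    header = lines[0].split()
    raw = np.array([[float(v) for v in line.split()] for line in lines[1:]])
    if raw.shape != (len(header), len(header)):
        raise ValueError("S matrix shape does not match its header")
    S = np.eye(space.dimension)
    pos = {key: i for i, key in enumerate(space.concepts)}
    for i, ki in enumerate(header):
        for j, kj in enumerate(header):
            if ki in pos and kj in pos:
                S[pos[ki], pos[kj]] = raw[i, j]
    return ConceptSimilarity(S)
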