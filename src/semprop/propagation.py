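"""Feature propagation (FP) and similarity propagation (SP) on reaction networks.

Both schemes spread semantic information along the references of a model.  The
strength of transfer is encoded in a sparse |M| x |M| propagation matrix R:
entry (x, a) = alpha when reaction x refers to species a as reactant or
product, entry (a, x) = beta for the reverse direction, with separate weights
for modifier and compartment edges.  Propagation is blocked at cofactor
species (currency metabolites such as ATP or water), whose rows and columns
are zeroed so that hub species cannot transfer similarity between unrelated
reactions.

Feature propagation solves the self-consistent system

    W = V + lambda R W        i.e.   W = (I - lambda R)^{-1} V

for the inferred feature matrix W given direct features V.  Similarity
propagation works on a *pair graph* whose nodes are same-type element pairs
(x in M, y in N) and whose transfer matrix is

    Q_{(x,y),(a,p)} = R^M_{xa} * R^N_{yp},

solving  psi = sigma + lambda Q psi  for the inferred pair similarities.

The scaling factor lambda is chosen below the inverse spectral radius of the
transfer matrix (default lambda = 1/(2r)) so the equivalent Neumann series
sum_k (lambda R)^k converges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model_io import NetworkModel
from .semantic_features import ConceptSimilarity, FeatureMatrix, direct_similarity

logger = logging.getLogger(__name__)

#: shipped default cofactor list: common currency metabolites as ChEBI entries.
DEFAULT_COFACTORS: frozenset[tuple[str, str]] = frozenset(
    {
        ("chebi", "CHEBI:15422"),  # ATP
        ("chebi", "CHEBI:16761"),  # ADP
        ("chebi", "CHEBI:16027"),  # AMP
        ("chebi", "CHEBI:15846"),  # NAD(+)
        ("chebi", "CHEBI:16908"),  # NADH
        ("chebi", "CHEBI:18009"),  # NADP(+)
        ("chebi", "CHEBI:16474"),  # NADPH
        ("chebi", "CHEBI:15377"),  # water
        ("chebi", "CHEBI:15378"),  # proton
        ("chebi", "CHEBI:18367"),  # phosphate
        ("chebi", "CHEBI:16526"),  # CO2
        ("chebi", "CHEBI:15379"),  # O2
    }
)

#: below 50 elements a dense eigensolve is cheaper and always converges
DENSE_EIG_LIMIT = 50


@dataclass(frozen=True)
class PropagationWeights:
    """Transfer weights for building propagation matrices.

    alpha: species -> reaction transfer (entry (reaction, species)).
    beta: reaction -> species transfer (entry (species, reaction)).
    modifier_weight: both directions along modifier (enzyme/regulator) edges.
    compartment_weight: both directions along compartment-of edges.
    lambda_fraction: multiplier c in lambda = c / r, 0 < c < 1 required for the
        full fixed-point solve (r is the transfer matrix's spectral radius).
    cofactor_ids: (resource, identifier) pairs marking cofactor species at
        which propagation stops.
    """

    alpha: float = 0.5
    beta: float = 0.5
    modifier_weight: float = 0.5
    compartment_weight: float = 0.0
    lambda_fraction: float = 0.5
    cofactor_ids: frozenset[tuple[str, str]] = DEFAULT_COFACTORS

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "modifier_weight", "compartment_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.lambda_fraction < 1:
            raise ValueError("lambda_fraction must lie in (0, 1)")


@dataclass
class PropagationMatrix:
    """Sparse per-model transfer matrix R, indexed like the model's elements."""

    element_ids: tuple[str, ...]
    matrix: sp.csr_matrix

    @property
    def n(self) -> int:
        return len(self.element_ids)


@dataclass
class PairGraph:
    """Pair propagation graph for two models: nodes are same-type element
    pairs (x in M, y in N), edge weights Q_{(x,y),(a,p)} = R^M_xa * R^N_yp."""

    pair_ids: tuple[tuple[str, str], ...]
    matrix: sp.csr_matrix

    @property
    def n(self) -> int:
        return len(self.pair_ids)

    def index(self) -> dict[tuple[str, str], int]:
        return {pair: i for i, pair in enumerate(self.pair_ids)}


def _cofactor_element_ids(model: NetworkModel, cofactor_ids: Iterable[tuple[str, str]]) -> set[str]:
    cofset = {(r.lower(), i) for r, i in cofactor_ids}
    blocked = set()
    for el in model.elements_of_type("species"):
        if any((ann.resource, ann.identifier) in cofset for ann in el.annotations):
            blocked.add(el.element_id)
    return blocked


def build_propagation_matrix(
    model: NetworkModel, weights: PropagationWeights | None = None
) -> PropagationMatrix:
    """Build the sparse transfer matrix R for one model.

    Reactant/product references between reaction x and species a produce
    entries R[x, a] = alpha and R[a, x] = beta; modifier and compartment-of
    edges get their own (symmetric) weights.  All entries touching a cofactor
    species are zero.
    """
    weights = weights or PropagationWeights()
    element_ids = tuple(model.element_ids)
    index = {eid: i for i, eid in enumerate(element_ids)}
    blocked = _cofactor_element_ids(model, weights.cofactor_ids)

    mat = sp.dok_matrix((len(element_ids), len(element_ids)))
    for ref in model.references:
        if ref.source_id in blocked or ref.target_id in blocked:
            continue
        i, j = index[ref.source_id], index[ref.target_id]
        if ref.role in ("reactant", "product"):
            # source is the reaction, target the species
            mat[i, j] = weights.alpha
            mat[j, i] = weights.beta
        elif ref.role == "modifier":
            mat[i, j] = weights.modifier_weight
            mat[j, i] = weights.modifier_weight
        elif ref.role == "compartment-of":
            mat[i, j] = weights.compartment_weight
            mat[j, i] = weights.compartment_weight
    csr = mat.tocsr()
    csr.eliminate_zeros()
    return PropagationMatrix(element_ids, csr)


def spectral_radius(matrix: sp.spmatrix | np.ndarray) -> float:
    """Largest absolute eigenvalue, sparse for large matrices with a dense
    fallback below :data:`DENSE_EIG_LIMIT` and a power-iteration last resort."""
    A = sp.csr_matrix(matrix)
    n = A.shape[0]
    if n == 0 or A.nnz == 0:
        return 0.0
    if n < DENSE_EIG_LIMIT:
        return float(np.max(np.abs(np.linalg.eigvals(A.toarray()))))
    try:
        vals = spla.eigs(A.astype(float), k=1, which="LM", return_eigenvectors=False,
                         maxiter=n * 100)
        return float(np.abs(vals[0]))
    except Exception as exc:  # ARPACK can fail on defective/near-degenerate inputs
        logger.warning("sparse eigensolve failed (%s); falling back to power iteration", exc)
        rng = np.random.default_rng(0)
        v = rng.standard_normal(n)
        r = 0.0
        for _ in range(1000):
            w = np.abs(A) @ np.abs(v)
            norm = np.linalg.norm(w)
            if norm == 0:
                return 0.0
            r, v = norm / np.linalg.norm(v), w / norm
        return float(r)


def choose_lambda(matrix: sp.spmatrix | np.ndarray, lambda_fraction: float = 0.5) -> float:
    """lambda = lambda_fraction / r with r the spectral radius; if r = 0 the
    propagation series terminates at k = 0 and lambda = 1 by convention."""
    if isinstance(matrix, (PropagationMatrix, PairGraph)):
        matrix = matrix.matrix
    r = spectral_radius(matrix)
    if r <= 1e-300:
        return 1.0
    return lambda_fraction / r


def _solve_or_series(
    A: sp.csr_matrix, rhs: np.ndarray, lam: float, max_steps: int | None
) -> np.ndarray:
    if max_steps is None:
        r = spectral_radius(A)
        if lam * r >= 1.0:
            raise ValueError(
                f"lambda * spectral_radius = {lam * r:.6g} >= 1: propagation series diverges"
            )
        system = sp.identity(A.shape[0], format="csc") - lam * A.tocsc()
        solve = spla.factorized(system)
        out = solve(np.asarray(rhs, dtype=float))
        return np.asarray(out)
    # truncated Neumann series sum_{k=0..K} (lam A)^k rhs
    term = np.asarray(rhs, dtype=float).copy()
    acc = term.copy()
    for _ in range(max_steps):
        term = lam * (A @ term)
        acc = acc + term
    return acc


def feature_propagate(
    V: FeatureMatrix,
    R: PropagationMatrix,
    lam: float | None = None,
    *,
    lambda_fraction: float = 0.5,
    max_steps: int | None = None,
) -> FeatureMatrix:
    """Solve W = V + lambda R W for the inferred feature matrix W.

    Implemented as a sparse LU solve of (I - lambda R) W = V (never an
    explicit inverse).  ``max_steps`` switches to the truncated propagation
    series instead, which needs no convergence condition.  Elements receiving
    no transfer keep their direct vectors (w_x = v_x).
    """
    if tuple(V.element_ids) != tuple(R.element_ids):
        raise ValueError("feature matrix and propagation matrix index different elements")
    if lam is None:
        lam = choose_lambda(R.matrix, lambda_fraction)
    W = _solve_or_series(R.matrix, V.values, lam, max_steps)
    # numerical dust from the LU solve may dip microscopically below zero
    W[np.abs(W) < 1e-14] = 0.0
    return FeatureMatrix(V.space, V.element_ids, np.maximum(W, 0.0))


def inferred_fp_similarity(
    wx: np.ndarray, wy: np.ndarray, S: ConceptSimilarity | None = None
) -> float:
    """FP similarity: the direct-similarity quadratic form applied to inferred
    vectors w instead of direct vectors v."""
    return direct_similarity(wx, wy, S)


def build_pair_graph(
    RM: PropagationMatrix,
    RN: PropagationMatrix,
    types_m: Mapping[str, str],
    types_n: Mapping[str, str],
) -> PairGraph:
    """Build Q over all same-type element pairs of two models.

    Q is the Kronecker product of the two transfer matrices restricted to
    same-type pair nodes; cross-type pairs are excluded outright (their
    similarity is defined to be 0), so species-pair and reaction-pair nodes
    can only interact through the explicit Q edges.
    """
    n_n = RN.n
    pair_ids: list[tuple[str, str]] = []
    flat_index: list[int] = []
    for i, xid in enumerate(RM.element_ids):
        tx = types_m[xid]
        for j, yid in enumerate(RN.element_ids):
            if types_n[yid] == tx:
                pair_ids.append((xid, yid))
                flat_index.append(i * n_n + j)
    Q = sp.kron(RM.matrix, RN.matrix, format="csr")
    sel = np.asarray(flat_index, dtype=int)
    Q = Q[sel][:, sel]
    Q.eliminate_zeros()
    return PairGraph(tuple(pair_ids), sp.csr_matrix(Q))


def similarity_propagate(
    sigma: np.ndarray,
    Q: PairGraph,
    lam: float | None = None,
    *,
    lambda_fraction: float = 0.5,
    max_steps: int | None = None,
) -> np.ndarray:
    """Solve psi = sigma + lambda Q psi for the inferred pair similarities.

    ``sigma`` is the vector of direct similarities over ``Q.pair_ids``.  The
    result is not clipped; values above 1 are meaningful propagation mass and
    capping them is a display-layer decision.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (Q.n,):
        raise ValueError(f"sigma has shape {sigma.shape}, expected ({Q.n},)")
    if sigma.size and sigma.min() < 0:
        raise ValueError("sigma must be non-negative")
    if lam is None:
        lam = choose_lambda(Q.matrix, lambda_fraction)
    psi = _solve_or_series(Q.matrix, sigma, lam, max_steps)
    psi[np.abs(psi) < 1e-14] = 0.0
    return np.maximum(psi, 0.0)


def read_weights_config(path: str | Path) -> PropagationWeights:
    """Read a key = value config file for propagation weights.

    Recognised keys: alpha, beta, modifier_weight, compartment_weight,
    lambda_fraction, cofactor_file (TSV of resource, identifier).
    """
    kwargs: dict = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "cofactor_file":
            kwargs["cofactor_ids"] = read_cofactor_file(value)
        elif key in ("alpha", "beta", "modifier_weight", "compartment_weight", "lambda_fraction"):
            kwargs[key] = float(value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return PropagationWeights(**kwargs)


def read_cofactor_file(path: str | Path) -> frozenset[tuple[str, str]]:
    """Read a cofactor list (TSV: resource, identifier)."""
    pairs = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("resource\t"):
            continue
        resource, _, identifier = line.partition("\t")
        if not identifier:
            raise ValueError(f"bad cofactor row: {line!r}")
        pairs.add((resource.lower(), identifier.strip()))
    return frozenset(pairs)
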