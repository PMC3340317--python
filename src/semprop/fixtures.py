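"""Synthetic reaction networks for testing and benchmarking.

These generators produce small annotated networks in the package's own
:class:`~semprop.model_io.NetworkModel` form (and, on request, as SBML files):
a linear metabolic chain with only its endpoints annotated, a minimal pair of
one-reaction models, a phosphorylation-style pair whose two protein states
carry identical annotations, branched and random bipartite species-reaction
topologies, plus the annotation-removal protocol used to benchmark alignment
quality as a function of annotation coverage.

All randomness flows through explicit integer seeds; a fixed seed reproduces
models, SBML bytes and benchmark tables exactly.  Annotation removal draws
the stripped element set as a prefix of one seeded permutation, so for a fixed
seed the removal sets are nested across fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import (
    MEASURES,
    Alignment,
    compute_similarity_table,
    evaluate_alignment,
    greedy_align,
)
from .model_io import Annotation, ModelElement, NetworkModel, Reference, write_sbml
from .propagation import PropagationWeights

#: resource name used by all generated annotations
FIXTURE_RESOURCE = "demo"

TOPOLOGIES = ("linear_chain", "single_reaction_pair", "branched", "random")


@dataclass(frozen=True)
class FixtureSpec:
    topology: str = "linear_chain"
    n_species: int = 5
    annotation_density: float = 1.0
    concept_pool_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0 <= self.annotation_density <= 1:
            raise ValueError("annotation_density must lie in [0, 1]")


def _annot(identifier: str) -> Annotation:
    return Annotation(FIXTURE_RESOURCE, identifier)


def _new_model(model_id: str) -> NetworkModel:
    model = NetworkModel(model_id)
    model.add_element(ModelElement("c", "compartment"))
    return model


def _add_species(model: NetworkModel, eid: str, *identifiers: str) -> None:
    model.add_element(ModelElement(eid, "species", {_annot(i) for i in identifiers}))
    model.add_reference(Reference(eid, "c", "compartment-of"))


def make_linear_chain(
    n_species: int,
    annotate_endpoints_only: bool = True,
    *,
    model_id: str = "chain",
    annotate_reactions: bool = False,
) -> NetworkModel:
    """Linear pathway s1 -> r1 -> s2 -> ... -> sn.

    With ``annotate_endpoints_only`` only s1 and sn carry (distinct,
    single-concept) annotations; otherwise every species gets its own concept,
    and reactions too if ``annotate_reactions``.
    """
    if n_species < 2:
        raise ValueError("a chain needs at least 2 species")
    model = _new_model(model_id)
    for i in range(1, n_species + 1):
        sid = f"s{i}"
        if annotate_endpoints_only and i not in (1, n_species):
            _add_species(model, sid)
        else:
            _add_species(model, sid, f"S{i:04d}")
    for i in range(1, n_species):
        rid = f"r{i}"
        annotations = {_annot(f"R{i:04d}")} if annotate_reactions else set()
        model.add_element(ModelElement(rid, "reaction", annotations))
        model.add_reference(Reference(rid, f"s{i}", "reactant"))
        model.add_reference(Reference(rid, f"s{i + 1}", "product"))
    return model


def make_reaction_pair() -> tuple[NetworkModel, NetworkModel]:
    """Two one-reaction models a -> b and p -> q with annotated species and
    unannotated reactions; cross-model species similarities are positive
    (sigma_ap = 1/sqrt(2), sigma_bq = 1) while the reactions start at 0."""
    m = _new_model("pairM")
    _add_species(m, "a", "G1")
    _add_species(m, "b", "G2")
    m.add_element(ModelElement("x", "reaction"))
    m.add_reference(Reference("x", "a", "reactant"))
    m.add_reference(Reference("x", "b", "product"))

    n = _new_model("pairN")
    _add_species(n, "p", "G1", "G3")
    _add_species(n, "q", "G2")
    n.add_element(ModelElement("y", "reaction"))
    n.add_reference(Reference("y", "p", "reactant"))
    n.add_reference(Reference("y", "q", "product"))
    return m, n


def make_phospho_pair() -> tuple[NetworkModel, NetworkModel]:
    """Two copies of a kinase-style chain in which the species ``k`` and
    ``kp`` (a protein and its modified state) carry identical annotations but
    sit in different network contexts."""

    def build(model_id: str) -> NetworkModel:
        model = _new_model(model_id)
        _add_species(model, "u", "X")
        _add_species(model, "k", "PROT_A")
        _add_species(model, "kp", "PROT_A")
        _add_species(model, "d", "Y")
        for rid, sub, prod in (("r1", "u", "k"), ("r2", "k", "kp"), ("r3", "kp", "d")):
            model.add_element(ModelElement(rid, "reaction"))
            model.add_reference(Reference(rid, sub, "reactant"))
            model.add_reference(Reference(rid, prod, "product"))
        return model

    return build("phosphoM"), build("phosphoN")


def make_branched(n_branches: int = 3, *, model_id: str = "branched") -> NetworkModel:
    """A hub species feeding ``n_branches`` reactions, each producing its own
    annotated terminal species."""
    model = _new_model(model_id)
    _add_species(model, "hub", "HUB0")
    for i in range(1, n_branches + 1):
        _add_species(model, f"t{i}", f"T{i:04d}")
        rid = f"r{i}"
        model.add_element(ModelElement(rid, "reaction"))
        model.add_reference(Reference(rid, "hub", "reactant"))
        model.add_reference(Reference(rid, f"t{i}", "product"))
    return model


def make_random_model(
    n_species: int,
    n_reactions: int,
    annotation_density: float = 1.0,
    concept_pool_size: int = 20,
    seed: int = 0,
    *,
    model_id: str = "random",
    max_degree: int = 4,
    connect_all: bool = True,
) -> NetworkModel:
    """Random bipartite species-reaction network.

    Each reaction draws 1-2 reactants and 1-2 products among species whose
    degree has not reached ``max_degree`` (degree-capped Erdos-Renyi-style
    wiring).  Each species/reaction is annotated with probability
    ``annotation_density`` with one or two concepts from a finite pool.  With
    ``connect_all`` (default) any species left untouched by the wiring is
    attached to a random reaction, so the network has no orphan species.
    """
    rng = np.random.default_rng(seed)
    model = _new_model(model_id)
    degree = {f"s{i}": 0 for i in range(1, n_species + 1)}

    def pick(k: int, exclude: set[str]) -> list[str]:
        open_ids = [s for s in degree if degree[s] < max_degree and s not in exclude]
        if len(open_ids) < k:
            open_ids = [s for s in degree if s not in exclude] or list(degree)
        chosen = rng.choice(len(open_ids), size=min(k, len(open_ids)), replace=False)
        return [open_ids[c] for c in sorted(chosen)]

    def concepts() -> set[str]:
        k = int(rng.integers(1, 3))
        cols = rng.choice(concept_pool_size, size=min(k, concept_pool_size), replace=False)
        return {f"K{c:04d}" for c in cols}

    for sid in degree:
        if rng.random() < annotation_density:
            _add_species(model, sid, *concepts())
        else:
            _add_species(model, sid)
    signatures: set[frozenset[str]] = set()
    for j in range(1, n_reactions + 1):
        rid = f"r{j}"
        annotations = {_annot(c) for c in concepts()} if rng.random() < annotation_density else set()
        model.add_element(ModelElement(rid, "reaction", annotations))
        # no duplicated reactions: re-draw if another reaction already touches
        # the same species set (directions ignored), so every reaction has its
        # own network neighbourhood
        for _ in range(50):
            reactants = pick(int(rng.integers(1, 3)), set())
            products = pick(int(rng.integers(1, 3)), set(reactants))
            signature = frozenset(reactants) | frozenset(products)
            if signature not in signatures:
                break
        signatures.add(signature)
        for sid in reactants:
            model.add_reference(Reference(rid, sid, "reactant"))
            degree[sid] += 1
        for sid in products:
            model.add_reference(Reference(rid, sid, "product"))
            degree[sid] += 1
    if connect_all and n_reactions > 0:
        taken = {
            (r.source_id, r.target_id) for r in model.references if r.role != "compartment-of"
        }
        for sid in sorted(s for s, d in degree.items() if d == 0):
            rid = f"r{int(rng.integers(1, n_reactions + 1))}"
            role = "reactant" if rng.random() < 0.5 else "product"
            if (rid, sid) not in taken:
                model.add_reference(Reference(rid, sid, role))
                degree[sid] += 1
    return model


def make_fixture(spec: FixtureSpec, model_id: str = "fixture") -> list[NetworkModel]:
    """Build the model(s) described by a :class:`FixtureSpec`."""
    if spec.topology == "linear_chain":
        return [
            make_linear_chain(
                spec.n_species,
                annotate_endpoints_only=spec.annotation_density < 1.0,
                model_id=model_id,
            )
        ]
    if spec.topology == "single_reaction_pair":
        return list(make_reaction_pair())
    if spec.topology == "branched":
        return [make_branched(max(spec.n_species - 1, 1), model_id=model_id)]
    return [
        make_random_model(
            spec.n_species,
            max(spec.n_species - 1, 1),
            spec.annotation_density,
            spec.concept_pool_size,
            spec.seed,
            model_id=model_id,
        )
    ]


def rename_model(model: NetworkModel, model_id: str) -> NetworkModel:
    """Copy of a model under a new model_id (elements untouched)."""
    copy = model.copy()
    copy.model_id = model_id
    return copy


def remove_annotations(
    model: NetworkModel,
    fraction: float,
    element_types: Iterable[str] = ("species", "reaction", "compartment"),
    seed: int = 0,
) -> NetworkModel:
    """Copy of ``model`` with floor(fraction * n_annotated) uniformly chosen
    elements (of the given types) stripped of all their annotations.

    The removal set is the prefix of one seeded permutation of the annotated
    elements, so for a fixed seed larger fractions strip supersets.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    stripped = model.copy()
    annotated = sorted(model.annotated_ids(element_types))
    k = math.floor(fraction * len(annotated))
    order = np.random.default_rng(seed).permutation(len(annotated))
    for idx in order[:k]:
        stripped.elements[annotated[idx]].annotations = set()
    return stripped


def benchmark_alignment(
    model_a: NetworkModel,
    model_b: NetworkModel,
    reference: Alignment,
    fractions: Sequence[float],
    replicates: int = 25,
    measures: Sequence[str] = MEASURES,
    seed: int = 0,
    weights: PropagationWeights | None = None,
    element_types: Iterable[str] = ("species", "reaction"),
) -> pd.DataFrame:
    """Removal -> similarity -> greedy alignment -> precision/recall, full
    factorial over removal fractions, replicates and similarity measures.

    Annotations are removed from ``model_a`` only; ``model_b`` stays intact.
    Returns a tidy DataFrame (measure, fraction, replicate, precision, recall),
    bit-reproducible for a fixed seed.
    """
    for measure in measures:
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}")
    rows = []
    for rep in range(replicates):
        rep_seed = int((seed * 1_000_003 + rep) % (2**31))
        for fraction in fractions:
            stripped = remove_annotations(model_a, fraction, element_types, rep_seed)
            for measure in measures:
                table = compute_similarity_table(stripped, model_b, measure, weights=weights)
                aligned = greedy_align([table], [stripped, model_b])
                precision, recall = evaluate_alignment(aligned, reference)
                rows.append((measure, fraction, rep, precision, recall))
    return pd.DataFrame(
        rows, columns=["measure", "fraction", "replicate", "precision", "recall"]
    )


def write_manifest(model: NetworkModel, path: str | Path) -> None:
    """TSV manifest of a fixture: element_id, type, comma-joined concepts."""
    lines = ["element_id\ttype\tconcepts"]
    for eid, el in model.elements.items():
        keys = ",".join(sorted(f"{a.resource}:{a.identifier}" for a in el.annotations))
        lines.append(f"{eid}\t{el.element_type}\t{keys}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_fixture(model: NetworkModel, out_dir: str | Path) -> tuple[Path, Path]:
    """Write one fixture model as SBML plus its manifest; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sbml_path = out_dir / f"{model.model_id}.xml"
    manifest_path = out_dir / f"{model.model_id}.manifest.tsv"
    write_sbml(model, sbml_path)
    write_manifest(model, manifest_path)
    return sbml_path, manifest_path
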