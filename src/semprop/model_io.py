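"""Reading and writing SBML models as annotated network structures.

An SBML model is reduced to the three element types that carry biological
meaning in a reaction network -- species, reactions and compartments -- plus
the role-labelled references among them (reactant, product, modifier,
compartment-of).  MIRIAM-style cross-references attached to each element are
parsed into :class:`Annotation` records; both the URN dialect
(``urn:miriam:<resource>:<id>``) and the identifiers.org URI dialect are
accepted and normalise to the same value.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from urllib.parse import unquote

import libsbml

logger = logging.getLogger(__name__)

ELEMENT_TYPES = ("species", "reaction", "compartment")
REFERENCE_ROLES = ("reactant", "product", "modifier", "compartment-of")

_URN_RE = re.compile(r"^urn:miriam:([^:]+):(.+)$")
_IDORG_RE = re.compile(r"^https?://identifiers\.org/([^/]+)/(.+)$")


@dataclass(frozen=True, order=True)
class Annotation:
    """A single MIRIAM-style cross-reference: (resource, identifier, qualifier).

    ``resource`` is the web resource namespace (e.g. ``chebi``), lower-cased so
    the two URI dialects compare equal; ``identifier`` is the entry within the
    resource, kept verbatim (percent-decoding applied); ``qualifier`` is the
    relation qualifier (``is``, ``isVersionOf``, ...).
    """

    resource: str
    identifier: str
    qualifier: str = "is"

    def __post_init__(self) -> None:
        if not self.resource or not self.identifier:
            raise ValueError("Annotation resource and identifier must be non-empty")

    @property
    def key(self) -> tuple[str, str]:
        return (self.resource, self.identifier)


@dataclass
class ModelElement:
    element_id: str
    element_type: str
    annotations: set[Annotation] = field(default_factory=set)
    display_name: str | None = None

    def __post_init__(self) -> None:
        if self.element_type not in ELEMENT_TYPES:
            raise ValueError(f"unknown element type {self.element_type!r}")


@dataclass(frozen=True)
class Reference:
    """Directed, role-labelled reference between two elements of one model.

    For reactant/product/modifier roles the source is the reaction and the
    target is the species it refers to.  For compartment-of the source is the
    species and the target its compartment.
    """

    source_id: str
    target_id: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in REFERENCE_ROLES:
            raise ValueError(f"unknown reference role {self.role!r}")


@dataclass
class NetworkModel:
    model_id: str
    elements: dict[str, ModelElement] = field(default_factory=dict)
    references: list[Reference] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ref in self.references:
            if ref.source_id not in self.elements or ref.target_id not in self.elements:
                raise ValueError(
                    f"reference {ref.source_id}->{ref.target_id} has unresolved endpoint"
                )

    def add_element(self, element: ModelElement) -> None:
        if element.element_id in self.elements:
            raise ValueError(f"duplicate element id {element.element_id!r}")
        self.elements[element.element_id] = element

    def add_reference(self, ref: Reference) -> None:
        if ref.source_id not in self.elements or ref.target_id not in self.elements:
            raise ValueError(
                f"reference {ref.source_id}->{ref.target_id} has unresolved endpoint"
            )
        self.references.append(ref)

    def elements_of_type(self, element_type: str) -> list[ModelElement]:
        return [e for e in self.elements.values() if e.element_type == element_type]

    @property
    def element_ids(self) -> list[str]:
        return list(self.elements)

    def element_types(self) -> dict[str, str]:
        return {eid: el.element_type for eid, el in self.elements.items()}

    def annotated_ids(self, element_types: Iterable[str] = ELEMENT_TYPES) -> list[str]:
        types = set(element_types)
        return [
            eid
            for eid, el in self.elements.items()
            if el.element_type in types and el.annotations
        ]

    def copy(self) -> "NetworkModel":
        elements = {
            eid: ModelElement(
                element_id=el.element_id,
                element_type=el.element_type,
                annotations=set(el.annotations),
                display_name=el.display_name,
            )
            for eid, el in self.elements.items()
        }
        return NetworkModel(self.model_id, elements, list(self.references))


def parse_miriam_uri(uri: str) -> tuple[str, str] | None:
    """Parse a MIRIAM URN or identifiers.org URI into (resource, identifier).

    Returns None for URIs in neither dialect.  The resource is lower-cased and
    the identifier percent-decoded, so ``urn:miriam:chebi:CHEBI%3A17925`` and
    ``http://identifiers.org/chebi/CHEBI:17925`` parse to the same pair.
    """
    m = _URN_RE.match(uri)
    if m:
        return m.group(1).lower(), unquote(m.group(2))
    m = _IDORG_RE.match(uri)
    if m:
        return m.group(1).lower(), unquote(m.group(2))
    return None


_BIOL_QUALIFIERS = {
    "is": libsbml.BQB_IS,
    "isVersionOf": libsbml.BQB_IS_VERSION_OF,
    "hasVersion": libsbml.BQB_HAS_VERSION,
    "hasPart": libsbml.BQB_HAS_PART,
    "isPartOf": libsbml.BQB_IS_PART_OF,
}


def _extract_annotations(sbase: libsbml.SBase) -> set[Annotation]:
    annotations: set[Annotation] = set()
    for i in range(sbase.getNumCVTerms()):
        cv = sbase.getCVTerm(i)
        if cv.getQualifierType() == libsbml.BIOLOGICAL_QUALIFIER:
            qualifier = libsbml.BiolQualifierType_toString(cv.getBiologicalQualifierType())
        elif cv.getQualifierType() == libsbml.MODEL_QUALIFIER:
            qualifier = libsbml.ModelQualifierType_toString(cv.getModelQualifierType())
        else:
            qualifier = "unknown"
        for j in range(cv.getNumResources()):
            uri = cv.getResourceURI(j)
            parsed = parse_miriam_uri(uri)
            if parsed is None:
                logger.warning("skipping annotation with unknown URI scheme: %s", uri)
                continue
            resource, identifier = parsed
            annotations.add(Annotation(resource, identifier, qualifier or "unknown"))
    return annotations


def read_sbml(path: str | Path) -> NetworkModel:
    """Read an SBML Level 2/3 file into a :class:`NetworkModel`.

    Species, reactions and compartments become elements; each reaction yields
    reactant/product/modifier references and each species a compartment-of
    reference.  Annotations in unknown URI schemes are skipped with a warning.
    """
    path = Path(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0 or doc.getModel() is None:
        msgs = [
            doc.getError(i).getMessage().strip()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ValueError(f"cannot parse SBML file {path}: " + "; ".join(msgs or ["no model"]))
    sbml_model = doc.getModel()
    model = NetworkModel(sbml_model.getId() or path.stem)

    for comp in sbml_model.getListOfCompartments():
        model.add_element(
            ModelElement(
                comp.getId(), "compartment", _extract_annotations(comp), comp.getName() or None
            )
        )
    for sp in sbml_model.getListOfSpecies():
        model.add_element(
            ModelElement(sp.getId(), "species", _extract_annotations(sp), sp.getName() or None)
        )
    for rxn in sbml_model.getListOfReactions():
        model.add_element(
            ModelElement(
                rxn.getId(), "reaction", _extract_annotations(rxn), rxn.getName() or None
            )
        )

    for sp in sbml_model.getListOfSpecies():
        comp_id = sp.getCompartment()
        if comp_id and comp_id in model.elements:
            model.add_reference(Reference(sp.getId(), comp_id, "compartment-of"))
    for rxn in sbml_model.getListOfReactions():
        rid = rxn.getId()
        for sr in rxn.getListOfReactants():
            model.add_reference(Reference(rid, sr.getSpecies(), "reactant"))
        for sr in rxn.getListOfProducts():
            model.add_reference(Reference(rid, sr.getSpecies(), "product"))
        for sr in rxn.getListOfModifiers():
            model.add_reference(Reference(rid, sr.getSpecies(), "modifier"))
    return model


def _attach_annotations(sbase: libsbml.SBase, element: ModelElement) -> None:
    if not element.annotations:
        return
    sbase.setMetaId(f"meta_{element.element_id}")
    # group resources by qualifier so equal qualifiers share one CV term
    by_qualifier: dict[str, list[Annotation]] = {}
    for ann in sorted(element.annotations):
        by_qualifier.setdefault(ann.qualifier, []).append(ann)
    for qualifier, anns in sorted(by_qualifier.items()):
        cv = libsbml.CVTerm()
        cv.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
        cv.setBiologicalQualifierType(_BIOL_QUALIFIERS.get(qualifier, libsbml.BQB_IS))
        for ann in anns:
            cv.addResource(f"http://identifiers.org/{ann.resource}/{ann.identifier}")
        sbase.addCVTerm(cv)


def write_sbml(model: NetworkModel, path: str | Path) -> None:
    """Write a :class:`NetworkModel` as an SBML Level 3 file.

    Annotations are emitted as identifiers.org URIs.  Species without a
    compartment-of reference are placed in an implicit ``default`` compartment
    (SBML requires one).
    """
    doc = libsbml.SBMLDocument(3, 1)
    m = doc.createModel()
    m.setId(model.model_id)

    compartment_of = {
        ref.source_id: ref.target_id
        for ref in model.references
        if ref.role == "compartment-of"
    }
    compartments = model.elements_of_type("compartment")
    species = model.elements_of_type("species")
    need_default = any(sp.element_id not in compartment_of for sp in species)
    for el in compartments:
        c = m.createCompartment()
        c.setId(el.element_id)
        c.setConstant(True)
        c.setSize(1.0)
        if el.display_name:
            c.setName(el.display_name)
        _attach_annotations(c, el)
    if need_default and not any(el.element_id == "default" for el in compartments):
        c = m.createCompartment()
        c.setId("default")
        c.setConstant(True)
        c.setSize(1.0)

    for el in species:
        s = m.createSpecies()
        s.setId(el.element_id)
        s.setCompartment(compartment_of.get(el.element_id, "default"))
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        if el.display_name:
            s.setName(el.display_name)
        _attach_annotations(s, el)

    refs_by_reaction: dict[str, list[Reference]] = {}
    for ref in model.references:
        if ref.role in ("reactant", "product", "modifier"):
            refs_by_reaction.setdefault(ref.source_id, []).append(ref)
    for el in model.elements_of_type("reaction"):
        r = m.createReaction()
        r.setId(el.element_id)
        r.setReversible(False)
        r.setFast(False)
        if el.display_name:
            r.setName(el.display_name)
        _attach_annotations(r, el)
        for ref in refs_by_reaction.get(el.element_id, []):
            if ref.role == "reactant":
                sr = r.createReactant()
                sr.setSpecies(ref.target_id)
                sr.setStoichiometry(1.0)
                sr.setConstant(True)
            elif ref.role == "product":
                sr = r.createProduct()
                sr.setSpecies(ref.target_id)
                sr.setStoichiometry(1.0)
                sr.setConstant(True)
            else:
                mod = r.createModifier()
                mod.setSpecies(ref.target_id)

    if libsbml.writeSBMLToFile(doc, str(Path(path))) != 1:
        raise IOError(f"failed to write SBML to {path}")


def write_annotation_suggestions(
    model: NetworkModel,
    suggestions: Mapping[str, Sequence[tuple[tuple[str, str], float]]],
    path: str | Path,
) -> None:
    """Write ranked per-element annotation suggestions as a TSV report.

    ``suggestions`` maps element_id to a score-descending list of
    ((resource, identifier), score).  Rows are ordered by element_id
    (lexicographic), then rank.
    """
    for eid in suggestions:
        if eid not in model.elements:
            raise KeyError(f"suggested element id {eid!r} not in model {model.model_id!r}")
    lines = ["element_id\trank\tresource\tidentifier\tscore"]
    for eid in sorted(suggestions):
        ranked = sorted(suggestions[eid], key=lambda item: -item[1])
        for rank, ((resource, identifier), score) in enumerate(ranked, start=1):
            lines.append(f"{eid}\t{rank}\t{resource}\t{identifier}\t{score:.6g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
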