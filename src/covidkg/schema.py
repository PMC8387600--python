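"""Schema definitions for the biomedical knowledge graph and the HIPAA ontology.

Two schema kinds live here:

* :class:`SchemaGraph` — the BKG schema: UMLS-semantic-type-style entity
  classes (124 in the packaged default, including the custom provenance
  class ``Data_Source``) and 46 typed relations, each with explicit
  domain and range class sets.
* :class:`HipaaOntologySchema` — the HIPAA-COVID regulation ontology: a
  small class hierarchy (Stakeholder with three mutually disjoint
  subclasses, Regulation, CovidRule with four guidance subclasses, and
  the privacy/security rule classes) plus its object properties.

Both kinds serialize to Turtle and OWL/XML through rdflib and round-trip
losslessly through :func:`serialize_schema` / :func:`parse_schema`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path

import yaml
from rdflib import Graph, Literal, Namespace, RDF, RDFS, OWL, URIRef

#: Single project namespace for BKG classes, relations and entities.
BKG = Namespace("http://covidkg.example/bkg#")
#: Namespace for the HIPAA-COVID ontology.
HIPAA = Namespace("http://covidkg.example/hipaa#")

_IS_CUSTOM = BKG["isCustomClass"]
_SCHEMA_KIND = BKG["schemaKind"]

SERIAL_FORMATS = {"turtle": "turtle", "owl-xml": "xml"}


class SchemaError(ValueError):
    """Raised for malformed or internally inconsistent schema definitions."""


@dataclass(frozen=True)
class EntityClass:
    """A named entity class, optionally below a parent class.

    ``is_custom`` marks classes added on top of the UMLS-style inventory;
    in the default BKG schema only ``Data_Source`` carries the flag.
    """

    name: str
    parent: str | None = None
    is_custom: bool = False


@dataclass(frozen=True)
class RelationType:
    """A typed relation with non-empty domain and range class sets."""

    name: str
    domain: frozenset[str]
    range: frozenset[str]

    def admits(self, head_label: str, tail_label: str) -> bool:
        return head_label in self.domain and tail_label in self.range


@dataclass
class SchemaGraph:
    """Entity classes plus typed relations, keyed by name in declaration order."""

    classes: dict[str, EntityClass] = field(default_factory=dict)
    relations: dict[str, RelationType] = field(default_factory=dict)

    def validate(self) -> None:
        for cls in self.classes.values():
            if cls.parent is not None and cls.parent not in self.classes:
                raise SchemaError(
                    f"class {cls.name!r} names unknown parent {cls.parent!r}"
                )
        for rel in self.relations.values():
            if not rel.domain or not rel.range:
                raise SchemaError(f"relation {rel.name!r} has empty domain or range")
            for endpoint in rel.domain | rel.range:
                if endpoint not in self.classes:
                    raise SchemaError(
                        f"relation {rel.name!r} references unknown class {endpoint!r}"
                    )

    @property
    def custom_classes(self) -> list[EntityClass]:
        return [c for c in self.classes.values() if c.is_custom]

    def relation_order(self) -> list[str]:
        """Relation names in schema declaration order (classifier class order)."""
        return list(self.relations)

    def relations_admitting(self, head_label: str, tail_label: str) -> list[str]:
        return [
            r.name for r in self.relations.values() if r.admits(head_label, tail_label)
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SchemaGraph):
            return NotImplemented
        return (
            set(self.classes.values()) == set(other.classes.values())
            and set(self.relations.values()) == set(other.relations.values())
        )


@dataclass
class HipaaOntologySchema:
    """HIPAA-COVID ontology: class hierarchy, disjointness, object properties.

    ``classes`` maps a class name to its parent (``None`` for top-level
    classes).  ``disjoint_sets`` lists groups of pairwise-disjoint sibling
    classes.  ``object_properties`` maps a property name to its
    (domain class, range class) pair.
    """

    classes: dict[str, str | None] = field(default_factory=dict)
    disjoint_sets: tuple[frozenset[str], ...] = ()
    object_properties: dict[str, tuple[str, str]] = field(default_factory=dict)

    def subclasses_of(self, name: str) -> list[str]:
        return [c for c, parent in self.classes.items() if parent == name]

    @property
    def covid_rule_classes(self) -> list[str]:
        return self.subclasses_of("CovidRule")

    def disjoint_pairs(self) -> list[tuple[str, str]]:
        """All unordered disjointness axioms implied by ``disjoint_sets``."""
        pairs = set()
        for group in self.disjoint_sets:
            for a, b in combinations(sorted(group), 2):
                pairs.add((a, b))
        return sorted(pairs)

    def validate(self) -> None:
        for name, parent in self.classes.items():
            if parent is not None and parent not in self.classes:
                raise SchemaError(f"class {name!r} names unknown parent {parent!r}")
        for group in self.disjoint_sets:
            for member in group:
                if member not in self.classes:
                    raise SchemaError(f"disjoint set references unknown class {member!r}")
        for prop, (dom, rng) in self.object_properties.items():
            if dom not in self.classes or rng not in self.classes:
                raise SchemaError(
                    f"object property {prop!r} references unknown class"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HipaaOntologySchema):
            return NotImplemented
        return (
            self.classes == other.classes
            and set(self.disjoint_sets) == set(other.disjoint_sets)
            and self.object_properties == other.object_properties
        )


def _load_packaged_schema_config() -> dict:
    text = resources.files("covidkg.data").joinpath("bkg_schema.yaml").read_text()
    return yaml.safe_load(text)


def build_bkg_schema(config: str | Path | dict | None = None) -> SchemaGraph:
    """Build the BKG schema, from the packaged default or a YAML config.

    The packaged default has 124 classes (123 UMLS-semantic-type-style
    names plus the custom ``Data_Source`` provenance class) and 46
    relations.  A config must provide ``classes`` (list of names) and
    ``relations`` (list of ``{name, domain, range}`` mappings); an
    optional ``custom_classes`` list flags provenance-style additions.
    """
    if config is None:
        raw = _load_packaged_schema_config()
    elif isinstance(config, dict):
        raw = config
    else:
        try:
            raw = yaml.safe_load(Path(config).read_text())
        except yaml.YAMLError as exc:
            raise SchemaError(f"cannot parse schema config {config}: {exc}") from exc
    if not isinstance(raw, dict) or "classes" not in raw:
        raise SchemaError("schema config must be a mapping with a 'classes' list")

    schema = SchemaGraph()
    for name in raw.get("classes", []):
        if not isinstance(name, str):
            raise SchemaError(f"malformed class entry: {name!r}")
        if name in schema.classes:
            raise SchemaError(f"duplicate class name: {name!r}")
        schema.classes[name] = EntityClass(name)
    for name in raw.get("custom_classes", []):
        if name in schema.classes:
            raise SchemaError(f"duplicate class name: {name!r}")
        schema.classes[name] = EntityClass(name, is_custom=True)
    for entry in raw.get("relations", []):
        if (
            not isinstance(entry, dict)
            or "name" not in entry
            or not entry.get("domain")
            or not entry.get("range")
        ):
            raise SchemaError(f"malformed relation entry: {entry!r}")
        name = entry["name"]
        if name in schema.relations:
            raise SchemaError(f"duplicate relation name: {name!r}")
        schema.relations[name] = RelationType(
            name, frozenset(entry["domain"]), frozenset(entry["range"])
        )
    schema.validate()
    return schema


def build_hipaa_schema() -> HipaaOntologySchema:
    """Build the HIPAA-COVID ontology schema.

    Stakeholder has exactly three pairwise-disjoint subclasses (Business
    Associates, Exempt Entities, Covered Entities); CovidRule has the four
    COVID guidance subclasses (media access, contacting recovered
    patients, PHI disclosure to law enforcement, telehealth); the privacy
    and security rule classes carry seven subclasses combined.
    """
    classes: dict[str, str | None] = {
        "Stakeholder": None,
        "Business_Associates": "Stakeholder",
        "Exempt_Entities": "Stakeholder",
        "Covered_Entities": "Stakeholder",
        "Regulation": None,
        "CovidRule": None,
        "Media_Access": "CovidRule",
        "Contacting_Covid19_Patients": "CovidRule",
        "PHI_To_Law_Enforcement": "CovidRule",
        "Telehealth": "CovidRule",
        "PrivacyRule": None,
        "Data_Safeguards": "PrivacyRule",
        "Notice_Of_Privacy_Practices": "PrivacyRule",
        "Minimum_Necessary": "PrivacyRule",
        "Patient_Access_Rights": "PrivacyRule",
        "SecurityRule": None,
        "Administrative_Safeguards": "SecurityRule",
        "Physical_Safeguards": "SecurityRule",
        "Technical_Safeguards": "SecurityRule",
    }
    schema = HipaaOntologySchema(
        classes=classes,
        disjoint_sets=(
            frozenset({"Business_Associates", "Exempt_Entities", "Covered_Entities"}),
        ),
        object_properties={
            "hasRegulation": ("Stakeholder", "Regulation"),
            "hasCovidRule": ("Regulation", "CovidRule"),
            "hasPrivacyRule": ("Regulation", "PrivacyRule"),
            "hasSecurityRule": ("Regulation", "SecurityRule"),
        },
    )
    schema.validate()
    return schema


def _bkg_to_rdf(schema: SchemaGraph) -> Graph:
    g = Graph()
    g.bind("BKG", BKG)
    g.bind("owl", OWL)
    root = URIRef(str(BKG))
    g.add((root, RDF.type, OWL.Ontology))
    g.add((root, _SCHEMA_KIND, Literal("bkg")))
    for cls in schema.classes.values():
        iri = BKG[cls.name]
        g.add((iri, RDF.type, OWL.Class))
        if cls.parent is not None:
            g.add((iri, RDFS.subClassOf, BKG[cls.parent]))
        if cls.is_custom:
            g.add((iri, _IS_CUSTOM, Literal(True)))
    for rel in schema.relations.values():
        prop = BKG[rel.name]
        g.add((prop, RDF.type, OWL.ObjectProperty))
        for dom in sorted(rel.domain):
            g.add((prop, RDFS.domain, BKG[dom]))
        for rng in sorted(rel.range):
            g.add((prop, RDFS.range, BKG[rng]))
    return g


def _hipaa_to_rdf(schema: HipaaOntologySchema) -> Graph:
    g = Graph()
    g.bind("HIPAA", HIPAA)
    g.bind("owl", OWL)
    root = URIRef(str(HIPAA))
    g.add((root, RDF.type, OWL.Ontology))
    g.add((root, _SCHEMA_KIND, Literal("hipaa")))
    for name, parent in schema.classes.items():
        iri = HIPAA[name]
        g.add((iri, RDF.type, OWL.Class))
        if parent is not None:
            g.add((iri, RDFS.subClassOf, HIPAA[parent]))
    for a, b in schema.disjoint_pairs():
        g.add((HIPAA[a], OWL.disjointWith, HIPAA[b]))
    for prop, (dom, rng) in schema.object_properties.items():
        iri = HIPAA[prop]
        g.add((iri, RDF.type, OWL.ObjectProperty))
        g.add((iri, RDFS.domain, HIPAA[dom]))
        g.add((iri, RDFS.range, HIPAA[rng]))
    return g


def serialize_schema(
    schema: SchemaGraph | HipaaOntologySchema, format: str = "turtle"
) -> str:
    """Serialize either schema kind to ``turtle`` or ``owl-xml`` text."""
    if format not in SERIAL_FORMATS:
        raise SchemaError(
            f"unsupported format {format!r}; expected one of {sorted(SERIAL_FORMATS)}"
        )
    if isinstance(schema, SchemaGraph):
        g = _bkg_to_rdf(schema)
    elif isinstance(schema, HipaaOntologySchema):
        g = _hipaa_to_rdf(schema)
    else:
        raise SchemaError(f"cannot serialize object of type {type(schema).__name__}")
    return g.serialize(format=SERIAL_FORMATS[format])


def _local(iri: URIRef, ns: Namespace) -> str:
    return str(iri)[len(str(ns)):]


def _disjoint_groups(pairs: set[tuple[str, str]]) -> tuple[frozenset[str], ...]:
    # Merge pairwise axioms into connected components; exact whenever each
    # disjoint group was emitted as a full clique (always true for our
    # serializer).
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for x in parent:
        groups.setdefault(find(x), set()).add(x)
    return tuple(sorted((frozenset(g) for g in groups.values()), key=sorted))


def parse_schema(text: str, format: str = "turtle") -> SchemaGraph | HipaaOntologySchema:
    """Parse text produced by :func:`serialize_schema` back into a schema."""
    if format not in SERIAL_FORMATS:
        raise SchemaError(f"unsupported format {format!r}")
    g = Graph()
    try:
        g.parse(data=text, format=SERIAL_FORMATS[format])
    except Exception as exc:  # rdflib raises several parser error types
        raise SchemaError(f"cannot parse schema document: {exc}") from exc

    kinds = list(g.objects(None, _SCHEMA_KIND))
    kind = str(kinds[0]) if kinds else "bkg"
    if kind == "hipaa":
        schema_h = HipaaOntologySchema()
        for iri in sorted(g.subjects(RDF.type, OWL.Class)):
            name = _local(iri, HIPAA)
            parents = [ _local(p, HIPAA) for p in g.objects(iri, RDFS.subClassOf)]
            schema_h.classes[name] = parents[0] if parents else None
        pairs = {
            tuple(sorted((_local(a, HIPAA), _local(b, HIPAA))))
            for a, _, b in g.triples((None, OWL.disjointWith, None))
        }
        schema_h.disjoint_sets = _disjoint_groups(pairs)
        for prop in sorted(g.subjects(RDF.type, OWL.ObjectProperty)):
            doms = list(g.objects(prop, RDFS.domain))
            rngs = list(g.objects(prop, RDFS.range))
            schema_h.object_properties[_local(prop, HIPAA)] = (
                _local(doms[0], HIPAA),
                _local(rngs[0], HIPAA),
            )
        schema_h.validate()
        return schema_h

    schema = SchemaGraph()
    for iri in sorted(g.subjects(RDF.type, OWL.Class)):
        name = _local(iri, BKG)
        parents = [_local(p, BKG) for p in g.objects(iri, RDFS.subClassOf)]
        is_custom = (iri, _IS_CUSTOM, Literal(True)) in g
        schema.classes[name] = EntityClass(
            name, parents[0] if parents else None, is_custom
        )
    for prop in sorted(g.subjects(RDF.type, OWL.ObjectProperty)):
        name = _local(prop, BKG)
        schema.relations[name] = RelationType(
            name,
            frozenset(_local(d, BKG) for d in g.objects(prop, RDFS.domain)),
            frozenset(_local(r, BKG) for r in g.objects(prop, RDFS.range)),
        )
    schema.validate()
    return schema
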