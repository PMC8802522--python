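"""Translate a parsed protocol into a retrospective-provenance RDF graph.

The model is activity-based.  Three levels of granularity:

1. one top-level activity per protocol (``<base>/<id>/protocol``) — the whole
   experiment, annotated with the head key-value information through
   ``prov:qualifiedAssociation``;
2. one activity per main section (``<base>/<id>/<section_slug>``);
3. one activity per activity-table row (``.../<section_slug>/<row_index>``).

The hierarchy is expressed with ``bfo:hasPart`` (an acyclic tree with a single
root per protocol) and the sequential order within each sibling group with
``prov:wasInformedBy`` (a document-order chain).  Every activity carries the
three generic types ``schema:Action``, ``prov:Activity`` and ``bfo:process``;
verb-derived ontology classes are attached with ``owl:sameAs``.  Linked
inventory items become ``prov:used`` entities of type
``schema:IndividualProduct``; the first mention of a research-data file marks
its creation (``prov:wasGeneratedBy``), later mentions are ``prov:used``.
Parameters become blank-node value specifications
(``obo:OBI_0001938`` / ``obo:OBI_0001937`` / ``obo:IAO_0000039``), mixture
recipes become ``obo:OBI_0000685`` activities whose recipe objective
(``obo:OBI_0000686``) is shared across identical recipes, and resources with
passage/lot information become deduplicated instance entities attached to
their inventory item by ``is_instance_of``.
"""

from __future__ import annotations

import hashlib
import logging
import re

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, PROV, RDF, RDFS, XSD

from .config import DEFAULT_CONFIG, PipelineConfig
from .parser import ActivityRow, ElnProtocol, InventoryItemDoc
from .textmine import (
    MixtureSpec,
    ParameterMention,
    ResourceMention,
    classify_activity,
    extract_parameters,
    parse_mixture,
    parse_resource_mention,
)

logger = logging.getLogger(__name__)

OBO = Namespace("http://purl.obolibrary.org/obo/")
SCHEMA = Namespace("http://schema.org/")
WD = Namespace("http://www.wikidata.org/entity/")

# generic activity types
BFO_PROCESS = OBO.BFO_0000015
HAS_PART = OBO.BFO_0000051
# value specifications
HAS_VALUE_SPECIFICATION = OBO.OBI_0001938
HAS_SPECIFIED_NUMERIC_VALUE = OBO.OBI_0001937
HAS_MEASUREMENT_UNIT_LABEL = OBO.IAO_0000039
# mixtures
MIXTURE_CREATION = OBO.OBI_0000685
HAS_SPECIFIED_INPUT = OBO.OBI_0000293
HAS_SPECIFIED_OUTPUT = OBO.OBI_0000299
MATERIAL_COMBINATION_OBJECTIVE = OBO.OBI_0000686
ACHIEVES_PLANNED_OBJECTIVE = OBO.OBI_0000417


class KGBuildError(ValueError):
    """Raised when the protocol cannot be translated (unresolved links, ...)."""


def _ep(config: PipelineConfig) -> Namespace:
    return Namespace(config.vocab_iri)


def _prefix_map(config: PipelineConfig) -> dict[str, str]:
    return {
        "obo": str(OBO),
        "ep": config.vocab_iri,
        "schema": str(SCHEMA),
        "prov": str(PROV),
        "owl": str(OWL),
        "rdfs": str(RDFS),
        "rdf": str(RDF),
        "xsd": str(XSD),
        "wd": str(WD),
    }


def expand_curie(token: str, config: PipelineConfig = DEFAULT_CONFIG) -> URIRef:
    """Expand a CURIE like ``obo:UO_0000031`` (or pass through an IRI)."""
    if token.startswith(("http://", "https://")):
        return URIRef(token)
    prefix, _, local = token.partition(":")
    table = _prefix_map(config)
    if prefix in table and local:
        return URIRef(table[prefix] + local)
    # bare OBO-idspace CURIEs such as CLO:0007699
    if prefix in ("CLO", "OBI", "CHEBI", "NCIT", "UO", "IAO", "BTO") and local:
        return URIRef(str(OBO) + f"{prefix}_{local}")
    raise KGBuildError(f"cannot expand CURIE {token!r}")


def new_graph(config: PipelineConfig = DEFAULT_CONFIG) -> Graph:
    g = Graph()
    for prefix, iri in _prefix_map(config).items():
        g.bind(prefix, iri)
    return g


_SLUG_RE = re.compile(r"[^a-z0-9]+")


def slugify(text: str) -> str:
    slug = _SLUG_RE.sub("_", text.lower()).strip("_")
    return slug or "section"


def section_slug(heading: str, rule_counters: dict[int, int], config: PipelineConfig) -> str:
    """Slug for a section heading, honouring the configured rewrite rules."""
    for i, (pattern, template) in enumerate(config.section_slug_rules):
        if re.search(pattern, heading):
            rule_counters[i] = rule_counters.get(i, 0) + 1
            return template.format(n=rule_counters[i])
    return slugify(heading)


_TIME_RE = re.compile(r"^(\d{1,2}):(\d{2})(?::(\d{2}))?$")


def _time_literal(raw: str) -> Literal:
    m = _TIME_RE.match(raw.strip())
    if m:
        h, mi, s = int(m.group(1)), m.group(2), m.group(3) or "00"
        return Literal(f"{h:02d}:{mi}:{s}", datatype=XSD.time)
    return Literal(raw)


def _add_generic_activity(g: Graph, iri: URIRef, label: str) -> None:
    g.add((iri, RDF.type, SCHEMA.Action))
    g.add((iri, RDF.type, PROV.Activity))
    g.add((iri, RDF.type, BFO_PROCESS))
    if label:
        g.add((iri, RDFS.label, Literal(label)))


def _person_iri(name: str, config: PipelineConfig) -> URIRef:
    return URIRef(f"{config.base_iri}agents/{slugify(name)}")


def _ensure_person(g: Graph, name: str, config: PipelineConfig) -> URIRef:
    iri = _person_iri(name, config)
    g.add((iri, RDF.type, PROV.Person))
    g.add((iri, RDF.type, SCHEMA.Person))
    g.add((iri, SCHEMA.name, Literal(name)))
    return iri


def _ensure_item(g: Graph, item: InventoryItemDoc, config: PipelineConfig) -> URIRef:
    iri = URIRef(f"{config.base_iri}inventory/{item.item_id}")
    ep = _ep(config)
    g.add((iri, RDF.type, SCHEMA.IndividualProduct))
    g.add((iri, RDF.type, PROV.Entity))
    g.add((iri, RDFS.label, Literal(item.name)))
    g.add((iri, SCHEMA.name, Literal(item.name)))
    g.add((iri, ep.category, Literal(item.category)))
    for ref in item.external_class_refs:
        try:
            g.add((iri, OWL.sameAs, expand_curie(ref, config)))
        except KGBuildError:
            logger.warning("unparseable external class ref %r on item %s", ref, item.item_id)
    return iri


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def add_value_specification(
    g: Graph,
    activity_iri: URIRef,
    p: ParameterMention,
    config: PipelineConfig = DEFAULT_CONFIG,
    node_label: str | None = None,
) -> BNode:
    """Attach one value-specification blank node to an activity.

    The node carries the numeric value and a link to the unit class; a unit
    with no configured class keeps its raw token as a literal (warning).
    """
    if (activity_iri, RDF.type, PROV.Activity) not in g:
        raise KGBuildError(f"activity {activity_iri} not in graph")
    node = BNode(node_label) if node_label else BNode()
    g.add((activity_iri, HAS_VALUE_SPECIFICATION, node))
    g.add((node, RDF.type, OBO.OBI_0001930))  # value specification
    g.add((node, HAS_SPECIFIED_NUMERIC_VALUE, Literal(p.value, datatype=XSD.decimal)))
    if p.unit_class:
        g.add((node, HAS_MEASUREMENT_UNIT_LABEL, expand_curie(p.unit_class, config)))
    else:  # pragma: no cover - extract_parameters only emits mapped units
        logger.warning("unit %r has no configured class; stored as literal", p.unit_token)
        g.add((node, HAS_MEASUREMENT_UNIT_LABEL, Literal(p.unit_token)))
    return node


def recipe_objective_iri(m: MixtureSpec, config: PipelineConfig = DEFAULT_CONFIG) -> URIRef:
    """Deterministic IRI of a recipe objective: identical recipes share it."""
    canonical = " + ".join(
        f"{c.fraction_percent:g}% [{c.category}] {c.name}" for c in m.components
    )
    digest = hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:12]
    return URIRef(f"{config.base_iri}recipes/{digest}")


def add_mixture(
    g: Graph,
    activity_context: URIRef,
    m: MixtureSpec,
    input_entities: list[URIRef],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> URIRef:
    """Model a mixture creation on *activity_context*.

    The context activity is typed as a mixture-creation activity, component
    entities are linked by ``has_specified_input``, the resulting mixture by
    ``has_specified_output``, and the recipe objective (shared across all
    activities using the same ordered recipe) by
    ``achieves_planned_objective``.  Returns the mixture entity IRI.
    """
    if len(input_entities) != len(m.components):
        raise KGBuildError(
            f"mixture has {len(m.components)} components but "
            f"{len(input_entities)} resolved input entities"
        )
    ep = _ep(config)
    g.add((activity_context, RDF.type, MIXTURE_CREATION))
    for entity in input_entities:
        g.add((activity_context, HAS_SPECIFIED_INPUT, entity))
    mixture = URIRef(str(activity_context) + "/mixture")
    g.add((mixture, RDF.type, ep.Mixture))
    g.add((mixture, RDF.type, PROV.Entity))
    g.add((mixture, RDFS.label, Literal(m.source_text)))
    g.add((activity_context, HAS_SPECIFIED_OUTPUT, mixture))
    objective = recipe_objective_iri(m, config)
    g.add((objective, RDF.type, MATERIAL_COMBINATION_OBJECTIVE))
    canonical = " + ".join(
        f"{c.fraction_percent:g}% [{c.category}] {c.name}" for c in m.components
    )
    g.add((objective, RDFS.label, Literal(canonical)))
    g.add((activity_context, ACHIEVES_PLANNED_OBJECTIVE, objective))
    if m.attribution:
        agent = _ensure_person(g, m.attribution, config)
        g.add((mixture, PROV.wasAttributedTo, agent))
    return mixture


def add_resource_instance(
    g: Graph,
    item_entity: URIRef,
    mention: ResourceMention,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> URIRef:
    """Mint (or re-use) the instance entity for an item + passage + lot."""
    ep = _ep(config)
    suffix = ""
    if mention.passage_number is not None:
        suffix += f"_P{mention.passage_number}"
    if mention.lot_number:
        suffix += f"_LOT{mention.lot_number}"
    iri = URIRef(f"{item_entity}/instance{suffix}")
    g.add((iri, RDF.type, ep.ResourceInstance))
    g.add((iri, RDF.type, PROV.Entity))
    g.add((iri, ep.is_instance_of, item_entity))
    label = mention.name
    if mention.passage_number is not None:
        g.add((iri, ep.has_passage_number, Literal(mention.passage_number, datatype=XSD.integer)))
        label += f" P{mention.passage_number}"
    if mention.lot_number:
        g.add((iri, ep.has_lot_number, Literal(mention.lot_number)))
        label += f" LOT {mention.lot_number}"
    g.add((iri, RDFS.label, Literal(label)))
    return iri


def _normalise(name: str) -> str:
    return re.sub(r"\s+", " ", name).strip().casefold()


class _InventoryIndex:
    def __init__(self, inventory: list[InventoryItemDoc]):
        self.by_id = {item.item_id: item for item in inventory}
        self.by_name = {_normalise(item.name): item for item in inventory}
        self.items = list(inventory)

    def resolve_name(self, name: str) -> InventoryItemDoc | None:
        key = _normalise(name)
        if key in self.by_name:
            return self.by_name[key]
        prefix = [it for k, it in self.by_name.items() if k.startswith(key)]
        if len(prefix) == 1:
            return prefix[0]
        contains = [it for k, it in self.by_name.items() if key in k]
        if len(contains) == 1:
            return contains[0]
        return None


def _attach_head(
    g: Graph, prot_iri: URIRef, protocol: ElnProtocol, config: PipelineConfig
) -> None:
    ep = _ep(config)
    org_iri: URIRef | None = None
    persons: list[URIRef] = []

    def association(role: URIRef, agent: URIRef, n: str) -> None:
        assoc = URIRef(f"{prot_iri}/association/{n}")
        g.add((prot_iri, PROV.qualifiedAssociation, assoc))
        g.add((assoc, RDF.type, PROV.Association))
        g.add((assoc, PROV.agent, agent))
        g.add((assoc, PROV.hadRole, role))
        g.add((prot_iri, PROV.wasAssociatedWith, agent))

    for kv in protocol.head:
        role = config.head_field_roles.get(kv.key.strip().lower())
        if role == "experimentalist":
            person = _ensure_person(g, kv.value.strip(), config)
            persons.append(person)
            association(ep.Experimentalist, person, "experimentalist")
        elif role == "involved":
            names = [n.strip() for n in re.split(r",| and ", kv.value) if n.strip()]
            for i, name in enumerate(names, start=1):
                person = _ensure_person(g, name, config)
                persons.append(person)
                association(ep.InvolvedPerson, person, f"involved_{i}")
        elif role == "objective":
            g.add((prot_iri, ep.objective, Literal(kv.value)))
        elif role == "organization":
            org_iri = URIRef(f"{config.base_iri}organizations/{slugify(kv.value)}")
            g.add((org_iri, RDF.type, PROV.Organization))
            g.add((org_iri, RDF.type, SCHEMA.Organization))
            g.add((org_iri, SCHEMA.name, Literal(kv.value)))
        elif role == "template":
            template = URIRef(f"{config.base_iri}templates/{slugify(kv.value)}")
            g.add((template, RDF.type, ep.ProtocolTemplate))
            g.add((template, RDFS.label, Literal(kv.value)))
            g.add((prot_iri, ep.usedTemplate, template))
        elif role == "date":
            g.add((prot_iri, ep.date, Literal(kv.value)))
        else:
            g.add((prot_iri, ep[f"head_{slugify(kv.key)}"], Literal(kv.value)))

    if org_iri is not None:
        for person in persons:
            g.add((person, PROV.actedOnBehalfOf, org_iri))


def _process_row(
    g: Graph,
    row: ActivityRow,
    row_iri: URIRef,
    index: _InventoryIndex,
    generated: set[URIRef],
    config: PipelineConfig,
) -> None:
    ep = _ep(config)
    _add_generic_activity(g, row_iri, row.step_text)
    g.add((row_iri, ep.startingTime, _time_literal(row.starting_time)))

    for cls in classify_activity(row.step_text, config=config):
        g.add((row_iri, OWL.sameAs, expand_curie(cls, config)))

    for i, p in enumerate(extract_parameters(row.step_text, config)):
        add_value_specification(g, row_iri, p, config, node_label=_vs_label(row_iri, i))

    used_items: dict[str, URIRef] = {}
    for link in row.inventory_links:
        item = index.by_id.get(link.target_id)
        if item is None:
            raise KGBuildError(
                f"unresolved inventory link {link.target_id!r} "
                f"({link.anchor_text!r}) in activity {row_iri}"
            )
        item_iri = _ensure_item(g, item, config)
        g.add((row_iri, PROV.used, item_iri))
        used_items[_normalise(item.name)] = item_iri

    for mention in parse_resource_mention(row.step_text):
        if mention.passage_number is None and mention.lot_number is None:
            continue
        item = index.resolve_name(mention.name)
        if item is None:
            logger.warning("resource mention %r not in inventory; skipped", mention.name)
            continue
        item_iri = _ensure_item(g, item, config)
        instance = add_resource_instance(g, item_iri, mention, config)
        g.add((row_iri, PROV.used, instance))

    mixture = parse_mixture(row.step_text)
    if mixture is not None:
        inputs: list[URIRef] = []
        for comp in mixture.components:
            item = index.resolve_name(comp.name)
            if item is None:
                raise KGBuildError(
                    f"mixture component [{comp.category}] {comp.name!r} "
                    f"does not resolve to an inventory item"
                )
            inputs.append(_ensure_item(g, item, config))
        add_mixture(g, row_iri, mixture, inputs, config)

    for ref in row.file_links:
        basename = ref.filename.rsplit("/", 1)[-1]
        rel = f"{config.data_dir_label}/{basename}"
        file_iri = URIRef(f"{_protocol_base(row_iri, config)}/{rel}")
        g.add((file_iri, RDF.type, SCHEMA.MediaObject))
        g.add((file_iri, RDF.type, PROV.Entity))
        g.add((file_iri, SCHEMA.name, Literal(rel)))
        g.add((file_iri, RDFS.label, Literal(basename)))
        if file_iri in generated:
            g.add((row_iri, PROV.used, file_iri))
        else:
            g.add((file_iri, PROV.wasGeneratedBy, row_iri))
            generated.add(file_iri)


def _vs_label(row_iri: URIRef, i: int) -> str:
    return "vs_" + hashlib.sha256(str(row_iri).encode()).hexdigest()[:10] + f"_{i}"


def _protocol_base(row_iri: URIRef, config: PipelineConfig) -> str:
    # <base><pid>/<slug>/<row> -> <base><pid>
    rest = str(row_iri)[len(config.base_iri):]
    pid = rest.split("/", 1)[0]
    return config.base_iri + pid


def build_graph(
    protocol: ElnProtocol,
    inventory: list[InventoryItemDoc],
    config: PipelineConfig = DEFAULT_CONFIG,
    graph: Graph | None = None,
) -> Graph:
    """Translate one parsed protocol (plus its inventory) into RDF.

    Pre-condition: every inventory link in the protocol resolves against
    *inventory*.  Passing an existing *graph* accumulates several protocols
    into one store; a protocol IRI that is already present raises.
    """
    g = graph if graph is not None else new_graph(config)
    index = _InventoryIndex(inventory)
    pid = protocol.protocol_id
    prot_iri = URIRef(f"{config.base_iri}{pid}/protocol")
    if (prot_iri, RDF.type, PROV.Activity) in g:
        raise KGBuildError(f"duplicate protocol IRI {prot_iri}")

    _add_generic_activity(g, prot_iri, protocol.title)
    _attach_head(g, prot_iri, protocol, config)

    generated: set[URIRef] = set()
    rule_counters: dict[int, int] = {}
    prev_section: URIRef | None = None
    for section in protocol.iter_sections():
        if not section.heading and not section.activity_rows:
            continue
        slug = section_slug(section.heading, rule_counters, config)
        sec_iri = URIRef(f"{config.base_iri}{pid}/{slug}")
        _add_generic_activity(g, sec_iri, section.heading)
        g.add((prot_iri, HAS_PART, sec_iri))
        if prev_section is not None:
            g.add((sec_iri, PROV.wasInformedBy, prev_section))
        prev_section = sec_iri

        for i, p in enumerate(extract_parameters(section.heading, config)):
            add_value_specification(g, sec_iri, p, config, node_label=_vs_label(sec_iri, i))

        prev_row: URIRef | None = None
        for row in section.activity_rows:
            row_iri = URIRef(f"{sec_iri}/{row.row_index}")
            _process_row(g, row, row_iri, index, generated, config)
            g.add((sec_iri, HAS_PART, row_iri))
            if prev_row is not None:
                g.add((row_iri, PROV.wasInformedBy, prev_row))
            prev_row = row_iri
    return g


def link_external_ids(g: Graph, config: PipelineConfig = DEFAULT_CONFIG) -> Graph:
    """Add ``owl:sameAs`` links for configured ORCID / ROR / item mappings."""
    for name, orcid in config.person_orcid.items():
        for person in g.subjects(SCHEMA.name, Literal(name)):
            if (person, RDF.type, PROV.Person) in g:
                g.add((person, OWL.sameAs, URIRef(orcid)))
    for name, ror in config.organization_ror.items():
        for org in g.subjects(SCHEMA.name, Literal(name)):
            if (org, RDF.type, PROV.Organization) in g:
                g.add((org, OWL.sameAs, URIRef(ror)))
    for name, target in config.item_sameas.items():
        for item in g.subjects(SCHEMA.name, Literal(name)):
            if (item, RDF.type, SCHEMA.IndividualProduct) in g:
                g.add((item, OWL.sameAs, expand_curie(target, config)))
    return g
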