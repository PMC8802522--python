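"""Knowledge-graph construction: hierarchy, sequence, entities, dedup."""

import pytest
from rdflib import Literal, URIRef
from rdflib.namespace import OWL, PROV, RDF, XSD

from elnprov import (
    add_mixture,
    add_resource_instance,
    add_value_specification,
    build_graph,
    link_external_ids,
    parse_mixture,
    parse_protocol,
    parse_resource_mention,
)
from elnprov.config import DEFAULT_CONFIG, PipelineConfig
from elnprov.kg import (
    ACHIEVES_PLANNED_OBJECTIVE,
    HAS_MEASUREMENT_UNIT_LABEL,
    HAS_PART,
    HAS_SPECIFIED_INPUT,
    HAS_SPECIFIED_OUTPUT,
    HAS_VALUE_SPECIFICATION,
    OBO,
    SCHEMA,
    KGBuildError,
    new_graph,
)
from elnprov.parser import InventoryItemDoc
from elnprov.textmine import ParameterMention

EP = DEFAULT_CONFIG.vocab_iri
BASE = DEFAULT_CONFIG.base_iri


def _mini_activity(g, iri="https://example.org/act/1"):
    act = URIRef(iri)
    g.add((act, RDF.type, PROV.Activity))
    return act


# --------------------------------------------------------------------------
# value specifications
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "value,unit_token,unit_class",
    [(5.0, "min", OBO.UO_0000031), (7.9, "Hz", OBO.UO_0000106)],
)
def test_value_specification(value, unit_token, unit_class):
    g = new_graph()
    act = _mini_activity(g)
    p = ParameterMention(value, unit_token, DEFAULT_CONFIG.unit_map[unit_token], (0, 1))
    node = add_value_specification(g, act, p)
    assert (act, HAS_VALUE_SPECIFICATION, node) in g
    assert (node, OBO.OBI_0001937, Literal(value, datatype=XSD.decimal)) in g
    assert (node, HAS_MEASUREMENT_UNIT_LABEL, unit_class) in g


def test_value_specification_requires_existing_activity():
    g = new_graph()
    p = ParameterMention(5.0, "min", "obo:UO_0000031", (0, 1))
    with pytest.raises(KGBuildError):
        add_value_specification(g, URIRef("https://example.org/missing"), p)


def test_zero_parameters_leave_graph_unchanged():
    g = new_graph()
    _mini_activity(g)
    before = len(g)
    # no parameters extracted -> nothing to add
    assert len(g) == before


# --------------------------------------------------------------------------
# mixtures
# --------------------------------------------------------------------------

CULTURE_MEDIUM = (
    "89% [Culture Medium] DMEM + 10% [Serum] FCS + 1% [Antibiotic] Gentamicin"
)


def test_mixture_inputs_output_objective():
    g = new_graph()
    act = _mini_activity(g)
    spec = parse_mixture(CULTURE_MEDIUM)
    inputs = [URIRef(f"https://example.org/items/{i}") for i in range(3)]
    mixture = add_mixture(g, act, spec, inputs)
    assert (act, RDF.type, OBO.OBI_0000685) in g
    assert len(list(g.objects(act, HAS_SPECIFIED_INPUT))) == 3
    assert list(g.objects(act, HAS_SPECIFIED_OUTPUT)) == [mixture]
    assert len(list(g.objects(act, ACHIEVES_PLANNED_OBJECTIVE))) == 1


def test_same_recipe_shares_objective_but_not_activity_or_mixture():
    g = new_graph()
    a1 = _mini_activity(g, "https://example.org/act/1")
    a2 = _mini_activity(g, "https://example.org/act/2")
    spec1 = parse_mixture(CULTURE_MEDIUM + " (Attributed to Alice Example)")
    spec2 = parse_mixture(CULTURE_MEDIUM + " (Attributed to Bob Example)")
    inputs = [URIRef(f"https://example.org/items/{i}") for i in range(3)]
    m1 = add_mixture(g, a1, spec1, inputs)
    m2 = add_mixture(g, a2, spec2, inputs)
    assert m1 != m2
    (o1,) = g.objects(a1, ACHIEVES_PLANNED_OBJECTIVE)
    (o2,) = g.objects(a2, ACHIEVES_PLANNED_OBJECTIVE)
    assert o1 == o2
    attributed = {next(g.objects(m, PROV.wasAttributedTo)) for m in (m1, m2)}
    assert len(attributed) == 2


def test_mixture_requires_matching_inputs():
    g = new_graph()
    act = _mini_activity(g)
    spec = parse_mixture(CULTURE_MEDIUM)
    with pytest.raises(KGBuildError):
        add_mixture(g, act, spec, [URIRef("https://example.org/items/0")])


# --------------------------------------------------------------------------
# resource instances
# --------------------------------------------------------------------------

def test_resource_instance_attributes_and_dedup():
    g = new_graph()
    item = URIRef("https://example.org/items/mg63")
    (mention,) = parse_resource_mention("[Cell line] MG-63 P25 LOT 57840088")
    i1 = add_resource_instance(g, item, mention)
    i2 = add_resource_instance(g, item, mention)
    assert i1 == i2  # same (item, passage, lot) -> same IRI
    assert (i1, URIRef(EP + "is_instance_of"), item) in g
    assert (i1, URIRef(EP + "has_passage_number"), Literal(25, datatype=XSD.integer)) in g
    assert (i1, URIRef(EP + "has_lot_number"), Literal("57840088")) in g


def test_resource_instance_without_passage_or_lot():
    g = new_graph()
    item = URIRef("https://example.org/items/lsm")
    (mention,) = parse_resource_mention("[Device] LSM780")
    iri = add_resource_instance(g, item, mention)
    assert (iri, URIRef(EP + "has_passage_number"), None) not in g
    assert (iri, URIRef(EP + "has_lot_number"), None) not in g


# --------------------------------------------------------------------------
# whole-protocol graphs
# --------------------------------------------------------------------------

def test_level3_count_under_stimulation_section(graphs):
    sec = URIRef(f"{BASE}eln1124/ap_1_with_stimulation")
    assert len(list(graphs["eln1124"].objects(sec, HAS_PART))) == 15


def test_haspart_is_tree_with_single_root(graphs):
    import networkx as nx

    for g in graphs.values():
        dag = nx.DiGraph()
        activities = set(g.subjects(RDF.type, PROV.Activity))
        for s, o in g.subject_objects(HAS_PART):
            if s in activities and o in activities:
                dag.add_edge(s, o)
        assert nx.is_directed_acyclic_graph(dag)
        roots = [n for n in dag.nodes if dag.in_degree(n) == 0]
        assert len(roots) == 1
        assert str(roots[0]).endswith("/protocol")


def test_sibling_sequence_is_document_order_path(graphs, protocols):
    # wasInformedBy forms a Hamiltonian path over each sibling group
    for pid, g in graphs.items():
        parents = set(g.subjects(RDF.type, PROV.Activity))
        for parent in parents:
            children = list(g.objects(parent, HAS_PART))
            if not children:
                continue
            edges = {
                (s, o)
                for s in children
                for o in g.objects(s, PROV.wasInformedBy)
                if o in children
            }
            assert len(edges) == len(children) - 1
            # in document order: child k informed by child k-1
            def row_key(iri):
                tail = str(iri).rsplit("/", 1)[-1]
                return int(tail) if tail.isdigit() else tail

            ordered = sorted(children, key=row_key) if all(
                str(c).rsplit("/", 1)[-1].isdigit() for c in children
            ) else None
            if ordered:
                assert edges == set(zip(ordered[1:], ordered[:-1]))


def test_every_mentioned_file_has_exactly_one_generator(graphs):
    for g in graphs.values():
        files = set(g.subjects(RDF.type, SCHEMA.MediaObject))
        assert files
        for f in files:
            assert len(list(g.objects(f, PROV.wasGeneratedBy))) == 1


def test_file_mentioned_twice_generated_once_then_used():
    doc = (
        "<html><body><h2>Sec</h2>"
        "<table><tr><th>Step</th><th>Starting time</th></tr>"
        "<tr><td>create <a href='uploads/a.czi'>a.czi</a></td><td>09:00</td></tr>"
        "<tr><td>inspect <a href='uploads/a.czi'>a.czi</a></td><td>09:05</td></tr>"
        "</table></body></html>"
    )
    g = build_graph(parse_protocol(doc, "p2"), [])
    f = URIRef(f"{BASE}p2/Data/a.czi")
    assert list(g.objects(f, PROV.wasGeneratedBy)) == [URIRef(f"{BASE}p2/sec/1")]
    assert (URIRef(f"{BASE}p2/sec/2"), PROV.used, f) in g


def test_protocol_without_file_links_has_no_generated_triples():
    doc = (
        "<html><body><h2>Sec</h2>"
        "<table><tr><th>Step</th><th>Starting time</th></tr>"
        "<tr><td>wash cells</td><td>09:00</td></tr></table></body></html>"
    )
    g = build_graph(parse_protocol(doc, "p3"), [])
    assert list(g.subject_objects(PROV.wasGeneratedBy)) == []


def test_starting_time_literal_forms(graphs):
    g = graphs["eln1124"]
    ep_time = URIRef(EP + "startingTime")
    literals = set(g.objects(None, ep_time))
    typed = {l for l in literals if l.datatype == XSD.time}
    plain = {str(l) for l in literals if l.datatype is None}
    assert typed  # HH:MM:SS values become xsd:time
    assert "immediately afterwards" in plain
    assert "" in plain  # the row with a missing time


def test_unresolved_inventory_link_is_an_error():
    doc = (
        "<html><body><h2>Sec</h2>"
        "<table><tr><th>Step</th><th>Starting time</th></tr>"
        "<tr><td><a href='database.php?mode=view&id=99'>[X] ghost</a></td>"
        "<td>09:00</td></tr></table></body></html>"
    )
    with pytest.raises(KGBuildError, match="99"):
        build_graph(parse_protocol(doc, "p4"), [])


def test_duplicate_protocol_iri_is_an_error(protocols, inventory):
    g = build_graph(protocols["eln942"], inventory)
    with pytest.raises(KGBuildError, match="duplicate"):
        build_graph(protocols["eln942"], inventory, graph=g)


def test_mixture_component_must_resolve_to_inventory():
    doc = (
        "<html><body><h2>Sec</h2>"
        "<table><tr><th>Step</th><th>Starting time</th></tr>"
        "<tr><td>mix 50% [Buffer] Unknown1 + 50% [Buffer] Unknown2</td>"
        "<td>09:00</td></tr></table></body></html>"
    )
    with pytest.raises(KGBuildError, match="Unknown1"):
        build_graph(parse_protocol(doc, "p5"), [])


def test_head_information_attached_via_qualified_association(graphs):
    g = graphs["eln1124"]
    prot = URIRef(f"{BASE}eln1124/protocol")
    assocs = list(g.objects(prot, PROV.qualifiedAssociation))
    assert len(assocs) == 3  # experimentalist + two involved persons
    agents = {next(g.objects(a, PROV.agent)) for a in assocs}
    names = {str(next(g.objects(a, SCHEMA.name))) for a in agents}
    assert "Susanne Staehlke" in names


# --------------------------------------------------------------------------
# external identifiers
# --------------------------------------------------------------------------

def test_link_external_ids_adds_ror_and_orcid(graphs):
    g = graphs["eln1124"]
    org = URIRef(f"{BASE}organizations/university_medical_center_rostock")
    assert (org, OWL.sameAs, URIRef("https://ror.org/04dm1cm79")) in g
    person = URIRef(f"{BASE}agents/susanne_staehlke")
    assert (person, OWL.sameAs, URIRef("https://orcid.org/0000-0002-1825-0097")) in g


def test_item_ontology_class_from_description_becomes_sameas(graphs):
    g = graphs["eln1124"]
    mg63 = URIRef(f"{BASE}inventory/1")
    assert (mg63, OWL.sameAs, OBO.CLO_0007699) in g


def test_empty_sameas_config_changes_nothing(protocols, inventory):
    g = build_graph(protocols["eln1021"], inventory)
    before = len(g)
    link_external_ids(g, PipelineConfig())  # no maps configured
    assert len(g) == before


def test_malformed_config_iri_rejected_at_load_time(tmp_path):
    from elnprov import load_config

    cfg = tmp_path / "cfg.yaml"
    cfg.write_text("organization_ror:\n  Some Org: not-an-iri\n")
    with pytest.raises(ValueError, match="malformed IRI"):
        load_config(cfg)


# --------------------------------------------------------------------------
# cross-protocol deduplication
# --------------------------------------------------------------------------

def test_union_of_seven_graphs_smaller_than_sum(graphs):
    union = new_graph()
    total = 0
    for g in graphs.values():
        total += len(g)
        for t in g:
            union.add(t)
    assert len(union) < total  # agents, organization, items, recipes shared


def test_used_inventory_items_per_protocol(graphs):
    for g in graphs.values():
        used = {
            o
            for o in g.objects(None, PROV.used)
            if (o, RDF.type, SCHEMA.IndividualProduct) in g
        }
        assert len(used) == 22
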