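# Methods

## The provenance model

`elnprov` implements an *activity-based* retrospective-provenance model: the
documentation of an experiment is a hierarchy of activities, and everything
else (resources, agents, parameters, research data) hangs off that hierarchy.

**Activity hierarchy.** Three levels of granularity, all minted under a
configurable base IRI (`https://w3id.org/eln-provenance/` by default):

| level | source in the protocol | IRI pattern |
|-------|------------------------|-------------|
| 1 | the whole experiment | `<base>/<protocol_id>/protocol` |
| 2 | one per main (headed) section | `<base>/<protocol_id>/<section_slug>` |
| 3 | one per activity-table row | `.../<section_slug>/<row_index>` |

The hierarchy is `bfo:hasPart` (`obo:BFO_0000051`) — an acyclic tree with a
single root per protocol.  Sequential order is `prov:wasInformedBy`, chained
*within each sibling group only*: row *k* was informed by row *k−1*, section
*n* by section *n−1*.  No edge crosses levels (the last row of a section is
not linked to the first row of the next one); the level-2 chain already
carries that order, and keeping levels separable makes the step-counting
queries straightforward.  Every activity carries the generic types
`schema:Action`, `prov:Activity` and `bfo:process` (`obo:BFO_0000015`);
verb-derived ontology classes (e.g. washing, `obo:OBI_0302888`) are attached
with `owl:sameAs` rather than `rdf:type`, treating them as external
annotations of the locally minted activity.

Section slugs come from a configurable rewrite table; headings matching
"with stimulation" become `ap_<n>_with_stimulation` (with a per-protocol
counter), mirroring conventional approach identifiers, and anything else is
a plain slug of the heading.

**Head information.** The key-value table at the top of a protocol is
attached to the level-1 activity.  Persons (experimentalist, involved
persons) become `prov:Person` agents linked through
`prov:qualifiedAssociation` nodes carrying a role
(`ep:Experimentalist` / `ep:InvolvedPerson`); the organization becomes a
`prov:Organization` that the persons `prov:actedOnBehalfOf`; objective,
template and date are recorded with dedicated predicates in the tool's own
vocabulary namespace (`ep:`); unrecognised keys degrade to generic literal
annotations.

**Resources.** Inventory items linked from a step become entities of type
`schema:IndividualProduct`, connected with `prov:used`; ontology classes
found in the item description (e.g. `obo:CLO_0007699` for the MG-63 cell
line) are attached via `owl:sameAs`.  A mention carrying passage or lot
information (`[Cell line] MG-63 P25 LOT 57840088`) additionally mints a
*resource instance* connected to its item by `ep:is_instance_of` with
`ep:has_passage_number` / `ep:has_lot_number`; the instance IRI is a pure
function of (item, passage, lot), so repeated mentions — also across
protocols — reuse the same node.  `is_instance_of`, `has_passage_number`
and `has_lot_number` have no published namespace and are therefore minted in
`ep:`.

**Parameters.** Number+unit matches become blank-node value specifications:
`obo:OBI_0001938` (has value specification) from the activity,
`obo:OBI_0001937` (has specified numeric value) for the decimal value and
`obo:IAO_0000039` (has measurement unit label) pointing at the
unit-ontology class.  Blank-node labels are derived deterministically from
the activity IRI so that serialisation is reproducible.  Parameters found in
a *section heading* attach to the level-2 activity — this is what makes a
stimulation approach queryable by its settings.

**Mixtures.** A recipe match types the step as a mixture-creation activity
(`obo:OBI_0000685`), links each resolved component with
`obo:OBI_0000293` (has specified input), the resulting mixture entity with
`obo:OBI_0000299` (has specified output) and a recipe objective
(`obo:OBI_0000686`) with `obo:OBI_0000417` (achieves planned objective).
The objective IRI is a hash of the ordered component list, so the *same
recipe* always references the *same objective* while activities and mixture
entities stay distinct; an attribution note links the mixture entity to its
agent via `prov:wasAttributedTo`.

**Research data.** The first mention of a file inside a step marks its
creation: `prov:wasGeneratedBy` from the file entity to that step.  Later
mentions of the same file become `prov:used` — this tie-break keeps exactly
one generator per file.  Files attached to a protocol but never mentioned in
a step are part of the crate but have no generating activity.

## Text mining

Deliberately basic — regular expressions and lookup tables, no statistical
NLP:

* **Numbers** are `\d+([.,]\d+)?` with the decimal comma normalised to a
  point (protocols from German-speaking labs routinely mix both).
* **Units** (defaults): `min`, `ms`, `h` (time), `°C` (temperature), `Hz`
  (frequency), `V` (voltage), `ml`, `µl` (volume).  `min`/`ms`/`Hz`/`V` map
  to their published unit-ontology classes (`UO_0000031`, `UO_0000028`,
  `UO_0000106`, `UO_0000218`); the rest use the standard UO identifiers.
  `%` is reserved for mixtures and never yields a generic parameter.
  Overlaps resolve to the longest unit token; a unit glued to a longer word
  (`5mins`, `_5V_` inside a filename) is not a parameter.
* **Mixture grammar** (strict, overridable): `percent "[" category "]"
  name`, components joined by `+`, at least two components, optional
  trailing `(Attributed to NAME)`.  Component names may contain
  parentheticals (`HEPES I (isotonic)`) but not `+` or `[`.  Fractions are
  not required to sum to 100.
* **Resource mentions**: `[Category] Name` with optional `P<int>` and
  `LOT <digits>` suffixes.  The name stops at brackets, punctuation, the
  passage/lot tokens or a short connective ("at", "in", "with", …), so
  `[Device] SANYO CO2 Incubator at 37°C` yields the device name only.
  Resolution against the inventory is by exact normalised name first, then
  unique prefix, then unique substring.
* **Verbs**: the first word of the step (after lower-casing and a small
  built-in lemma table) is looked up in the verb map; the first mapped verb
  wins, including for multi-verb steps ("wash and incubate" classifies as
  washing).  Only wash/incubate/place carry published ontology classes; the
  other default verbs map to classes in the `ep:` vocabulary rather than
  guessing foreign identifiers.  All ties everywhere resolve to the first
  match.

## RO-Crate bundles

A crate holds the research data under `Data/`, HTML copies of the protocol
and inventory pages at the root, and `ro-crate-metadata.json` containing the
complete provenance graph plus the crate plumbing (root `schema:Dataset`
`./` linking every file via `schema:hasPart`; per-file `encodingFormat`,
`contentSize` and a checksum, SHA-256 by default, with the algorithm
recorded).  Two deliberate deviations from stock RO-Crate 1.1 conventions:

* the `@context` is an **inline prefix map**, not the published remote
  context IRI, so descriptors parse without network access;
* research-data file entities keep the knowledge graph's absolute IRI as
  their `@id` (the graph and the crate then describe the same node) and
  record the crate-relative path in `schema:name`.  HTML copies, which the
  graph does not mention, use plain relative-path `@id`s.

The descriptor is emitted by a deterministic JSON-LD writer (entities and
values sorted, stable blank-node labels, `json.dumps(sort_keys=True)`), so
identical inputs produce byte-identical descriptors.  `validate_crate`
checks descriptor parseability, root-dataset typing, `hasPart` coverage in
both directions (every referenced file on disk, every on-disk file
referenced) and size/checksum integrity; violations are returned as data,
not raised.  CZI has no IANA media type; the default label
`application/vnd.zeiss.czi` is a config entry.

## Query service

The seven W7 questions ship as SPARQL files (`src/elnprov/queries/*.rq`)
with documented binding slots; execution is in-memory on an rdflib dataset
with one named graph per crate (loading is idempotent, and each triple's
source crate is preserved).  The same query text works against any external
SPARQL 1.1 endpoint loaded with the descriptors.  Execution order is
recovered by counting `prov:wasInformedBy+` predecessors; the
order-comparison question returns one SPARQL row per stimulation approach,
which the service folds into one row per experiment
(`7.9Hz, 1V | 7.9Hz, 5V | …`).  An optional pseudonymisation update replaces
person names with `PersonN Anonymous` (stable numbering, keep-list for
names that are already pseudonyms).

## The fixture generator

The generator emulates the documentation of a calcium-imaging study of
intracellular Ca²⁺ dynamics under electrical stimulation, at the study's
documented scale: **seven protocols**, each composed of four sub-template
parts (Preparation; Fluo-3 Staining; one Ca-imaging-with-Stimulation section
per setting, **15 atomic steps** each; Ca-imaging without Stimulation), all
referring to a shared **22-item inventory**, with the seven published
permutations of the stimulation settings (7.9/20 Hz × 1/5 V; one protocol
has five entries because a setting was repeated after an imaging issue).
Starting times alternate `HH:MM:SS` timestamps, the phrase "immediately
afterwards" and one missing value, so both literal branches are exercised.
Each stimulation approach uploads five dummy files (two CZI stubs, two tiny
JPEGs, one small XML table) numbered consecutively across the protocol, so
approach 1's time series is `02_Zeitserie-Stimulation_<v>V_<f>Hz.czi`.
Attachment payloads are seeded pseudo-random bytes (CZI), a seeded 8×8 JPEG
and a seeded XML table — only name, size and checksum matter downstream.
Head-block field names (Experimentalist, Involved persons, Objective,
Organization, Template, Date) follow the answers the W7 queries are expected
to give and are config-overridable.

What the fixtures do **not** emulate: real microscopy content (files are
KB-scale stubs instead of ~100 MB CZI containers), free-text deviations from
the template (every generated protocol is perfectly regular), OCR noise or
hand-written markup irregularities beyond what the parser tests inject, and
multilingual step texts.  Passing tests therefore demonstrate the
structure-exploitation and modelling rules, not robustness to arbitrary
real-world ELN exports; 18 of the 22 inventory items are named in the
documented use case, the remaining 4 are realistic Ca-imaging consumables.

## Numerical and degenerate-input choices

* Starting times matching `HH:MM[:SS]` become `xsd:time` literals
  (normalised to `HH:MM:SS`); anything else — including "immediately
  afterwards" and the empty string — stays a plain literal.
* Empty protocol input is a structured error; a document without headings
  degrades to a single implicit root section with a warning; a row without
  a time cell gets an empty starting time with a warning.  All data loss is
  reported through the module loggers, never swallowed.
* Unresolved inventory links and unresolvable mixture components are hard
  errors (the graph would otherwise silently lose the resource semantics);
  unresolvable passage/lot mentions only warn.
* Inventory links are recognised by href substring (`database.php`,
  `/items/` by default); every other anchor is a file link.
* Level-2 sections do not aggregate the `prov:used` links of their rows;
  resource usage stays at the level where it is documented.

## Known limitations

* The verb and unit maps are small lookup tables; terms outside them keep
  only generic typing.  Entity disambiguation beyond name lookup is out of
  scope.
* No TBox authoring, reasoning, SHACL validation, BagIt/OCFL packaging,
  repository deposit or live ELN API access.
* The W7 query texts are reconstructions validated against the fixture
  suite; a differently-shaped graph would need adapted queries.
* Duplicate file basenames across crates are allowed (they are distinct
  nodes); a bare-filename binding for the "how" question can therefore
  match several crates when queried over a multi-crate store.
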