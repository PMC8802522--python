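"""Pipeline configuration: lookup tables that drive text mining and graph building.

Everything that is a *mapping decision* rather than an algorithm lives here:
the verb -> ontology-class map, the unit -> unit-ontology map, URL patterns
that distinguish inventory links from file links, IRI minting bases, and the
optional owl:sameAs maps (ORCID for persons, ROR for organizations, ontology
classes / Wikidata for inventory items).  All of it can be overridden from a
YAML file so the pipeline can be retargeted at a differently configured ELN
without code changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

#: Base IRI under which all protocol-local resources are minted.
DEFAULT_BASE_IRI = "https://w3id.org/eln-provenance/"

#: Namespace for relations and classes this tool defines itself (the ones the
#: source material introduces without a namespace: is_instance_of,
#: has_lot_number, has_passage_number, ...).
VOCAB_IRI = "https://w3id.org/eln-provenance/vocab#"

OBO = "http://purl.obolibrary.org/obo/"

# Units are identified in free text by their token; each token maps to exactly
# one unit-ontology class.  min/ms/V/Hz use the classes printed alongside the
# use case; the remaining tokens use the standard UO identifiers.
DEFAULT_UNIT_MAP: dict[str, str] = {
    "min": "obo:UO_0000031",   # minute
    "ms": "obo:UO_0000028",    # millisecond
    "h": "obo:UO_0000032",     # hour
    "°C": "obo:UO_0000027",    # degree Celsius
    "Hz": "obo:UO_0000106",    # hertz
    "V": "obo:UO_0000218",     # volt
    "ml": "obo:UO_0000098",    # milliliter
    "µl": "obo:UO_0000101",    # microliter
}

# Head-verb -> ontology classes.  wash / incubate / place carry published OBO
# classes; verbs with no published class are typed in the tool's own
# vocabulary namespace (prefix "ep") rather than guessing foreign identifiers.
DEFAULT_VERB_MAP: dict[str, list[str]] = {
    "wash": ["obo:OBI_0302888"],
    "incubate": ["obo:OMIT_0005807", "obo:OBI_0001007", "obo:OBI_0302893"],
    "place": ["obo:NCIT_C52253"],
    "prepare": ["ep:Preparing"],
    "centrifuge": ["ep:Centrifuging"],
    "aspirate": ["ep:Aspirating"],
    "resuspend": ["ep:Resuspending"],
    "transfer": ["ep:Transferring"],
    "add": ["ep:Adding"],
    "take": ["ep:TakingOut"],
    "seed": ["ep:Seeding"],
    "detach": ["ep:Detaching"],
    "count": ["ep:Counting"],
    "stain": ["ep:Staining"],
    "record": ["ep:Recording"],
    "mix": ["ep:Mixing"],
}

# Trivial lemma table for head-verb detection (inflected form -> lemma).
DEFAULT_LEMMA_TABLE: dict[str, str] = {
    "washed": "wash", "washing": "wash", "washes": "wash",
    "incubated": "incubate", "incubating": "incubate", "incubates": "incubate",
    "placed": "place", "placing": "place",
    "prepared": "prepare", "preparing": "prepare",
    "centrifuged": "centrifuge", "centrifuging": "centrifuge",
    "added": "add", "adding": "add",
    "transferred": "transfer", "transferring": "transfer",
    "seeded": "seed", "seeding": "seed",
    "stained": "stain", "staining": "stain",
    "recorded": "record", "recording": "record",
    "counted": "count", "counting": "count",
    "mixed": "mix", "mixing": "mix",
}

# Well-known CURIE prefixes accepted when scanning inventory descriptions for
# external ontology class references.
DEFAULT_CURIE_PREFIXES: tuple[str, ...] = (
    "obo", "CLO", "OBI", "CHEBI", "NCIT", "UO", "IAO", "BTO", "wd", "schema",
)

# Anchor hrefs matching any of these substrings are treated as inventory-item
# links (elabFTW's inventory lives under database.php); anything else that
# resolves to an uploaded file is a file link.
DEFAULT_INVENTORY_HREF_PATTERNS: tuple[str, ...] = ("database.php", "/items/")

# Section headings are slugged for IRI minting; headings matching a rule get
# the rule's template (with {n} an ordinal counter over matches of that rule),
# everything else falls back to a generic slug.  The defaults mirror the
# published activity identifiers (ap_1_with_stimulation, ...).
DEFAULT_SECTION_SLUG_RULES: tuple[tuple[str, str], ...] = (
    (r"(?i)with\s+stimulation", "ap_{n}_with_stimulation"),
    (r"(?i)without\s+stimulation", "ap_without_stimulation"),
)

# Head key-value keys (lower-cased) that receive dedicated modelling rather
# than a generic literal annotation on the protocol association.
DEFAULT_HEAD_FIELD_ROLES: dict[str, str] = {
    "experimentalist": "experimentalist",
    "experimenter": "experimentalist",
    "involved persons": "involved",
    "objective": "objective",
    "organization": "organization",
    "organisation": "organization",
    "template": "template",
    "date": "date",
}

#: Media-type table for crate file metadata.  CZI has no IANA registration;
#: the vendor-style label below is itself a config entry.
DEFAULT_MIME_MAP: dict[str, str] = {
    ".czi": "application/vnd.zeiss.czi",
    ".jpg": "image/jpeg",
    ".jpeg": "image/jpeg",
    ".xml": "application/xml",
    ".html": "text/html",
    ".json": "application/ld+json",
    ".txt": "text/plain",
    ".csv": "text/csv",
}

NUMBER_PATTERN = r"\d+(?:[.,]\d+)?"


@dataclass(frozen=True)
class PipelineConfig:
    """Immutable bag of lookup tables used across the pipeline."""

    base_iri: str = DEFAULT_BASE_IRI
    vocab_iri: str = VOCAB_IRI
    unit_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_UNIT_MAP))
    verb_map: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_VERB_MAP.items()}
    )
    lemma_table: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LEMMA_TABLE))
    curie_prefixes: tuple[str, ...] = DEFAULT_CURIE_PREFIXES
    inventory_href_patterns: tuple[str, ...] = DEFAULT_INVENTORY_HREF_PATTERNS
    section_slug_rules: tuple[tuple[str, str], ...] = DEFAULT_SECTION_SLUG_RULES
    head_field_roles: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_HEAD_FIELD_ROLES)
    )
    mime_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MIME_MAP))
    number_pattern: str = NUMBER_PATTERN
    #: crate-internal directory for research data files
    data_dir_label: str = "Data"
    checksum_algorithm: str = "sha256"
    # owl:sameAs maps applied by link_external_ids
    person_orcid: dict[str, str] = field(default_factory=dict)
    organization_ror: dict[str, str] = field(default_factory=dict)
    item_sameas: dict[str, str] = field(default_factory=dict)

    def unit_tokens_longest_first(self) -> list[str]:
        return sorted(self.unit_map, key=len, reverse=True)


_IRI_RE = re.compile(r"^https?://\S+$")


def _validate_sameas(mapping: dict[str, str], what: str) -> None:
    for key, iri in mapping.items():
        if not _IRI_RE.match(iri):
            raise ValueError(f"malformed IRI in {what} map for {key!r}: {iri!r}")


def load_config(path: str | Path | None = None, **overrides: Any) -> PipelineConfig:
    """Build a :class:`PipelineConfig`, optionally overridden from a YAML file.

    The YAML schema is flat: any top-level key matching a ``PipelineConfig``
    field replaces that field (dicts replace wholesale, they are not merged).
    Unknown keys raise, so typos fail loudly at load time.
    """
    cfg = PipelineConfig()
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    data.update(overrides)
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    # normalise list-like fields loaded from YAML
    for key in ("inventory_href_patterns", "curie_prefixes"):
        if key in data:
            data[key] = tuple(data[key])
    if "section_slug_rules" in data:
        data["section_slug_rules"] = tuple(tuple(r) for r in data["section_slug_rules"])
    cfg = replace(cfg, **data)
    _validate_sameas(cfg.person_orcid, "person_orcid")
    _validate_sameas(cfg.organization_ror, "organization_ror")
    _validate_sameas(cfg.item_sameas, "item_sameas")
    return cfg


DEFAULT_CONFIG = PipelineConfig()
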