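"""Read ELN protocol and inventory-item HTML exports into a document model.

ELN software such as elabFTW exports an experiment record as one HTML page:
a key-value table with general information at the top (experimenter,
objective, organization, ...), followed by headed sections each of which
contains an *activity table* — two columns, "Step" and "Starting time", one
atomic activity per row.  Steps link inventory-database items (resources,
devices, software) and uploaded research-data files.  This module turns such
a page into an :class:`ElnProtocol` tree without losing document order.

The parser is deliberately tolerant: lxml's HTML parser repairs unclosed
tags, missing headings degrade to a single implicit root section, and any
data loss is reported through the module logger instead of an exception.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from urllib.parse import parse_qs, urlparse

from lxml import etree, html

from .config import DEFAULT_CONFIG, PipelineConfig

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Structured parsing failure (e.g. empty input)."""


# --------------------------------------------------------------------------
# document model
# --------------------------------------------------------------------------

@dataclass
class KeyValuePair:
    key: str
    value: str

    def __post_init__(self) -> None:
        if not self.key:
            raise ValueError("KeyValuePair.key must be non-empty")


@dataclass
class InventoryLink:
    target_id: str
    anchor_text: str

    def __post_init__(self) -> None:
        if not self.target_id:
            raise ValueError("InventoryLink.target_id must be non-empty")


@dataclass
class AttachmentRef:
    filename: str  # relative path
    anchor_text: str

    def __post_init__(self) -> None:
        if not self.filename:
            raise ValueError("AttachmentRef.filename must be non-empty")
        if self.filename.startswith("/"):
            raise ValueError(f"AttachmentRef.filename must be relative: {self.filename!r}")


@dataclass
class ActivityRow:
    step_html: str
    step_text: str
    starting_time: str
    inventory_links: list[InventoryLink] = field(default_factory=list)
    file_links: list[AttachmentRef] = field(default_factory=list)
    row_index: int = 1


@dataclass
class SectionNode:
    heading: str
    level: int
    key_values: list[KeyValuePair] = field(default_factory=list)
    activity_rows: list[ActivityRow] = field(default_factory=list)
    children: list["SectionNode"] = field(default_factory=list)

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class ElnProtocol:
    protocol_id: str
    title: str
    head: list[KeyValuePair] = field(default_factory=list)
    sections: list[SectionNode] = field(default_factory=list)
    attachments: list[AttachmentRef] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.protocol_id:
            raise ValueError("protocol_id must be non-empty")

    def iter_sections(self):
        for s in self.sections:
            yield from s.walk()

    def head_value(self, key: str) -> str | None:
        key = key.strip().lower()
        for kv in self.head:
            if kv.key.strip().lower() == key:
                return kv.value
        return None


@dataclass
class InventoryItemDoc:
    item_id: str
    category: str
    name: str
    properties: list[KeyValuePair] = field(default_factory=list)
    external_class_refs: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

_WS_RE = re.compile(r"[\s ]+")


def _norm(text: str | None) -> str:
    """Collapse whitespace (incl. non-breaking spaces) and strip."""
    return _WS_RE.sub(" ", text or "").strip()


def _text_of(el: etree._Element) -> str:
    return _norm(" ".join(el.itertext()))


def _inner_html(el: etree._Element) -> str:
    parts = [el.text or ""]
    for child in el:
        parts.append(html.tostring(child, encoding="unicode"))
    return "".join(parts).strip()


def _parse_html(document: str) -> etree._Element:
    if not document or not document.strip():
        raise ParseError("empty input")
    root = html.fromstring(document)
    return root


def _is_inventory_href(href: str, config: PipelineConfig) -> bool:
    return any(pat in href for pat in config.inventory_href_patterns)


def _inventory_target_id(href: str) -> str:
    """Extract the item identifier from an inventory link href.

    elabFTW style links look like ``database.php?mode=view&id=12``; the ``id``
    query parameter wins, otherwise the last non-empty path segment is used.
    """
    parsed = urlparse(href)
    qs = parse_qs(parsed.query)
    if "id" in qs and qs["id"]:
        return qs["id"][0]
    segments = [s for s in parsed.path.split("/") if s]
    return segments[-1] if segments else href


def _harvest_links(
    el: etree._Element, config: PipelineConfig
) -> tuple[list[InventoryLink], list[AttachmentRef]]:
    inv: list[InventoryLink] = []
    files: list[AttachmentRef] = []
    for a in el.iter("a"):
        href = a.get("href") or ""
        if not href:
            continue
        text = _text_of(a)
        if _is_inventory_href(href, config):
            inv.append(InventoryLink(target_id=_inventory_target_id(href), anchor_text=text))
        else:
            filename = urlparse(href).path.lstrip("/")
            if filename:
                files.append(AttachmentRef(filename=filename, anchor_text=text))
    return inv, files


# --------------------------------------------------------------------------
# table classification and extraction
# --------------------------------------------------------------------------

def classify_table(table: etree._Element | str) -> str:
    """Classify a ``<table>`` as ``key_value``, ``activity_list`` or ``other``.

    A table is an activity list iff its header row carries both labels
    "Step" and "Starting time" (case-insensitive, whitespace-normalised);
    a two-column table without those headers is a key-value mapping;
    everything else is ``other``.
    """
    if isinstance(table, str):
        table = html.fragment_fromstring(table)
    if table.tag != "table":
        raise ValueError("classify_table expects a <table> element")
    rows = table.findall(".//tr")
    if not rows:
        return "other"
    header_cells = [_norm(c.text_content()).lower() for c in rows[0].findall("./th")]
    if not header_cells:
        header_cells = [_norm(c.text_content()).lower() for c in rows[0].findall("./td")]
    if "step" in header_cells and "starting time" in header_cells:
        return "activity_list"
    ncols = max(len(r.findall("./th")) + len(r.findall("./td")) for r in rows)
    if ncols == 2:
        return "key_value"
    return "other"


def extract_activity_rows(
    table: etree._Element | str, config: PipelineConfig = DEFAULT_CONFIG
) -> list[ActivityRow]:
    """One :class:`ActivityRow` per body row of an activity table, in order.

    Nested enumerations and lists inside the Step cell are kept verbatim in
    ``step_html`` — third-level structure is not split further.  A row with a
    missing time cell gets ``starting_time == ""`` and a warning.
    """
    if isinstance(table, str):
        table = html.fragment_fromstring(table)
    if classify_table(table) != "activity_list":
        raise ValueError("not an activity table")
    rows = table.findall(".//tr")
    header = rows[0]
    labels = [_norm(c.text_content()).lower() for c in header.findall("./th") + header.findall("./td")]
    step_i = labels.index("step")
    time_i = labels.index("starting time")
    out: list[ActivityRow] = []
    for idx, tr in enumerate(rows[1:], start=1):
        cells = tr.findall("./td") + tr.findall("./th")
        if not cells:
            continue
        step_cell = cells[step_i] if step_i < len(cells) else None
        if step_cell is None:
            logger.warning("activity row %d has no step cell; skipped", idx)
            continue
        if time_i < len(cells):
            starting_time = _norm(cells[time_i].text_content())
        else:
            starting_time = ""
            logger.warning("activity row %d missing time cell; starting_time set empty", idx)
        inv, files = _harvest_links(step_cell, DEFAULT_CONFIG if config is None else config)
        out.append(
            ActivityRow(
                step_html=_inner_html(step_cell),
                step_text=_text_of(step_cell),
                starting_time=starting_time,
                inventory_links=inv,
                file_links=files,
                row_index=len(out) + 1,
            )
        )
    return out


def _extract_key_values(table: etree._Element) -> list[KeyValuePair]:
    pairs: list[KeyValuePair] = []
    for tr in table.findall(".//tr"):
        cells = tr.findall("./th") + tr.findall("./td")
        if len(cells) < 2:
            continue
        key = _norm(cells[0].text_content())
        if not key:
            logger.warning("key-value row with empty key skipped")
            continue
        pairs.append(KeyValuePair(key=key, value=_norm(cells[1].text_content())))
    return pairs


# --------------------------------------------------------------------------
# protocol parsing
# --------------------------------------------------------------------------

_HEADING_TAGS = {f"h{i}": i for i in range(1, 7)}


def parse_protocol(
    html_document: str, protocol_id: str, config: PipelineConfig = DEFAULT_CONFIG
) -> ElnProtocol:
    """Parse one protocol page into an :class:`ElnProtocol`.

    The section tree mirrors heading nesting (h1–h6 tag rank only; bold
    paragraphs never start sections).  Tables are classified and dispatched:
    key-value tables before the first heading populate the protocol head,
    key-value tables inside sections populate the section, activity tables
    yield activity rows.  All links are harvested, with inventory links told
    apart from file links by href pattern.
    """
    root = _parse_html(html_document)
    title_el = root.find(".//title")
    title = _norm(title_el.text_content()) if title_el is not None else ""

    body = root.find(".//body")
    if body is None:
        body = root

    protocol = ElnProtocol(protocol_id=protocol_id, title=title)

    # walk the body in document order, maintaining a section stack
    implicit_root = SectionNode(heading="", level=0)
    stack: list[SectionNode] = [implicit_root]
    saw_heading = False

    def current() -> SectionNode:
        return stack[-1]

    for el in body.iter():
        tag = el.tag if isinstance(el.tag, str) else ""
        if tag in _HEADING_TAGS:
            saw_heading = True
            level = _HEADING_TAGS[tag]
            node = SectionNode(heading=_text_of(el), level=level)
            while stack[-1].level >= level:
                stack.pop()
            stack[-1].children.append(node)
            stack.append(node)
        elif tag == "table":
            kind = classify_table(el)
            if kind == "activity_list":
                rows = extract_activity_rows(el, config)
                base = len(current().activity_rows)
                for r in rows:
                    r.row_index = base + r.row_index if base else r.row_index
                current().activity_rows.extend(rows)
                for r in rows:
                    protocol.attachments.extend(r.file_links)
            elif kind == "key_value":
                pairs = _extract_key_values(el)
                if current() is implicit_root and not saw_heading:
                    protocol.head.extend(pairs)
                elif current() is implicit_root:
                    protocol.head.extend(pairs)
                else:
                    current().key_values.extend(pairs)
            else:
                logger.debug("table of kind 'other' ignored for structure")

    if not title and implicit_root.children:
        protocol.title = implicit_root.children[0].heading

    if not saw_heading:
        logger.warning("protocol %s has no headings; using implicit root section", protocol_id)
        implicit_root.heading = title or protocol_id
        implicit_root.level = 1
        protocol.sections = [implicit_root]
    else:
        protocol.sections = implicit_root.children
        # stray rows collected outside any heading stay on an implicit section
        if implicit_root.activity_rows:
            pre = SectionNode(heading="", level=1, activity_rows=implicit_root.activity_rows)
            protocol.sections.insert(0, pre)
    return protocol


# --------------------------------------------------------------------------
# inventory item parsing
# --------------------------------------------------------------------------

def _curie_regex(config: PipelineConfig) -> re.Pattern[str]:
    prefixes = "|".join(re.escape(p) for p in config.curie_prefixes)
    return re.compile(rf"\b(?:{prefixes}):[A-Za-z0-9_][A-Za-z0-9_.-]*\b")


_IRI_TOKEN_RE = re.compile(r"https?://[^\s<>\"']+")


def parse_inventory_item(
    html_document: str, item_id: str, config: PipelineConfig = DEFAULT_CONFIG
) -> InventoryItemDoc:
    """Parse one inventory-item page.

    Properties come from the page's key-value table; the category is the
    value of a "Category" property (missing -> "uncategorised" plus a
    warning); external ontology references are any CURIE- or IRI-shaped
    tokens in the page text.
    """
    root = _parse_html(html_document)
    title_el = root.find(".//title")
    name = _norm(title_el.text_content()) if title_el is not None else ""
    if not name:
        h = root.find(".//h1")
        name = _text_of(h) if h is not None else item_id

    properties: list[KeyValuePair] = []
    for table in root.iter("table"):
        if classify_table(table) == "key_value":
            properties.extend(_extract_key_values(table))

    category = ""
    for kv in properties:
        if kv.key.strip().lower() == "category":
            category = kv.value
            break
    if not category:
        category = "uncategorised"
        logger.warning("inventory item %s has no category; set to 'uncategorised'", item_id)

    text = _norm(" ".join(root.itertext()))
    refs: list[str] = []
    for m in _IRI_TOKEN_RE.finditer(text):
        refs.append(m.group(0).rstrip(".,;)"))
    for m in _curie_regex(config).finditer(text):
        refs.append(m.group(0))
    # de-duplicate, preserving order
    seen: set[str] = set()
    refs = [r for r in refs if not (r in seen or seen.add(r))]

    return InventoryItemDoc(
        item_id=item_id, category=category, name=name,
        properties=properties, external_class_refs=refs,
    )
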