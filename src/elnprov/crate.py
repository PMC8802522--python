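"""Assemble and validate ready-to-publish RO-Crate bundles.

A crate is a directory with a JSON-LD descriptor ``ro-crate-metadata.json``
whose root data entity is a ``schema:Dataset`` linking every contained file
via ``hasPart``.  The bundle holds the research-data files (under ``Data/``),
human-readable HTML copies of the ELN protocol and the inventory items, and
the complete provenance graph merged into the descriptor.  Each file entity
carries integrity metadata: media type, byte size and checksum.

Two conscious deviations from stock RO-Crate 1.1 conventions, both in the
name of deterministic, network-free round-trips:

* the ``@context`` is an inline prefix map instead of the published remote
  context IRI (a remote context would require dereferencing at parse time);
* research-data file entities keep the knowledge graph's absolute IRI as
  their ``@id`` (so graph and crate describe the same nodes) and record the
  crate-relative path in ``schema:name``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import RDF, XSD

from .config import DEFAULT_CONFIG, PipelineConfig
from .kg import SCHEMA, _prefix_map

logger = logging.getLogger(__name__)

METADATA_FILENAME = "ro-crate-metadata.json"
PREVIEW_FILENAME = "ro-crate-preview.html"
DCTERMS = "http://purl.org/dc/terms/"
ROCRATE_SPEC = "https://w3id.org/ro/crate/1.1"


class CrateError(RuntimeError):
    pass


@dataclass(frozen=True)
class FileMeta:
    path: str  # crate-relative
    mime_type: str
    size_bytes: int
    checksum: str  # hex digest
    algorithm: str = "sha256"


@dataclass
class CrateBundle:
    root_dir: Path
    metadata_descriptor: dict
    files: list[FileMeta] = field(default_factory=list)
    html_copies: list[str] = field(default_factory=list)

    @property
    def descriptor_path(self) -> Path:
        return self.root_dir / METADATA_FILENAME


def file_metadata(path: str | Path, config: PipelineConfig = DEFAULT_CONFIG,
                  rel_path: str | None = None) -> FileMeta:
    """Media type (by extension, fallback octet-stream), size and checksum."""
    p = Path(path)
    if not p.is_file():
        raise CrateError(f"cannot read file {p}")
    mime = config.mime_map.get(p.suffix.lower(), "application/octet-stream")
    data = p.read_bytes()
    digest = hashlib.new(config.checksum_algorithm, data).hexdigest()
    return FileMeta(
        path=rel_path or p.name,
        mime_type=mime,
        size_bytes=len(data),
        checksum=digest,
        algorithm=config.checksum_algorithm,
    )


# --------------------------------------------------------------------------
# deterministic JSON-LD emission
# --------------------------------------------------------------------------

def _compact(iri: str, prefixes: dict[str, str]) -> str:
    best_prefix, best_ns = "", ""
    for prefix, ns in prefixes.items():
        if iri.startswith(ns) and len(ns) > len(best_ns):
            best_prefix, best_ns = prefix, ns
    if best_ns and len(iri) > len(best_ns):
        return f"{best_prefix}:{iri[len(best_ns):]}"
    return iri


def _term_to_jsonld(term, prefixes: dict[str, str]):
    if isinstance(term, URIRef):
        return {"@id": _compact(str(term), prefixes)}
    if isinstance(term, BNode):
        return {"@id": f"_:{term}"}
    assert isinstance(term, Literal)
    if term.datatype and term.datatype != XSD.string:
        return {"@value": str(term), "@type": _compact(str(term.datatype), prefixes)}
    return str(term)


def _sort_key(value) -> tuple:
    if isinstance(value, dict):
        return (1, value.get("@id", value.get("@value", "")), value.get("@type", ""))
    return (0, str(value), "")


def graph_to_entities(graph: Graph, prefixes: dict[str, str]) -> list[dict]:
    """Flatten an RDF graph into a sorted list of JSON-LD node objects."""
    nodes: dict[str, dict] = {}
    for s, p, o in graph:
        sid = f"_:{s}" if isinstance(s, BNode) else _compact(str(s), prefixes)
        node = nodes.setdefault(sid, {"@id": sid})
        if p == RDF.type and isinstance(o, URIRef):
            node.setdefault("@type", []).append(_compact(str(o), prefixes))
            continue
        key = _compact(str(p), prefixes)
        node.setdefault(key, []).append(_term_to_jsonld(o, prefixes))
    for node in nodes.values():
        for key, values in list(node.items()):
            if key == "@id":
                continue
            values.sort(key=_sort_key)
            node[key] = values[0] if len(values) == 1 else values
    return sorted(nodes.values(), key=lambda n: n["@id"])


def _context(config: PipelineConfig) -> dict[str, str]:
    ctx = dict(sorted(_prefix_map(config).items()))
    ctx["dcterms"] = DCTERMS
    return ctx


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def _copy_into(src: Path, dest: Path) -> None:
    if dest.exists():
        raise CrateError(f"path collision inside crate: {dest}")
    dest.parent.mkdir(parents=True, exist_ok=True)
    shutil.copyfile(src, dest)


def _file_entity_id(graph: Graph, rel: str, prefixes: dict[str, str]) -> str:
    """The graph node for a copied file, if the graph mentions it."""
    for subject in graph.subjects(SCHEMA.name, Literal(rel)):
        if (subject, RDF.type, SCHEMA.MediaObject) in graph:
            return _compact(str(subject), prefixes)
    return rel


def assemble_crate(
    graph: Graph,
    data_files: list[str | Path],
    html_copies: list[str | Path],
    out_dir: str | Path,
    config: PipelineConfig = DEFAULT_CONFIG,
    crate_name: str = "",
    preview: bool = False,
) -> CrateBundle:
    """Copy all inputs into *out_dir* and write the JSON-LD descriptor.

    Data files land under ``Data/``, HTML copies at the crate root.  The
    provenance graph is merged into the descriptor; every copied file gets a
    file entity with media type, size and checksum, reachable from the root
    dataset via ``hasPart``.  Assembly is deterministic for identical inputs.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        raise CrateError(f"output directory {out} is not empty")
    out.mkdir(parents=True, exist_ok=True)

    prefixes = _context(config)
    metas: list[FileMeta] = []
    copied_html: list[str] = []

    for src in data_files:
        src = Path(src)
        rel = f"{config.data_dir_label}/{src.name}"
        _copy_into(src, out / rel)
        metas.append(file_metadata(out / rel, config, rel_path=rel))
    for src in html_copies:
        src = Path(src)
        rel = src.name
        _copy_into(src, out / rel)
        metas.append(file_metadata(out / rel, config, rel_path=rel))
        copied_html.append(rel)

    entities = graph_to_entities(graph, prefixes)
    by_id = {e["@id"]: e for e in entities}

    has_part = []
    for meta in metas:
        eid = _file_entity_id(graph, meta.path, prefixes)
        entity = by_id.get(eid)
        if entity is None:
            entity = {"@id": eid, "@type": ["schema:MediaObject"], "schema:name": meta.path}
            entities.append(entity)
            by_id[eid] = entity
        types = entity.setdefault("@type", [])
        if "schema:MediaObject" not in types:
            types.append("schema:MediaObject")
        entity["schema:encodingFormat"] = meta.mime_type
        entity["schema:contentSize"] = str(meta.size_bytes)
        entity["ep:checksum"] = meta.checksum
        entity["ep:checksumAlgorithm"] = meta.algorithm
        has_part.append({"@id": eid})

    root_entity = {
        "@id": "./",
        "@type": "schema:Dataset",
        "schema:name": crate_name or out.name,
        "schema:hasPart": sorted(has_part, key=lambda d: d["@id"]),
    }
    descriptor_entity = {
        "@id": METADATA_FILENAME,
        "@type": "schema:CreativeWork",
        "schema:about": {"@id": "./"},
        "dcterms:conformsTo": {"@id": ROCRATE_SPEC},
    }
    for e in entities:
        if isinstance(e.get("@type"), list):
            e["@type"] = sorted(e["@type"])

    descriptor = {
        "@context": _context(config),
        "@graph": [descriptor_entity, root_entity] + sorted(entities, key=lambda n: n["@id"]),
    }
    (out / METADATA_FILENAME).write_text(
        json.dumps(descriptor, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
    if preview:
        _write_preview(out, descriptor, metas)
    return CrateBundle(
        root_dir=out, metadata_descriptor=descriptor, files=metas, html_copies=copied_html
    )


def _write_preview(out: Path, descriptor: dict, metas: list[FileMeta]) -> None:
    """Minimal human-readable table of contents generated from the descriptor."""
    name = ""
    for e in descriptor["@graph"]:
        if e.get("@id") == "./":
            name = e.get("schema:name", "")
    rows = "\n".join(
        f"<tr><td>{m.path}</td><td>{m.mime_type}</td><td>{m.size_bytes}</td></tr>"
        for m in sorted(metas, key=lambda m: m.path)
    )
    html = (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{name}</title></head><body>"
        f"<h1>{name}</h1>"
        "<table><tr><th>File</th><th>Media type</th><th>Size (bytes)</th></tr>"
        f"{rows}</table></body></html>\n"
    )
    (out / PREVIEW_FILENAME).write_text(html, encoding="utf-8")


# --------------------------------------------------------------------------
# validation and loading
# --------------------------------------------------------------------------

def _entity_rel_path(entity: dict) -> str | None:
    name = entity.get("schema:name")
    eid = entity.get("@id", "")
    if isinstance(name, str) and ("/" in name or "." in name) and not name.startswith("http"):
        return name
    if eid and not eid.startswith(("http://", "https://", "_:")) and eid not in ("./",):
        return eid
    return None


def validate_crate(path: str | Path, config: PipelineConfig = DEFAULT_CONFIG) -> list[str]:
    """Self-consistency check; returns a list of violations (empty = valid)."""
    root = Path(path)
    violations: list[str] = []
    desc_path = root / METADATA_FILENAME
    if not desc_path.is_file():
        return [f"missing {METADATA_FILENAME}"]
    try:
        descriptor = json.loads(desc_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        return [f"descriptor does not parse: {exc}"]
    graph_entities = descriptor.get("@graph")
    if not isinstance(graph_entities, list):
        return ["descriptor has no @graph"]
    by_id = {e.get("@id"): e for e in graph_entities if isinstance(e, dict)}

    root_entity = by_id.get("./")
    if root_entity is None:
        violations.append("no root data entity './'")
        return violations
    types = root_entity.get("@type", [])
    if "schema:Dataset" not in ([types] if isinstance(types, str) else types):
        violations.append("root data entity is not typed schema:Dataset")

    parts = root_entity.get("schema:hasPart", [])
    if isinstance(parts, dict):
        parts = [parts]
    part_ids = {p.get("@id") for p in parts if isinstance(p, dict)}

    # every file entity in hasPart must exist on disk and match its metadata
    referenced_paths: set[str] = set()
    for pid in sorted(p for p in part_ids if p):
        entity = by_id.get(pid)
        if entity is None:
            violations.append(f"hasPart references unknown entity {pid}")
            continue
        rel = _entity_rel_path(entity)
        if rel is None:
            violations.append(f"file entity {pid} has no resolvable path")
            continue
        referenced_paths.add(rel)
        fpath = root / rel
        if not fpath.is_file():
            violations.append(f"missing file: {rel}")
            continue
        size = entity.get("schema:contentSize")
        if size is not None and int(size) != fpath.stat().st_size:
            violations.append(f"size mismatch for {rel}")
        checksum = entity.get("ep:checksum")
        algo = entity.get("ep:checksumAlgorithm", config.checksum_algorithm)
        if checksum is not None:
            actual = hashlib.new(algo, fpath.read_bytes()).hexdigest()
            if actual != checksum:
                violations.append(f"checksum mismatch for {rel}")

    # every data file on disk must be covered by hasPart
    for fpath in sorted(root.rglob("*")):
        if not fpath.is_file():
            continue
        rel = fpath.relative_to(root).as_posix()
        if rel in (METADATA_FILENAME, PREVIEW_FILENAME):
            continue
        if rel not in referenced_paths:
            violations.append(f"file on disk not covered by hasPart: {rel}")
    return violations


def load_crate_graph(path: str | Path, config: PipelineConfig = DEFAULT_CONFIG) -> Graph:
    """Parse a crate's descriptor back into an RDF graph.

    Crate-relative identifiers are resolved against a per-crate base IRI so
    that HTML-copy entities from different crates never collide.
    """
    root = Path(path)
    base = f"{config.base_iri}crates/{root.name}/"
    g = Graph()
    g.parse(root / METADATA_FILENAME, format="json-ld", publicID=base)
    return g
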