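"""Load crate descriptors into a triple store and answer the W7 questions.

The seven provenance questions (Who, Which, How, When, Why, Where, and the
use-case specific "what was the order of the stimulation parameters") ship as
SPARQL text files under ``elnprov/queries`` — queries are data, not code.
Execution is in-memory on an rdflib dataset with one named graph per crate,
so loading is idempotent and each triple's source crate is retained; the same
query text can be posted verbatim to any external SPARQL 1.1 endpoint that
has the crate descriptors loaded.

Binding slots (passed as ``bindings={...}``):

==========  =======================================================
question    slots
==========  =======================================================
how         ``file`` — (suffix of) the crate-relative file name
which       ``section`` — IRI of a section activity (optional)
when        ``section`` — IRI of a section activity (optional)
others      none
==========  =======================================================
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdflib import Dataset, Graph, Literal, URIRef
from rdflib.namespace import PROV, RDF

from .config import DEFAULT_CONFIG, PipelineConfig
from .crate import load_crate_graph, validate_crate
from .kg import SCHEMA, _prefix_map

logger = logging.getLogger(__name__)

W7_QUESTIONS = ("who", "which", "how", "when", "why", "where", "what_order")


class QueryError(ValueError):
    pass


@dataclass
class ResultTable:
    columns: list[str]
    rows: list[tuple] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(self.columns)
        writer.writerows(self.rows)
        return buf.getvalue()

    def pretty(self) -> str:
        if not self.columns:
            return "(empty)"
        cells = [self.columns] + [[str(c) for c in row] for row in self.rows]
        widths = [max(len(r[i]) for r in cells) for i in range(len(self.columns))]
        lines = [
            "  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip() for row in cells
        ]
        lines.insert(1, "  ".join("-" * w for w in widths))
        return "\n".join(lines)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.pretty()


class QueryStore:
    """Union view over the descriptors of one or more loaded crates."""

    def __init__(self, config: PipelineConfig = DEFAULT_CONFIG):
        self.config = config
        self.dataset = Dataset(default_union=True)
        self._loaded: dict[str, URIRef] = {}

    @property
    def graph(self) -> Dataset:
        return self.dataset

    def __len__(self) -> int:
        return sum(1 for _ in self.dataset.quads((None, None, None, None)))

    def crate_of_triple(self, triple) -> list[str]:
        """Source crates of a triple (triple-level provenance)."""
        s, p, o = triple
        return [str(ctx) for _, _, _, ctx in self.dataset.quads((s, p, o, None))]

    def load_crate(self, path: str | Path) -> None:
        """Load one crate; re-loading the same path is a no-op."""
        key = str(Path(path).resolve())
        violations = validate_crate(path, self.config)
        if violations:
            raise QueryError(f"invalid crate {path}: {violations[0]}")
        graph_id = URIRef(f"{self.config.base_iri}crates/{Path(path).name}")
        if key in self._loaded:
            logger.debug("crate %s already loaded; skipped", path)
            return
        named = self.dataset.graph(graph_id)
        incoming = load_crate_graph(path, self.config)
        for triple in incoming:
            named.add(triple)
        self._loaded[key] = graph_id


def load_crates(
    paths: list[str | Path], config: PipelineConfig = DEFAULT_CONFIG
) -> QueryStore:
    store = QueryStore(config)
    for p in paths:
        store.load_crate(p)
    return store


def _query_text(question: str) -> str:
    ref = resources.files("elnprov.queries").joinpath(f"{question}.rq")
    return ref.read_text(encoding="utf-8")


_BINDING_SLOTS = {
    "how": {"file": "fileName"},
    "which": {"section": "section"},
    "when": {"section": "section"},
}
_REQUIRED = {"how": ("file",)}


def _fmt_number(lit) -> str:
    return f"{float(lit):g}"


def run_w7(
    store: QueryStore,
    question: str,
    bindings: dict[str, str] | None = None,
    config: PipelineConfig | None = None,
) -> ResultTable:
    """Answer one W7 question over the loaded crates.

    Returns the question's result table; an unknown question id raises, a
    missing required binding yields an empty table with a warning.
    """
    if question not in W7_QUESTIONS:
        raise QueryError(f"unknown question id {question!r}; expected one of {W7_QUESTIONS}")
    cfg = config or store.config
    bindings = bindings or {}
    init = {}
    for slot, var in _BINDING_SLOTS.get(question, {}).items():
        if slot in bindings:
            value = bindings[slot]
            term = URIRef(value) if value.startswith(("http://", "https://")) else Literal(value)
            init[var] = term
    for slot in _REQUIRED.get(question, ()):
        if slot not in bindings:
            logger.warning("question %r requires binding %r; returning empty table", question, slot)
            return ResultTable(columns=[], rows=[])

    init_ns = {k: URIRef(v) for k, v in _prefix_map(cfg).items()}
    result = store.dataset.query(
        _query_text(question), initBindings=init, initNs=init_ns
    )
    solutions = list(result)
    if question == "what_order":
        return _fold_what_order(solutions)
    columns = [str(v) for v in result.vars]
    rows = [tuple("" if c is None else str(c) for c in row) for row in solutions]
    return ResultTable(columns=columns, rows=rows)


def _fold_what_order(solutions) -> ResultTable:
    """One row per experiment with its ordered stimulation parameter pairs."""
    per_protocol: dict[str, dict] = {}
    for row in solutions:
        d = row.asdict()
        protocol = str(d["protocol"])
        entry = per_protocol.setdefault(
            protocol, {"title": str(d.get("title", "")), "pairs": []}
        )
        pair = f"{_fmt_number(d['freq'])}Hz, {_fmt_number(d['volt'])}V"
        entry["pairs"].append(pair)
    rows = [
        (protocol, entry["title"], " | ".join(entry["pairs"]))
        for protocol, entry in sorted(per_protocol.items())
    ]
    return ResultTable(columns=["protocol", "title", "stimulationParameters"], rows=rows)


def pseudonymise(
    store: QueryStore | Graph, keep: tuple[str, ...] = ()
) -> dict[str, str]:
    """Replace person names with ``PersonN Anonymous`` via a graph update.

    Names in *keep* are preserved.  Returns the original->pseudonym map.
    The replacement is stable: persons are numbered in sorted name order.
    """
    g = store.dataset if isinstance(store, QueryStore) else store
    names: set[str] = set()
    for person in g.subjects(RDF.type, PROV.Person):
        for name in g.objects(person, SCHEMA.name):
            if str(name) not in keep:
                names.add(str(name))
    mapping = {
        name: f"Person{i} Anonymous" for i, name in enumerate(sorted(names), start=1)
    }
    if isinstance(g, Dataset):
        contexts = list(g.graphs())
    else:
        contexts = [g]
    for ctx in contexts:
        for person in list(ctx.subjects(RDF.type, PROV.Person)):
            for name in list(ctx.objects(person, SCHEMA.name)):
                if str(name) in mapping:
                    ctx.remove((person, SCHEMA.name, name))
                    ctx.add((person, SCHEMA.name, Literal(mapping[str(name)])))
    return mapping
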