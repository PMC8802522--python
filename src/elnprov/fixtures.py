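"""Synthetic use-case suite: Ca-imaging ELN protocols as HTML exports.

The generated corpus emulates the documentation of a calcium-imaging study of
intracellular Ca2+ dynamics under electrical stimulation: seven protocols,
each a permutation of the same stimulation settings (frequency in Hz, voltage
in V), composed from four sub-template parts — Preparation, Fluo-3 Staining,
one Ca-imaging-with-Stimulation section per setting (15 atomic steps each),
and Ca-imaging without Stimulation.  A shared inventory of 22 items (cell
line, media, buffers, devices, software, labware) is linked from the steps;
each stimulation approach uploads five dummy research-data files (stub CZI
microscopy containers, tiny JPEGs, small XML measurement tables) named after
its parameters, e.g. ``02_Zeitserie-Stimulation_5V_7.9Hz.czi``.

Everything is deterministic: a fixed seed yields byte-identical output.  The
data files carry no meaningful imaging content — only their names, sizes and
checksums matter downstream.
"""

from __future__ import annotations

import hashlib
import html as html_escape
import io
import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

from PIL import Image

ESC = html_escape.escape


@dataclass(frozen=True)
class InventoryEntry:
    item_id: str
    category: str
    name: str
    manufacturer: str = ""
    class_ref: str = ""  # CURIE of an external ontology class, if any
    description: str = ""


#: The shared inventory: 22 items, as referred to by every protocol.
INVENTORY_ITEMS: tuple[InventoryEntry, ...] = (
    InventoryEntry("1", "Cell line", "MG-63", "ATCC", "obo:CLO_0007699",
                   "Human osteosarcoma cell line used for Ca-imaging."),
    InventoryEntry("2", "Culture Medium", "DMEM", "Gibco"),
    InventoryEntry("3", "Serum", "FCS", "PAN-Biotech"),
    InventoryEntry("4", "Antibiotic", "Gentamicin", "Ratiopharm", "obo:CHEBI_17833"),
    InventoryEntry("5", "Washing solution", "PBS without Ca/Mg", "PAN-Biotech"),
    InventoryEntry("6", "Buffer", "HEPES I (isotonic)", ""),
    InventoryEntry("7", "Buffer", "HEPES II (hypotonic)", ""),
    InventoryEntry("8", "Staining solution", "Fluo-3/AM", "Thermo Fisher"),
    InventoryEntry("9", "Detergent", "Pluronic F-127", "Thermo Fisher"),
    InventoryEntry("10", "Solvent", "DMSO", "Sigma-Aldrich", "obo:CHEBI_28262"),
    InventoryEntry("11", "Chemical", "ATP", "Sigma-Aldrich", "obo:CHEBI_15422"),
    InventoryEntry("12", "Detachment solution", "Trypsin-EDTA", "PAN-Biotech"),
    InventoryEntry("13", "Device", "SANYO CO2 Incubator", "SANYO"),
    InventoryEntry("14", "Device", "Eppendorf Centrifuge", "Eppendorf"),
    InventoryEntry("15", "Device", "Eppendorf Thermomixer C (incubation shaker)", "Eppendorf"),
    InventoryEntry("16", "Device", "LSM780", "ZEISS"),
    InventoryEntry("17", "Device", "IonOptix 12 well plate chamber", "IonOptix"),
    InventoryEntry("18", "Device", "IonOptix C-Pace EM", "IonOptix"),
    InventoryEntry("19", "Device", "Neubauer counting chamber", "Marienfeld"),
    InventoryEntry("20", "Software", "ZEN 2011 (black edition)", "ZEISS"),
    InventoryEntry("21", "Labware", "12 well plate", "Greiner"),
    InventoryEntry("22", "Labware", "Tube: 10ml", "Greiner"),
)

EXPERIMENTALIST = "Susanne Staehlke"
INVOLVED_PERSONS = "Person1 Anonymous, Person2 Anonymous"
OBJECTIVE = "Intracellular calcium dynamic caused by electric fields"
ORGANIZATION = "University Medical Center Rostock"
TEMPLATE_NAME = "Ca-imaging"

#: (protocol_id, title suffix, date label, stimulation order).  The orders are
#: the seven published permutations; one protocol has five entries because a
#: setting was repeated after an issue during the experiment.
PROTOCOL_TABLE: tuple[tuple[str, str, str, tuple[tuple[float, float], ...]], ...] = (
    ("eln1124", "29.01.2021", "29.01.2021",
     ((7.9, 1), (7.9, 5), (20, 5), (20, 1))),
    ("eln1042", "", "15.01.2021",
     ((20, 1), (7.9, 1), (7.9, 5), (20, 5))),
    ("eln1021", "", "08.01.2021",
     ((20, 1), (20, 5), (7.9, 5), (7.9, 1))),
    ("eln1022", "", "08.01.2021",
     ((7.9, 5), (7.9, 1), (20, 1), (20, 5), (7.9, 5))),
    ("eln1023", "Failed (durch ATP Zugabe hat sich der Bildausschnitt verändert)",
     "11.01.2021",
     ((7.9, 1), (7.9, 5), (20, 5), (20, 1))),
    ("eln942", "", "18.12.2020",
     ((7.9, 5), (7.9, 1), (20, 1), (20, 5))),
    ("eln1071", "22.01.2021", "22.01.2021",
     ((7.9, 5), (20, 5), (20, 1), (7.9, 1))),
)


@dataclass(frozen=True)
class FixtureSpec:
    protocol_id: str
    title: str
    date_label: str
    stimulation_settings: tuple[tuple[float, float], ...]
    steps_per_approach: int = 15
    inventory_size: int = 22
    seed: int = 1

    def __post_init__(self) -> None:
        for f, v in self.stimulation_settings:
            if f <= 0 or v <= 0:
                raise ValueError("frequencies and voltages must be positive")


def default_specs(seed: int = 1) -> list[FixtureSpec]:
    specs = []
    for pid, suffix, date, settings in PROTOCOL_TABLE:
        title = "Ca-imaging (with stimulation)"
        if suffix:
            title += f" {suffix}"
        specs.append(
            FixtureSpec(
                protocol_id=pid, title=title, date_label=date,
                stimulation_settings=settings, seed=seed,
            )
        )
    return specs


# --------------------------------------------------------------------------
# HTML building blocks
# --------------------------------------------------------------------------

def _num(x: float) -> str:
    return f"{x:g}"


def _item_link(item: InventoryEntry) -> str:
    return (
        f'<a href="database.php?mode=view&amp;id={item.item_id}">'
        f"[{ESC(item.category)}] {ESC(item.name)}</a>"
    )


def _file_link(filename: str) -> str:
    return f'<a href="uploads/{ESC(filename)}">{ESC(filename)}</a>'


_BY_ID = {it.item_id: it for it in INVENTORY_ITEMS}


def _L(item_id: str) -> str:
    return _item_link(_BY_ID[item_id])


@dataclass(frozen=True)
class _Step:
    text: str                       # may contain markup and {placeholders}
    offset_min: int | None = None   # None -> "immediately afterwards"
    empty_time: bool = False


# The Preparation sub-template (times relative to 08:00).
_PREPARATION: tuple[_Step, ...] = (
    _Step(f"take {_L('1')} P25 LOT 57840088 out of {_L('13')}", 0),
    _Step(
        "prepare culture medium: 89% "
        f"{_L('2')} + 10% {_L('3')} + 1% {_L('4')}"
        " (Attributed to Susanne Staehlke)"
    ),
    _Step(f"wash cells with {_L('5')}", 10),
    _Step(f"detach cells with {_L('12')}"),
    _Step(f"count cells using {_L('19')}", 20),
    _Step(f"seed cells into {_L('21')}"),
    _Step(f"incubate 30min in {_L('13')} at 37°C", 25),
    _Step(f"prepare {_L('18')} stimulation device", 55),
)

# The Fluo-3 Staining sub-template (times relative to 09:00).
_STAINING: tuple[_Step, ...] = (
    _Step(f"prepare staining solution: {_L('8')} in {_L('10')} with {_L('9')}", 0),
    _Step(f"transfer cell suspension into {_L('22')}"),
    _Step(f"centrifuge 5min in {_L('14')}", 5),
    _Step(f"wash cells with {_L('5')}"),
    _Step("add 1.5ml staining solution to the cells", 10),
    _Step(f"incubate 30min in {_L('15')} at 37°C"),
    _Step(f"prepare measurement buffer: 50% {_L('6')} + 50% {_L('7')}", 35),
)

# The Ca-imaging-with-Stimulation sub-template.  The time pattern alternates
# timestamps, "immediately afterwards" and one missing value; the final step
# carries the stimulation parameters and the generated research data.
_APPROACH_FILLER: tuple[_Step, ...] = (
    _Step(f"prepare {_L('22')}", 0),
    _Step(f"wash cells with {_L('5')}"),
    _Step(f"centrifuge 3min in {_L('14')}", 1),
    _Step("aspirate supernatant", 6),
    _Step(f"resuspend pellet in 50% {_L('6')} + 50% {_L('7')}"),
    _Step(f"add {_L('8')} working solution"),
    _Step(f"incubate 20min in {_L('15')}", 10),
    _Step(
        f"prepare {_L('16')} with {_L('17')} and {_L('18')}:"
        "<ul><li>set laser to 488 nm</li><li>select 40x objective</li></ul>"
    ),
    _Step(f"centrifuge 3min in {_L('14')}", 40),
    _Step("aspirate supernatant", 45),
    _Step(f"resuspend pellet in {_L('6')}", empty_time=True),
    _Step(
        f"transfer cells into {_L('21')} and wash with {_L('5')}; "
        "overview image {jpg_overview}"
    ),
    _Step(f"add {_L('6')}; single frame " + "{czi_frame}"),
    _Step(f"place {_L('17')} electrodes on plate"),
)

_APPROACH_FINAL = _Step(
    "incubate for 10min with stimulation in LSM hood: record with "
    f"{_L('16')} and {_L('20')}"
    " at {f}Hz and {v}V; time series {czi_series}, raw measurements"
    " {xml_series}, excerpt {jpg_excerpt}",
    50,
)

# The Ca-imaging-without-Stimulation sub-template (times relative to 15:00).
_WITHOUT_STIMULATION: tuple[_Step, ...] = (
    _Step(f"transfer sample to {_L('16')}", 0),
    _Step(f"record baseline with {_L('20')}"),
    _Step(f"add {_L('11')} as positive control", 5),
    _Step("incubate 5min at 37°C"),
    _Step(f"wash cells with {_L('5')}", 15),
)

IMMEDIATELY = "immediately afterwards"


def _time(base: datetime, offset_min: int) -> str:
    return (base + timedelta(minutes=offset_min)).strftime("%H:%M:%S")


def _rows_html(steps: list[tuple[str, str]]) -> str:
    body = "".join(
        f"<tr><td>{text}</td><td>{ESC(time)}</td></tr>" for text, time in steps
    )
    return (
        "<table><tr><th>Step</th><th>Starting time</th></tr>" + body + "</table>"
    )


def approach_filenames(approach_index: int, freq: float, volt: float) -> dict[str, str]:
    """The five research-data files of one stimulation approach.

    Files are numbered consecutively across the protocol (five per approach),
    so approach 1's time series is ``02_Zeitserie-Stimulation_<v>V_<f>Hz.czi``.
    """
    n0 = 5 * (approach_index - 1)
    tag = f"{_num(volt)}V_{_num(freq)}Hz"
    return {
        "jpg_overview": f"{n0 + 1:02d}_Uebersicht_{tag}.jpg",
        "czi_series": f"{n0 + 2:02d}_Zeitserie-Stimulation_{tag}.czi",
        "xml_series": f"{n0 + 3:02d}_Zeitserie-Stimulation_{tag}.xml",
        "czi_frame": f"{n0 + 4:02d}_Einzelbild_{tag}.czi",
        "jpg_excerpt": f"{n0 + 5:02d}_Ausschnitt_{tag}.jpg",
    }


def _approach_steps(spec: FixtureSpec, k: int, freq: float, volt: float,
                    base: datetime) -> tuple[list[tuple[str, str]], dict[str, str]]:
    files = approach_filenames(k, freq, volt)
    links = {key: _file_link(name) for key, name in files.items()}
    n = spec.steps_per_approach
    chosen: list[_Step] = [
        _APPROACH_FILLER[i % len(_APPROACH_FILLER)] for i in range(n - 1)
    ]
    chosen.append(_APPROACH_FINAL)
    rows: list[tuple[str, str]] = []
    for step in chosen:
        text = step.text.format(f=_num(freq), v=_num(volt), **links)
        if step.empty_time:
            time = ""
        elif step.offset_min is None:
            time = IMMEDIATELY
        else:
            time = _time(base, step.offset_min)
        rows.append((text, time))
    return rows, files


def _static_rows(steps: tuple[_Step, ...], base: datetime) -> list[tuple[str, str]]:
    rows = []
    for step in steps:
        if step.empty_time:
            time = ""
        elif step.offset_min is None:
            time = IMMEDIATELY
        else:
            time = _time(base, step.offset_min)
        rows.append((step.text, time))
    return rows


def protocol_html(spec: FixtureSpec) -> tuple[str, list[str]]:
    """Render one protocol page; returns (html, list of data file names)."""
    head_rows = "".join(
        f"<tr><td>{ESC(k)}</td><td>{ESC(v)}</td></tr>"
        for k, v in (
            ("Experimentalist", EXPERIMENTALIST),
            ("Involved persons", INVOLVED_PERSONS),
            ("Objective", OBJECTIVE),
            ("Organization", ORGANIZATION),
            ("Template", TEMPLATE_NAME),
            ("Date", spec.date_label),
        )
    )
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset=\"utf-8\">",
        f"<title>{ESC(spec.title)}</title></head><body>",
        f"<table>{head_rows}</table>",
        "<h2>Preparation</h2>",
        _rows_html(_static_rows(_PREPARATION, datetime(2021, 1, 29, 8, 0))),
        "<h2>Fluo-3 Staining</h2>",
        _rows_html(_static_rows(_STAINING, datetime(2021, 1, 29, 9, 0))),
    ]
    all_files: list[str] = []
    for k, (freq, volt) in enumerate(spec.stimulation_settings, start=1):
        base = datetime(2021, 1, 29, 9, 40) + timedelta(minutes=65 * (k - 1))
        rows, files = _approach_steps(spec, k, freq, volt, base)
        parts.append(
            f"<h2>Ca-imaging with Stimulation ({_num(freq)} Hz, {_num(volt)} V)</h2>"
        )
        parts.append(_rows_html(rows))
        all_files.extend(files.values())
    parts.append("<h2>Ca-imaging without Stimulation</h2>")
    parts.append(_rows_html(_static_rows(_WITHOUT_STIMULATION, datetime(2021, 1, 29, 15, 0))))
    parts.append("</body></html>")
    return "\n".join(parts), all_files


def inventory_item_html(item: InventoryEntry) -> str:
    rows = [("Category", item.category), ("Name", item.name)]
    if item.manufacturer:
        rows.append(("Manufacturer", item.manufacturer))
    table = "".join(
        f"<tr><td>{ESC(k)}</td><td>{ESC(v)}</td></tr>" for k, v in rows
    )
    desc = ESC(item.description) if item.description else ""
    if item.class_ref:
        desc += f" Ontology class: {item.class_ref}"
    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        f"<title>{ESC(item.name)}</title></head><body>"
        f"<h1>{ESC(item.name)}</h1>"
        f"<table>{table}</table>"
        f"<p>{desc.strip()}</p>"
        "</body></html>\n"
    )


# --------------------------------------------------------------------------
# dummy attachment payloads
# --------------------------------------------------------------------------

def _file_rng(seed: int, protocol_id: str, filename: str) -> random.Random:
    digest = hashlib.sha256(f"{seed}:{protocol_id}:{filename}".encode()).digest()
    return random.Random(int.from_bytes(digest[:8], "big"))


def _czi_stub(rng: random.Random) -> bytes:
    # opaque binary stub; only name, size and checksum matter downstream
    return b"ZISRAWFILE" + rng.randbytes(2048 + rng.randrange(1024))


def _jpeg_stub(rng: random.Random) -> bytes:
    img = Image.new("RGB", (8, 8))
    img.putdata([
        (rng.randrange(256), rng.randrange(256), rng.randrange(256))
        for _ in range(64)
    ])
    buf = io.BytesIO()
    img.save(buf, format="JPEG", quality=90)
    return buf.getvalue()


def _xml_stub(rng: random.Random, filename: str) -> bytes:
    points = "\n".join(
        f'  <point t="{t}" value="{rng.uniform(0.0, 1.0):.4f}"/>' for t in range(10)
    )
    return (
        f'<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<luminescence source="{filename}">\n{points}\n</luminescence>\n'
    ).encode()


def _attachment_bytes(seed: int, protocol_id: str, filename: str) -> bytes:
    rng = _file_rng(seed, protocol_id, filename)
    if filename.endswith(".czi"):
        return _czi_stub(rng)
    if filename.endswith(".jpg"):
        return _jpeg_stub(rng)
    if filename.endswith(".xml"):
        return _xml_stub(rng, filename)
    return rng.randbytes(256)


# --------------------------------------------------------------------------
# suite generation
# --------------------------------------------------------------------------

def generate_inventory(out_dir: str | Path) -> list[Path]:
    """Write the 22 shared inventory-item pages under ``<out>/inventory``."""
    inv_dir = Path(out_dir) / "inventory"
    inv_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for item in INVENTORY_ITEMS:
        path = inv_dir / f"item_{int(item.item_id):02d}.html"
        path.write_text(inventory_item_html(item), encoding="utf-8")
        paths.append(path)
    return paths


def generate_protocol(
    spec: FixtureSpec,
    inventory: tuple[InventoryEntry, ...] = INVENTORY_ITEMS,
    out_dir: str | Path = ".",
) -> Path:
    """Write one protocol page plus its dummy attachments; returns the page path."""
    pdir = Path(out_dir) / spec.protocol_id
    uploads = pdir / "uploads"
    uploads.mkdir(parents=True, exist_ok=True)
    page, files = protocol_html(spec)
    path = pdir / "protocol.html"
    path.write_text(page, encoding="utf-8")
    for filename in files:
        (uploads / filename).write_bytes(
            _attachment_bytes(spec.seed, spec.protocol_id, filename)
        )
    return path


def generate_suite(out_dir: str | Path, seed: int = 1) -> list[FixtureSpec]:
    """Generate the full seven-protocol suite plus the shared inventory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    generate_inventory(out)
    specs = default_specs(seed)
    for spec in specs:
        generate_protocol(spec, INVENTORY_ITEMS, out)
    return specs


def default_external_id_maps() -> dict[str, dict[str, str]]:
    """owl:sameAs maps for the fixture suite.

    The organization uses its published ROR id; the experimentalist gets the
    ORCID documentation example identifier (synthetic stand-in, not the
    researcher's real iD).
    """
    return {
        "person_orcid": {EXPERIMENTALIST: "https://orcid.org/0000-0002-1825-0097"},
        "organization_ror": {ORGANIZATION: "https://ror.org/04dm1cm79"},
        "item_sameas": {},
    }
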