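"""Shared fixtures: one generated suite, parsed documents, graphs and crates.

Everything is generated programmatically at test time with a fixed seed; no
test data is stored in the repository.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from elnprov import (
    assemble_crate,
    build_graph,
    generate_suite,
    link_external_ids,
    load_crates,
    parse_inventory_item,
    parse_protocol,
)
from elnprov.config import DEFAULT_CONFIG, PipelineConfig
from elnprov.fixtures import PROTOCOL_TABLE, default_external_id_maps

PROTOCOL_IDS = [row[0] for row in PROTOCOL_TABLE]


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    maps = default_external_id_maps()
    return PipelineConfig(
        person_orcid=maps["person_orcid"],
        organization_ror=maps["organization_ror"],
    )


@pytest.fixture(scope="session")
def suite_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("suite")
    generate_suite(out, seed=1)
    return out


def load_inventory(suite_dir: Path, config: PipelineConfig):
    items = []
    for path in sorted((suite_dir / "inventory").glob("*.html")):
        item_id = path.stem.split("_")[-1].lstrip("0")
        items.append(parse_inventory_item(path.read_text(encoding="utf-8"), item_id, config))
    return items


@pytest.fixture(scope="session")
def inventory(suite_dir, config):
    return load_inventory(suite_dir, config)


@pytest.fixture(scope="session")
def protocols(suite_dir, config):
    out = {}
    for pid in PROTOCOL_IDS:
        html = (suite_dir / pid / "protocol.html").read_text(encoding="utf-8")
        out[pid] = parse_protocol(html, pid, config)
    return out


@pytest.fixture(scope="session")
def graphs(protocols, inventory, config):
    out = {}
    for pid, protocol in protocols.items():
        g = build_graph(protocol, inventory, config)
        link_external_ids(g, config)
        out[pid] = g
    return out


@pytest.fixture(scope="session")
def crates_dir(tmp_path_factory, suite_dir, graphs, config) -> Path:
    out = tmp_path_factory.mktemp("crates")
    for pid, g in graphs.items():
        data_files = sorted((suite_dir / pid / "uploads").glob("*"))
        html_copies = [suite_dir / pid / "protocol.html"] + sorted(
            (suite_dir / "inventory").glob("*.html")
        )
        assemble_crate(g, data_files, html_copies, out / pid, config, crate_name=pid)
    return out


@pytest.fixture(scope="session")
def store(crates_dir, config):
    return load_crates([crates_dir / pid for pid in PROTOCOL_IDS], config)
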