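# elnprov — structure-based provenance documentation from ELN protocols

Wet-lab experiments are increasingly documented in electronic laboratory
notebooks (ELNs).  An *ELN protocol* — the record of one actually executed
experiment, with timestamps, lot and passage numbers, device parameters and
the uploaded research-data files — contains almost everything needed to
document the **retrospective provenance** of that data, but locked up in
semi-structured HTML.  `elnprov` turns such protocols into machine-readable
knowledge graphs and ready-to-publish data bundles:

1. **Parse** elabFTW-style protocol and inventory-item HTML exports:
   key-value head tables, heading-structured sections, two-column
   *Step*/*Starting time* activity tables, links to inventory items and
   uploaded files.
2. **Mine** the step texts with regular expressions and lookup tables:
   parameters identified by their unit (`5min`, `37°C`, `7.9Hz`), mixture
   recipes (`89% [Culture Medium] DMEM + 10% [Serum] FCS + 1% [Antibiotic]
   Gentamicin`), resource mentions with passage/lot
   (`[Cell line] MG-63 P25 LOT 57840088`), head verbs, attribution notes.
3. **Translate** everything into an RDF graph using PROV-O, BFO, OBI and
   schema.org: a three-level activity hierarchy (`bfo:hasPart`), document
   order as `prov:wasInformedBy` chains, resources as `prov:used` entities,
   file creation as `prov:wasGeneratedBy`, parameters as OBI value
   specifications (`OBI_0001938`/`OBI_0001937`/`IAO_0000039`), mixtures as
   `OBI_0000685` activities with shared recipe objectives, and ORCID/ROR/
   ontology links via `owl:sameAs`.
4. **Bundle** the graph, the research data and human-readable HTML copies as
   an RO-Crate (`ro-crate-metadata.json` + `Data/`), with media type, byte
   size and checksum for every file.
5. **Query** one or many crates with SPARQL to answer the seven W7
   provenance questions: *Who, Which, How, When, Why, Where*, and *What was
   the order of the stimulation parameters?*

A built-in fixture generator emulates the intended use case — seven
calcium-imaging protocols that permute the same electrical-stimulation
settings (frequency × voltage), a shared 22-item inventory, and dummy CZI /
JPEG / XML attachments — so the whole pipeline is testable offline.

## Worked example

```sh
elnprov fixtures --seed 1 --out suite
elnprov bundle --protocol-dir suite/eln942 --inventory suite/inventory --out crates/eln942
elnprov validate crates/eln942
elnprov query how --file 02_Zeitserie-Stimulation_5V_7.9Hz.czi crates/eln942
```

prints the generating activity and protocol of the named microscopy file:

```
file                                                                               activity                                                          protocol
---------------------------------------------------------------------------------  ----------------------------------------------------------------  -----------------------------------------------
https://w3id.org/eln-provenance/eln942/Data/02_Zeitserie-Stimulation_5V_7.9Hz.czi  https://w3id.org/eln-provenance/eln942/ap_1_with_stimulation/15  https://w3id.org/eln-provenance/eln942/protocol
```

i.e. the file was generated by atomic step 15 ("incubate for 10min with
stimulation … at 7.9Hz and 5V") of the first stimulation approach of protocol
eln942.  Comparing experiments works the same way; after bundling all seven
protocols:

```sh
elnprov query what_order crates/*
```

```
protocol                                          title                                     stimulationParameters
------------------------------------------------  ----------------------------------------  -------------------------------------------
https://w3id.org/eln-provenance/eln1124/protocol  Ca-imaging (with stimulation) 29.01.2021  7.9Hz, 1V | 7.9Hz, 5V | 20Hz, 5V | 20Hz, 1V
...                                               ...                                       ...
```

one row per experiment with its stimulation settings in execution order —
the information needed to judge whether the ordering of the approaches
influenced the measured Ca²⁺ dynamics.

The same functionality is available as a library:

```python
from elnprov import parse_protocol, build_graph, assemble_crate, load_crates, run_w7
```

## Configuration

All mapping decisions (verb → ontology class, unit → unit-ontology class,
inventory-link URL patterns, IRI base, ORCID/ROR/ontology `sameAs` maps,
media types) live in `elnprov.config.PipelineConfig` and can be overridden
from a YAML file passed via `--config`; see `docs/methods.md` for the model
and the defaults.

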