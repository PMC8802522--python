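# What was the order of the stimulation parameters in a particular experiment?
# One row per stimulation approach with its frequency (Hz) and voltage (V);
# nPrev orders the approaches within each protocol.  The service folds the
# rows into one row per experiment.
PREFIX prov: <http://www.w3.org/ns/prov#>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX schema: <http://schema.org/>
PREFIX ep: <https://w3id.org/eln-provenance/vocab#>
PREFIX owl: <http://www.w3.org/2002/07/owl#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>

SELECT ?protocol ?title ?section ?freq ?volt (COUNT(DISTINCT ?prev) AS ?nPrev)
WHERE {
  ?protocol ep:usedTemplate ?template ;
            rdfs:label ?title ;
            obo:BFO_0000051 ?section .
  ?section obo:OBI_0001938 ?vsF .
  ?vsF obo:IAO_0000039 obo:UO_0000106 ; obo:OBI_0001937 ?freq .
  ?section obo:OBI_0001938 ?vsV .
  ?vsV obo:IAO_0000039 obo:UO_0000218 ; obo:OBI_0001937 ?volt .
  OPTIONAL { ?section prov:wasInformedBy+ ?prev }
}
GROUP BY ?protocol ?title ?section ?freq ?volt
ORDER BY ?protocol ?nPrev
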