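# How was a particular file created?
# Required binding: ?fileName (suffix of the crate-relative file name).
PREFIX prov: <http://www.w3.org/ns/prov#>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX schema: <http://schema.org/>
PREFIX ep: <https://w3id.org/eln-provenance/vocab#>
PREFIX owl: <http://www.w3.org/2002/07/owl#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>

SELECT ?file ?activity ?protocol
WHERE {
  ?file prov:wasGeneratedBy ?activity ;
        schema:name ?name .
  ?section obo:BFO_0000051 ?activity .
  ?protocol obo:BFO_0000051 ?section .
  FILTER NOT EXISTS { ?parent obo:BFO_0000051 ?protocol }
  FILTER(STRENDS(?name, ?fileName))
}
ORDER BY ?file ?activity
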