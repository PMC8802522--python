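# Why was the experiment done?
# The objective of each protocol, together with its template.
PREFIX prov: <http://www.w3.org/ns/prov#>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX schema: <http://schema.org/>
PREFIX ep: <https://w3id.org/eln-provenance/vocab#>
PREFIX owl: <http://www.w3.org/2002/07/owl#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>

SELECT ?template ?protocol ?objective
WHERE {
  ?protocol ep:usedTemplate ?t .
  ?t rdfs:label ?template .
  ?protocol ep:objective ?objective .
}
ORDER BY ?protocol
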