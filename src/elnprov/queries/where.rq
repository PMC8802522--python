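# Where was the experiment conducted?
# Organizations the participating researchers acted on behalf of.
PREFIX prov: <http://www.w3.org/ns/prov#>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX schema: <http://schema.org/>
PREFIX ep: <https://w3id.org/eln-provenance/vocab#>
PREFIX owl: <http://www.w3.org/2002/07/owl#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>

SELECT DISTINCT ?organization
WHERE {
  ?person a prov:Person ;
          prov:actedOnBehalfOf ?org .
  ?org schema:name ?organization .
}
ORDER BY ?organization
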