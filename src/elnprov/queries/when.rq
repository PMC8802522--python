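# When was an activity conducted?
# Starting times (timestamps or phrases) per atomic activity in execution
# order.  Optional binding: ?section restricts to one approach.
PREFIX prov: <http://www.w3.org/ns/prov#>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX schema: <http://schema.org/>
PREFIX ep: <https://w3id.org/eln-provenance/vocab#>
PREFIX owl: <http://www.w3.org/2002/07/owl#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>

SELECT ?activity ?startingTime (COUNT(DISTINCT ?prev) AS ?nPrev)
WHERE {
  ?section obo:BFO_0000051 ?activity .
  ?activity ep:startingTime ?startingTime .
  OPTIONAL { ?activity prov:wasInformedBy+ ?prev }
}
GROUP BY ?activity ?startingTime
ORDER BY ?nPrev ?activity
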