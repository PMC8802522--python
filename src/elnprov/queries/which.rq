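# Which biological and chemical resources and which equipment was used?
# One row per atomic activity with its used resources (inventory items,
# resource instances with passage/lot, mixture inputs) in execution order.
# Optional binding: ?section restricts to one approach.
PREFIX prov: <http://www.w3.org/ns/prov#>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX schema: <http://schema.org/>
PREFIX ep: <https://w3id.org/eln-provenance/vocab#>
PREFIX owl: <http://www.w3.org/2002/07/owl#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>

SELECT ?activity (GROUP_CONCAT(DISTINCT COALESCE(?resourceName, ""); separator=", ") AS ?resources) (COUNT(DISTINCT ?prev) AS ?nPrev)
WHERE {
  ?section obo:BFO_0000051 ?activity .
  ?activity a prov:Activity .
  FILTER NOT EXISTS { ?activity obo:BFO_0000051 ?part }
  OPTIONAL {
    { ?activity prov:used ?resource } UNION { ?activity obo:OBI_0000293 ?resource }
    ?resource rdfs:label ?resourceName .
    FILTER NOT EXISTS { ?resource a schema:MediaObject }
  }
  OPTIONAL { ?activity prov:wasInformedBy+ ?prev }
}
GROUP BY ?activity
ORDER BY ?nPrev ?activity
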