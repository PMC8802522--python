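# Who participated in the study?
# One row per experimentalist with the other involved persons.
PREFIX prov: <http://www.w3.org/ns/prov#>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX schema: <http://schema.org/>
PREFIX ep: <https://w3id.org/eln-provenance/vocab#>
PREFIX owl: <http://www.w3.org/2002/07/owl#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>

SELECT ?experimentalist (GROUP_CONCAT(DISTINCT COALESCE(?involvedName, ""); separator=", ") AS ?involvedPersons)
WHERE {
  ?protocol prov:qualifiedAssociation ?qa .
  ?qa prov:hadRole ep:Experimentalist ; prov:agent ?person .
  ?person schema:name ?experimentalist .
  OPTIONAL {
    ?protocol prov:qualifiedAssociation ?qa2 .
    ?qa2 prov:hadRole ep:InvolvedPerson ; prov:agent ?other .
    ?other schema:name ?involvedName .
  }
}
GROUP BY ?experimentalist
ORDER BY ?experimentalist
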