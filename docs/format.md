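# Turtle dialect reference

Namespace: `s3db:` → `http://s3db.example.org/core#` (placeholder; no
official namespace is published). Well-known prefixes (`foaf:`, `rdf:`,
`rdfs:`, `owl:`) are expanded on export and contracted back on import.

## Reified style (normative, accepted by import)

| Triple | Meaning |
|---|---|
| `<e> rdf:type s3db:<kind>` | entity of kind deployment/project/collection/rule/item/statement/user |
| `<e> rdfs:label "text"` | optional human-readable label |
| `<e> s3db:createdBy <user>` | optional creator (gives the `self` permission state meaning) |
| `<dep> s3db:baseURI "uri"` | the deployment's minting base |
| `<s> s3db:DP\|PC\|PR\|CI\|Rsubject\|Robject\|Rpredicate\|Spredicate\|Ssubject\|Sobject\|DU\|UU <o>` | one relation instance |
| `<rule> s3db:RobjectLiteral "name"` | rule object that is a bare name (cannot be an RDF subject) |
| `<stmt> s3db:SobjectLiteral "value"` | literal statement object |
| `<user> s3db:operator "bundle\|state\|target"^^s3db:assignment` | one operator-state assignment |

External resources (e.g. `foaf:firstName`) appear only as subjects of
`s3db:Robject` triples and carry no `rdf:type`.

## Compact style (derived convenience view)

Adds, for every statement, one triple with the rule URI as predicate:

```
:I_Mary :R_people_in_places :I_Houston .
:I_Mary :R_people_have_names "Mary" .
```

Compact documents still contain all reified triples; import ignores the
compact triples (they are foreign predicates) and rebuilds from the reified
ones.

## Operator bundle configuration (YAML)

```yaml
letters: [a, s, n]
default_decision: deny
operators:
  - {name: view, states: [all, self, none]}
  - {name: edit, states: [all, self, none]}
  - {name: use,  states: [all, self, none]}
```

## CLI exit codes

0 success · 1 validation/import failure · 2 usage error.
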