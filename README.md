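# s3dbcore

A Python implementation of the S3DB core model: a minimal RDF design pattern
for biomedical data management that separates the **description of a domain**
from its **observational instantiation**, together with the finite-state
machinery that propagates **user-operator states** (permissions, typically)
from the description down to the data instantiating it.

It is aimed at people building semantic data infrastructure — multi-project
repositories, clinical or molecular-epidemiology databases — who want
domain experts to evolve the schema freely without corrupting existing data,
and who need fine-grained, inheritable access control without per-record
permission tables.

## The model

Seven entity kinds, canonically ordered `[D, P, C, R, I, S, U]` —
deployment, project, collection, rule, item, statement, user — are connected
by twelve typed relationships with fixed domain/range pairs
(`DP: D→P`, `PC: P→C`, `PR: P→R`, `CI: C→I`, `Rsubject: C→R`, `Robject: C→R`,
`Rpredicate: I→R`, `Spredicate: R→S`, `Ssubject: I→S`, `Sobject: I→S`,
`DU: D→U`, `UU: U→U`).

The two-tier predication pattern sits at the center:

* a **rule** is a dyadic predicate `(subject collection, predicate item,
  object)` — "people *live in* places", with the object a collection or any
  other resource (e.g. `foaf:firstName`);
* a **statement** uses the whole rule as its predicate —
  `:I_Mary :R_people_in_places :I_Houston`, or
  `:I_Mary :R_people_have_names "Mary"` when the rule's object is not a
  collection.

Because the tiers are separate, re-pointing a rule's object never changes
the URI or value of any statement that instantiates it.

An **operator** `f` is a discrete variable with `n` ordered states, each
usable in a dominant (upper-case) or recessive (lower-case) form, asserted
as `{U f E}` triples between a user and any entity. Three functions resolve
effective states:

* `merge(S)` — the dominant state of minimum index if any dominant state is
  assigned, else the recessive state of maximum index;
* `migrate(s, m)` — states pass along every relationship licensed by a
  Boolean kind-by-kind transition matrix `T`; a string of `m`-tuples
  (`m` = operators sharing the alphabet) leaves its first tuple behind as
  the source's effective state and passes the rest; singular strings pass
  unchanged; incomplete tuples borrow the symbol to their left;
* `percolate` — iterated migration to the fixed point where no entity's
  effective state changes.

The stock configuration bundles three operators — *view*, *edit*, *use* —
over the ordered states `(all, self, none)` = indexes `(1, 2, 3)`.

## Worked example

```
$ s3db --store demo.ttl fixture mary
wrote demo.ttl: 13 entities, 2 statements
$ s3db --store demo.ttl add user --label alice
http://example.org/deploy/U1
$ s3db --store demo.ttl assign --user http://example.org/deploy/U1 \
      --target http://example.org/deploy/C_person --state asn
ok
$ s3db --store demo.ttl effective --user http://example.org/deploy/U1 \
      --target http://example.org/deploy/I_Mary
{
  "user": "http://example.org/deploy/U1",
  "target": "http://example.org/deploy/I_Mary",
  "effective": {
    "view": "all",
    "edit": "self",
    "use": "none"
  }
}
$ s3db --store demo.ttl allowed --user http://example.org/deploy/U1 \
      --target http://example.org/deploy/I_Mary --operator view
allow
```

The single assignment `asn` on the *collection* of people percolated to the
item Mary (and to every rule and statement downstream): alice may view Mary
(`all`, index 1), may edit only entities she created (`self`, index 2), and
may not use her (`none`, index 3) — so `allowed --operator use` prints
`deny`.

The same flows are available as a library:

```python
from s3dbcore import (Store, build_mary_fixture, EntityKind, default_bundle,
                      percolate, is_allowed)
store = build_mary_fixture(Store.new("http://example.org/deploy"))
alice = store.create_entity(EntityKind.USER, "alice")
store.assign(alice, "http://example.org/deploy/C_person", "asn")
pool = percolate(store, alice.uri)
is_allowed(store, pool, alice.uri, "http://example.org/deploy/I_Mary", "view")
# True
```

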