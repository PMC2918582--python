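# Methods

## The model

A store is a typed directed graph with one deployment root. Entity kinds are
fixed at seven (deployment, project, collection, rule, item, statement,
user; canonical order `[D, P, C, R, I, S, U]` by initial) and relationship
kinds at twelve, each with an immutable (domain, range) pair. Relationship
direction always runs from domain description toward instantiation — the
item is the *subject* of the `Ssubject` edge pointing at the statement, the
inverse of plain RDF reification — which is what lets one Boolean transition
matrix drive both the schema typing and the state propagation.

Rules and statements form the two-tier predication pattern. A rule is the
triple (subject collection, predicate item, object); a statement's predicate
is a whole rule, its subject an item of the rule's subject collection, and
its object either an item of the rule's object collection or, when the
rule's object is not a collection, an opaque literal. Statement construction
enforces both membership constraints and the literal/item object typing;
`validate_store` re-checks them (plus domain/range typing of every edge and
the single root) on demand, returning machine-coded violations.

No cardinality constraints exist anywhere: an item may belong to many
collections, a collection may subject many rules, and so on.

## Operator states

An operator has `n` ordered states; a state symbol is an index `1..n` plus a
dominance flag rendered as letter case. A bundle groups `m` operators that
share one state alphabet, so one string of `m`-tuples spans all of them
(tuple position `j` belongs to operator `j`).

* **merge** — minimum-index dominant if any dominant state is assigned,
  else maximum-index recessive. The published rendering of this resolution
  is not machine-readable; this formalization is pinned because it uniquely
  reproduces both documented examples (`merge({'b','c','d'}) = 3`,
  `merge({'b','c','C','D'}) = 2`) and the accompanying remark that a
  recessive index 3 loses to a dominant index 2. Merge is commutative,
  associative and idempotent, so set-merge equals any pairwise fold.
* **migrate** — a string is first *normalized* to whole `m`-tuples by
  repeating its last symbol (left-borrowing: an unspecified operator
  position takes its left neighbour's symbol). A normalized string of one
  tuple passes unchanged; a longer one sheds its first tuple — the source's
  effective state — and passes the remainder. This normalization rule is
  the unique padding that reproduces all four documented `m = 3` examples
  (`'a'→'aaa'`, `'abc'→'abc'`, `'abcb'→'bbb'`, `'abcbc'→'bcc'`).
  Normalization is applied once, when an assignment is seeded into a pool.
* **percolate** — pools of strings per entity, seeded from one user's
  assignments, closed under one-step migration along every edge of the
  instance graph (the relation instances whose kind-level cell is true in
  the transition matrix). Termination is structural: every pooled string is
  a whole-tuple suffix of finitely many assignment strings and length-`m`
  strings migrate to themselves, so closure is reached even on cycles
  (user-to-user links). The fixed point is independent of edge processing
  order; the implementation exposes the iteration order as a parameter only
  so tests can demonstrate that confluence.

Pools deliberately keep the full string sets rather than merging after each
iteration: plural strings are depth-indexed (tuple `i` governs
depth-`(i-1)` descendants) and early merging would collapse that
expressivity. Effective states are merged only at reporting time, from the
operator's first-tuple symbols of everything pooled at the entity; both
readings agree at the fixed point for singular states, which is all the
fixed-point condition constrains.

## Permissions

The stock bundle is three operators (view, edit, use) over the ordered
states (all, self, none) — index 1 most permissive. Decision mapping:
index 1 allows, index 3 denies, index 2 allows only when the entity's
recorded creator is the requesting user; that reading of "self" is a design
choice (the source never defines it) and is why entities carry optional
creator metadata. An entity reached by no state maps to a configurable
default, deny unless the bundle says otherwise — again a choice, since no
default is documented. Display names for states are configurable (the
prototype being modelled calls them none/self/all in one place and
yes/self/no in another); indexes are canonical.

User-to-user propagation (assignments of a linked user migrating along `UU`
edges before entity percolation) is implemented behind `enable_uu`, default
off, matching the reference prototype's behaviour. Percolation is computed
per user independently. `percolate` accepts any transition matrix over any
kind alphabet; the stock 7×7 matrix, derived mechanically from the twelve
relationship typings (10 distinct true cells, each carrying the licensing
relationship indexes), is merely the default.

## Serialization

The reified Turtle dialect is normative: `rdf:type` triples in a
placeholder `s3db:` namespace (no official namespace is published), one
triple per relation instance, `s3db:RobjectLiteral` / `s3db:SobjectLiteral`
for values that cannot be RDF subjects/objects of the reified edges, and
assignments packed as `user s3db:operator "bundle|state|target"^^s3db:assignment`.
The compact style additionally writes each statement with its rule as the
predicate, as a human would; compact triples alone cannot round-trip
statement URIs, so import accepts only the reified dialect. Import is
lenient by default (foreign triples become external-resource records with a
warning) and strict on request. See `docs/format.md` for the full dialect.

## Synthetic stores

`generate_random_store` builds valid stores of configurable shape:
counts per kind, extra many-to-many membership density (default 0.15), the
fraction of rules with literal objects (default 0.4), and random operator
assignments with bounded tuple depth, including ragged lengths so the
left-borrowing normalization is exercised. Defaults (4 collections,
12 items, 4 rules, 10 statements, 2 users, 3 assignments) mirror the scale
of the worked example; the property campaigns in the test suite run 100
seeds at roughly 30 entities each, a size where the brute-force
path-enumeration oracle is still exact and the whole suite stays in seconds.
Everything is deterministic per seed, down to the serialized Turtle.

What the generator does *not* emulate: multi-deployment federation, foreign
URIs resolved over the network, authentication, or realistic biomedical
label vocabularies — passing tests say nothing about those. It also never
generates *invalid* stores, so negative paths are covered by hand-built
breakages in the unit tests instead.

## Numerical and degenerate choices

* URI minting is sequential per kind (`<base>/I1`, `<base>/I2`, ...) for
  reproducibility, with a seeded random style available; minting skips any
  identifier already taken by an explicitly named entity.
* Empty merge input raises; callers map it to the `unassigned` sentinel.
* Deletion refuses while dependents exist; `cascade=True` removes them
  transitively.
* Rule-object edits are allowed only for non-collection objects; re-pointing
  a collection object would orphan item objects and is refused.
* Predicate items that belong to no collection are legal (the model
  explicitly defers this) and reported as warnings, not errors.

## Known limitations

Single deployment per store; no query language, HTTP service, or
description-logic reasoning — the pattern is enforced purely by assertion.
Literals are opaque text with no datatype system. Stores are held fully in
memory; the implementation targets model-sized graphs, not bulk data.
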