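"""Seeded generator of random valid stores with operator assignments.

The generator builds instance graphs of arbitrary shape that always satisfy
the core-model invariants — every statement's subject really is a member of
its rule's subject collection, rule objects are collections or external
resources, and so on — so property suites can run against any seed.  Shapes
default to a mid-sized store (a handful of collections and rules, a few
dozen items and statements) comparable to the worked examples; counts,
many-to-many membership density, the fraction of literal-object rules, and
assignment depth are all dials of :class:`GeneratorParams`.

Determinism: the same parameters and seed always produce the identical
store, byte-for-byte identical under Turtle export.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .errors import GeneratorParameterError
from .model import EntityKind, RelationKind, Store
from .states import OperatorBundle, default_bundle

_WORDS = ("tumor", "sample", "isolate", "assay", "patient", "lesion", "probe",
          "variant", "tissue", "clone", "marker", "strain", "cohort", "site")


@dataclass(frozen=True)
class GeneratorParams:
    """Shape and randomness of a synthetic store."""

    n_projects: int = 1
    n_collections: int = 4
    n_items: int = 12
    n_rules: int = 4
    n_statements: int = 10
    n_users: int = 2
    n_uu_links: int = 0
    extra_membership_density: float = 0.15  # chance of extra CI links per item
    literal_rule_fraction: float = 0.4
    n_assignments: int = 3
    max_tuple_depth: int = 2
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_projects, self.n_collections, self.n_items,
                  self.n_rules, self.n_statements, self.n_users,
                  self.n_uu_links, self.n_assignments)
        if any(c < 0 for c in counts):
            raise GeneratorParameterError("all counts must be >= 0")
        for f in (self.extra_membership_density, self.literal_rule_fraction):
            if not 0.0 <= f <= 1.0:
                raise GeneratorParameterError("densities must lie in [0, 1]")
        if self.max_tuple_depth < 1:
            raise GeneratorParameterError("max_tuple_depth must be >= 1")
        if self.n_collections and not self.n_projects:
            raise GeneratorParameterError("collections need a project")
        if self.n_items and not self.n_collections:
            raise GeneratorParameterError("items need a collection")
        if self.n_rules and (not self.n_collections or not self.n_items):
            raise GeneratorParameterError(
                "rules need a subject collection and a predicate item")
        if self.n_statements and not self.n_rules:
            raise GeneratorParameterError("statements need a rule")
        if self.n_uu_links and self.n_users < 2:
            raise GeneratorParameterError("user-to-user links need two users")
        if self.n_assignments and not self.n_users:
            raise GeneratorParameterError("assignments need a user")


def generate_random_store(params: GeneratorParams | None = None, *,
                          bundle: OperatorBundle | None = None,
                          base_uri: str = "http://example.org/deploy") -> Store:
    """Build a random valid store; assignments land in ``store.assignments``."""
    params = params or GeneratorParams()
    params.validate()
    if bundle is None:
        bundle = default_bundle()
    rng = random.Random(params.seed)
    store = Store.new(base_uri)
    dep = store.deployment

    users = [store.create_entity(EntityKind.USER, f"user{i}")
             for i in range(params.n_users)]
    for u in users:
        store.assert_relation(dep, RelationKind.DU, u)
    uu_pairs = set()
    while len(uu_pairs) < params.n_uu_links:
        a, b = rng.sample(users, 2)
        uu_pairs.add((a.uri, b.uri))
    for a, b in sorted(uu_pairs):
        store.assert_relation(a, RelationKind.UU, b)

    projects = []
    for i in range(params.n_projects):
        p = store.create_entity(EntityKind.PROJECT, f"project{i}")
        store.assert_relation(dep, RelationKind.DP, p)
        projects.append(p)

    collections = []
    for i in range(params.n_collections):
        c = store.create_entity(
            EntityKind.COLLECTION, f"{rng.choice(_WORDS)}_{i}",
            creator=rng.choice(users).uri if users else None)
        store.assert_relation(rng.choice(projects), RelationKind.PC, c)
        collections.append(c)

    items = []
    for i in range(params.n_items):
        it = store.create_entity(
            EntityKind.ITEM, f"{rng.choice(_WORDS)}_{i}",
            creator=rng.choice(users).uri if users else None)
        home = rng.choice(collections)
        store.assert_relation(home, RelationKind.CI, it)
        for c in collections:  # many-to-many memberships
            if c is not home and rng.random() < params.extra_membership_density:
                store.assert_relation(c, RelationKind.CI, it)
        items.append(it)

    rules = []
    for i in range(params.n_rules):
        subj = rng.choice(collections)
        pred = rng.choice(items)
        if rng.random() < params.literal_rule_fraction:
            obj = f"attr:{rng.choice(_WORDS)}_{i}"
        else:
            obj = rng.choice(collections)
        rules.append(store.add_rule(rng.choice(projects), subj, pred, obj,
                                    label=f"rule{i}"))

    for i in range(params.n_statements):
        rule = rng.choice(rules)
        members = store.members(rule.subject_collection)
        if not members:  # guarantee an eligible subject
            it = rng.choice(items)
            store.assert_relation(rule.subject_collection, RelationKind.CI, it)
            members = [it]
        subj = rng.choice(members)
        if rule.object_is_collection:
            obj_members = store.members(rule.object)
            if not obj_members:
                it = rng.choice(items)
                store.assert_relation(rule.object, RelationKind.CI, it)
                obj_members = [it]
            store.add_statement(rule, subj, rng.choice(obj_members),
                                creator=rng.choice(users).uri if users else None)
        else:
            store.add_statement(rule, subj, f"value_{i}",
                                creator=rng.choice(users).uri if users else None)

    targets = [e for e in store.entities.values() if not e.external]
    letters = bundle.alphabet.letters
    for _ in range(params.n_assignments):
        user = rng.choice(users)
        target = rng.choice(targets)
        length = rng.randint(1, bundle.m * params.max_tuple_depth)
        state = "".join(
            c.upper() if rng.random() < 0.25 else c
            for c in (rng.choice(letters) for _ in range(length)))
        store.assign(user, target, state)
    return store
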