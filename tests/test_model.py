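"""Entity kinds, typed relations, rules/statements, and store invariants."""

import pytest

from s3dbcore import (
    Entity,
    EntityKind,
    RelationKind,
    Store,
    build_mary_fixture,
    validate_store,
)
from s3dbcore.errors import (
    DependentsExistError,
    DomainViolation,
    DuplicateRootError,
    FixtureCollisionError,
    MembershipError,
    ObjectTypeError,
    RangeViolation,
    S3DBError,
    UnsupportedEditError,
)
from s3dbcore.model import RelationInstance

BASE = "http://example.org/deploy"


class TestKinds:
    def test_seven_entity_kinds_in_canonical_order(self):
        order = EntityKind.canonical_order()
        assert [k.initial for k in order] == list("DPCRISU")
        assert [k.ordinal for k in order] == list(range(1, 8))

    def test_twelve_relationship_kinds_match_domain_range_table(self):
        table = {
            1: ("DP", "D", "P"), 2: ("PC", "P", "C"), 3: ("PR", "P", "R"),
            4: ("CI", "C", "I"), 5: ("Rsubject", "C", "R"),
            6: ("Robject", "C", "R"), 7: ("Rpredicate", "I", "R"),
            8: ("Spredicate", "R", "S"), 9: ("Ssubject", "I", "S"),
            10: ("Sobject", "I", "S"), 11: ("DU", "D", "U"),
            12: ("UU", "U", "U"),
        }
        assert len(RelationKind) == 12
        for rk in RelationKind:
            name, dom, rng = table[rk.index]
            assert rk.rel_name == name
            assert rk.domain_kind.initial == dom
            assert rk.range_kind.initial == rng


class TestMinting:
    def test_first_item_uri_is_base_i1(self, fresh_store):
        assert fresh_store.mint_uri(EntityKind.ITEM) == f"{BASE}/I1"

    def test_successive_mints_are_distinct(self, fresh_store):
        a = fresh_store.create_entity(EntityKind.ITEM)
        b = fresh_store.create_entity(EntityKind.ITEM)
        assert a.uri != b.uri

    def test_replayed_construction_yields_identical_uris(self):
        def build():
            s = Store.new(BASE)
            p = s.create_entity(EntityKind.PROJECT)
            c = s.create_entity(EntityKind.COLLECTION)
            s.assert_relation(p, RelationKind.PC, c)
            return sorted(s.entities)
        assert build() == build()

    def test_random_style_is_seed_deterministic_and_collision_free(self):
        uris = [Store(BASE, uri_style="random", random_seed=7).mint_uri(
            EntityKind.ITEM) for _ in range(2)]
        assert uris[0] == uris[1]
        s = Store(BASE, uri_style="random", random_seed=7)
        assert len({s.create_entity(EntityKind.ITEM).uri for _ in range(50)}) == 50


class TestEntities:
    def test_second_deployment_is_refused(self, fresh_store):
        with pytest.raises(DuplicateRootError):
            fresh_store.create_entity(EntityKind.DEPLOYMENT)

    def test_item_without_collection_membership_is_accepted(self, fresh_store):
        ent = fresh_store.create_entity(EntityKind.ITEM, "lives_in")
        assert fresh_store.entities[ent.uri].kind is EntityKind.ITEM

    def test_non_external_entity_requires_kind(self):
        with pytest.raises(S3DBError):
            Entity(uri="x", kind=None)


class TestRelations:
    def test_ci_between_collection_and_item(self, fresh_store):
        c = fresh_store.create_entity(EntityKind.COLLECTION, "person")
        i = fresh_store.create_entity(EntityKind.ITEM, "Mary")
        rel = fresh_store.assert_relation(c, RelationKind.CI, i)
        assert rel in fresh_store.relations

    def test_domain_violation_names_the_table_row(self, fresh_store):
        c = fresh_store.create_entity(EntityKind.COLLECTION)
        i = fresh_store.create_entity(EntityKind.ITEM)
        with pytest.raises(DomainViolation, match="relationship 2"):
            fresh_store.assert_relation(i, RelationKind.PC, c)

    def test_range_violation_raises(self, fresh_store):
        p = fresh_store.create_entity(EntityKind.PROJECT)
        i = fresh_store.create_entity(EntityKind.ITEM)
        with pytest.raises(RangeViolation):
            fresh_store.assert_relation(p, RelationKind.PC, i)

    def test_user_to_user_link_is_typed_correctly(self, fresh_store):
        a = fresh_store.create_entity(EntityKind.USER, "a")
        b = fresh_store.create_entity(EntityKind.USER, "b")
        fresh_store.assert_relation(a, RelationKind.UU, b)

    def test_reassertion_is_idempotent(self, fresh_store):
        c = fresh_store.create_entity(EntityKind.COLLECTION)
        i = fresh_store.create_entity(EntityKind.ITEM)
        fresh_store.assert_relation(c, RelationKind.CI, i)
        before = (set(fresh_store.relations), dict(fresh_store.entities))
        fresh_store.assert_relation(c, RelationKind.CI, i)
        assert (set(fresh_store.relations), dict(fresh_store.entities)) == before

    @pytest.mark.parametrize("k", [0, 1, 3])
    def test_item_may_belong_to_many_collections(self, fresh_store, k):
        cols = [fresh_store.create_entity(EntityKind.COLLECTION)
                for _ in range(k)]
        i = fresh_store.create_entity(EntityKind.ITEM)
        for c in cols:
            fresh_store.assert_relation(c, RelationKind.CI, i)
        memberships = [r for r in fresh_store.relations
                       if r.relation is RelationKind.CI and r.object == i.uri]
        assert len(memberships) == k


@pytest.fixture
def domain(fresh_store):
    """Project with person/places collections, Mary and Houston as members."""
    s = fresh_store
    p = s.create_entity(EntityKind.PROJECT, "example")
    c_person = s.create_entity(EntityKind.COLLECTION, "person")
    c_places = s.create_entity(EntityKind.COLLECTION, "places")
    s.assert_relation(p, RelationKind.PC, c_person)
    s.assert_relation(p, RelationKind.PC, c_places)
    mary = s.create_entity(EntityKind.ITEM, "Mary")
    houston = s.create_entity(EntityKind.ITEM, "Houston")
    lives_in = s.create_entity(EntityKind.ITEM, "lives_in")
    s.assert_relation(c_person, RelationKind.CI, mary)
    s.assert_relation(c_places, RelationKind.CI, houston)
    return dict(store=s, project=p, person=c_person, places=c_places,
                mary=mary, houston=houston, lives_in=lives_in)


class TestRules:
    def test_collection_object_rule_asserts_all_four_links(self, domain):
        s = domain["store"]
        r = s.add_rule(domain["project"], domain["person"], domain["lives_in"],
                       domain["places"])
        assert r.object_is_collection
        for rel, subj in [(RelationKind.PR, domain["project"].uri),
                          (RelationKind.RSUBJECT, domain["person"].uri),
                          (RelationKind.RPREDICATE, domain["lives_in"].uri),
                          (RelationKind.ROBJECT, domain["places"].uri)]:
            assert RelationInstance(subj, rel, r.uri) in s.relations

    def test_external_resource_object_rule(self, domain):
        s = domain["store"]
        r = s.add_rule(domain["project"], domain["person"], domain["lives_in"],
                       "foaf:firstName")
        assert not r.object_is_collection
        assert s.entities["foaf:firstName"].external

    def test_collection_predicate_is_refused(self, domain):
        with pytest.raises(DomainViolation, match="relationship 7"):
            domain["store"].add_rule(domain["project"], domain["person"],
                                     domain["places"], domain["places"])


class TestStatements:
    def test_item_object_statement(self, domain):
        s = domain["store"]
        r = s.add_rule(domain["project"], domain["person"], domain["lives_in"],
                       domain["places"])
        stmt = s.add_statement(r, domain["mary"], domain["houston"])
        assert stmt.object == domain["houston"].uri and stmt.object_is_item

    def test_literal_object_statement(self, domain):
        s = domain["store"]
        r = s.add_rule(domain["project"], domain["person"], domain["lives_in"],
                       "foaf:firstName")
        stmt = s.add_statement(r, domain["mary"], "Mary")
        assert stmt.object == "Mary" and not stmt.object_is_item

    def test_subject_outside_rule_collection_is_refused(self, domain):
        s = domain["store"]
        r = s.add_rule(domain["project"], domain["person"], domain["lives_in"],
                       domain["places"])
        with pytest.raises(MembershipError):
            s.add_statement(r, domain["houston"], domain["mary"])

    def test_literal_for_collection_object_rule_is_refused(self, domain):
        s = domain["store"]
        r = s.add_rule(domain["project"], domain["person"], domain["lives_in"],
                       domain["places"])
        with pytest.raises(ObjectTypeError):
            s.add_statement(r, domain["mary"], "Houston the literal")

    def test_item_for_literal_object_rule_is_refused(self, domain):
        s = domain["store"]
        r = s.add_rule(domain["project"], domain["person"], domain["lives_in"],
                       "foaf:firstName")
        with pytest.raises(ObjectTypeError):
            s.add_statement(r, domain["mary"], domain["houston"])

    def test_object_outside_rule_object_collection_is_refused(self, domain):
        s = domain["store"]
        r = s.add_rule(domain["project"], domain["person"], domain["lives_in"],
                       domain["places"])
        other = s.create_entity(EntityKind.ITEM, "stray")
        with pytest.raises(MembershipError):
            s.add_statement(r, domain["mary"], other)


class TestRuleObjectEditing:
    def test_edit_keeps_statement_uris_and_values(self, domain):
        s = domain["store"]
        r = s.add_rule(domain["project"], domain["person"], domain["lives_in"],
                       "foaf:firstName")
        stmt = s.add_statement(r, domain["mary"], "Mary")
        before = dict(s.statements)
        r2 = s.update_rule_object(r, "name")
        assert r2.object == "name"
        assert dict(s.statements) == before
        assert s.statements[stmt.uri].object == "Mary"

    def test_identity_edit_is_a_noop(self, domain):
        s = domain["store"]
        r = s.add_rule(domain["project"], domain["person"], domain["lives_in"],
                       "foaf:firstName")
        rels = set(s.relations)
        assert s.update_rule_object(r, "foaf:firstName") == r
        assert set(s.relations) == rels

    def test_collection_object_edit_is_refused(self, domain):
        s = domain["store"]
        r = s.add_rule(domain["project"], domain["person"], domain["lives_in"],
                       domain["places"])
        with pytest.raises(UnsupportedEditError):
            s.update_rule_object(r, "somewhere_else")


class TestDeletion:
    def test_refused_while_dependents_exist(self, domain):
        s = domain["store"]
        with pytest.raises(DependentsExistError):
            s.delete_entity(domain["person"].uri)

    def test_cascade_removes_dependents_transitively(self, domain):
        s = domain["store"]
        r = s.add_rule(domain["project"], domain["person"], domain["lives_in"],
                       domain["places"])
        stmt = s.add_statement(r, domain["mary"], domain["houston"])
        s.delete_entity(domain["person"].uri, cascade=True)
        assert r.uri not in s.rules and stmt.uri not in s.statements
        assert not any(v.severity == "error" for v in validate_store(s))


class TestValidation:
    def test_mary_fixture_has_no_errors(self, mary_store):
        errors = [v for v in validate_store(mary_store)
                  if v.severity == "error"]
        assert errors == []

    def test_predicate_item_without_collection_is_a_warning(self, mary_store):
        codes = {v.code for v in validate_store(mary_store)}
        assert codes <= {"W_PREDICATE_NO_COLLECTION"}

    def test_lost_membership_is_reported(self, mary_store):
        ci = next(r for r in mary_store.relations
                  if r.relation is RelationKind.CI
                  and r.object.endswith("I_Mary"))
        mary_store.relations.discard(ci)
        codes = [v.code for v in validate_store(mary_store)
                 if v.severity == "error"]
        assert codes.count("E_MEMBERSHIP") == 2  # both statements break


class TestMaryFixture:
    def test_entity_census(self, mary_store):
        counts = {}
        for e in mary_store.entities.values():
            key = e.kind.kind_name if e.kind else "external"
            counts[key] = counts.get(key, 0) + 1
        assert counts == {"deployment": 1, "project": 1, "collection": 2,
                          "item": 4, "rule": 2, "statement": 2, "external": 1}

    def test_names_rule_statement_has_literal_mary(self, mary_store):
        rule = next(r for r in mary_store.rules.values()
                    if r.object == "foaf:firstName")
        stmt = next(s for s in mary_store.statements.values()
                    if s.rule == rule.uri)
        assert (stmt.object, stmt.object_is_item) == ("Mary", False)

    def test_lives_in_statement_links_mary_to_houston(self, mary_store):
        stmt = next(s for s in mary_store.statements.values()
                    if s.object_is_item)
        assert stmt.subject_item.endswith("I_Mary")
        assert stmt.object.endswith("I_Houston")

    def test_collision_on_non_fresh_store(self, mary_store):
        with pytest.raises(FixtureCollisionError):
            build_mary_fixture(mary_store)
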