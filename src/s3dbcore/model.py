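"""The core two-tier entity/relationship model.

Seven entity kinds — deployment, project, collection, rule, statement, item,
user — are connected by twelve typed relationships with fixed domain/range
pairs.  The design separates *description of a domain* (rules: "people live
in places") from its *observational instantiation* (statements: "Mary lives
in Houston").  A rule is a dyadic predicate over a subject collection, a
predicate item and an object (a collection or any other resource); each
statement then uses a whole rule as its predicate, linking an item of the
rule's subject collection to an item of the object collection, or to a
literal value when the rule's object is not a collection.

Because domain and instantiation live in separate tiers, the domain can be
edited (e.g. renaming the resource a rule points at) without touching the
URIs or values of the statements that already instantiate it.
"""

from __future__ import annotations

import enum
import logging
import random as _random
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Union

from .errors import (
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

logger = logging.getLogger(__name__)


class EntityKind(enum.Enum):
    """The seven entity kinds, in the canonical order [D, P, C, R, I, S, U]."""

    DEPLOYMENT = ("deployment", "D", 1)
    PROJECT = ("project", "P", 2)
    COLLECTION = ("collection", "C", 3)
    RULE = ("rule", "R", 4)
    ITEM = ("item", "I", 5)
    STATEMENT = ("statement", "S", 6)
    USER = ("user", "U", 7)

    def __init__(self, kind_name: str, initial: str, ordinal: int):
        self.kind_name = kind_name
        self.initial = initial
        self.ordinal = ordinal

    @classmethod
    def from_name(cls, name: str) -> "EntityKind":
        for k in cls:
            if k.kind_name == name:
                return k
        raise S3DBError(f"unknown entity kind {name!r}")

    @classmethod
    def canonical_order(cls) -> tuple["EntityKind", ...]:
        return tuple(sorted(cls, key=lambda k: k.ordinal))


_K = EntityKind


class RelationKind(enum.Enum):
    """The twelve relationship kinds with their domain/range typing.

    The direction of every relationship runs from domain description toward
    its instantiation, which is also the direction operator states migrate.
    Note the subject/predicate/object relationships of rules and statements
    are inverted relative to plain RDF reification (the item points *at* the
    statement it is subject of), precisely so that this directionality holds.
    """

    DP = (1, _K.DEPLOYMENT, _K.PROJECT)
    PC = (2, _K.PROJECT, _K.COLLECTION)
    PR = (3, _K.PROJECT, _K.RULE)
    CI = (4, _K.COLLECTION, _K.ITEM)
    RSUBJECT = (5, _K.COLLECTION, _K.RULE)
    ROBJECT = (6, _K.COLLECTION, _K.RULE)
    RPREDICATE = (7, _K.ITEM, _K.RULE)
    SPREDICATE = (8, _K.RULE, _K.STATEMENT)
    SSUBJECT = (9, _K.ITEM, _K.STATEMENT)
    SOBJECT = (10, _K.ITEM, _K.STATEMENT)
    DU = (11, _K.DEPLOYMENT, _K.USER)
    UU = (12, _K.USER, _K.USER)

    def __init__(self, index: int, domain_kind: EntityKind, range_kind: EntityKind):
        self.index = index
        self.domain_kind = domain_kind
        self.range_kind = range_kind

    @property
    def rel_name(self) -> str:
        # canonical mixed-case names as used in the vocabulary
        return _REL_NAMES[self]

    @classmethod
    def from_name(cls, name: str) -> "RelationKind":
        for k, n in _REL_NAMES.items():
            if n == name or k.name == name.upper():
                return k
        raise S3DBError(f"unknown relationship kind {name!r}")


_REL_NAMES = {
    RelationKind.DP: "DP",
    RelationKind.PC: "PC",
    RelationKind.PR: "PR",
    RelationKind.CI: "CI",
    RelationKind.RSUBJECT: "Rsubject",
    RelationKind.ROBJECT: "Robject",
    RelationKind.RPREDICATE: "Rpredicate",
    RelationKind.SPREDICATE: "Spredicate",
    RelationKind.SSUBJECT: "Ssubject",
    RelationKind.SOBJECT: "Sobject",
    RelationKind.DU: "DU",
    RelationKind.UU: "UU",
}


@dataclass(frozen=True)
class Entity:
    """A URI-identified node of the store.

    ``kind`` is None only for *external* resources — foreign URIs or bare
    literal names used as rule objects, which are referenced but not minted
    by the store.
    """

    uri: str
    kind: Optional[EntityKind]
    label: Optional[str] = None
    creator: Optional[str] = None
    external: bool = False

    def __post_init__(self):
        if self.kind is None and not self.external:
            raise S3DBError(f"entity {self.uri!r} without kind must be external")


@dataclass(frozen=True)
class RelationInstance:
    """A typed edge; set semantics, so re-asserting is a no-op."""

    subject: str
    relation: RelationKind
    object: str


@dataclass(frozen=True)
class Rule:
    """Domain description: (subject collection, predicate item, object).

    ``object`` is either the URI of a collection entity or the URI/name of an
    external resource; ``object_is_collection`` disambiguates.
    """

    uri: str
    subject_collection: str
    predicate_item: str
    object: str
    object_is_collection: bool


@dataclass(frozen=True)
class Statement:
    """Observational instantiation: the rule is the statement's predicate."""

    uri: str
    subject_item: str
    rule: str
    object: str
    object_is_item: bool


@dataclass(frozen=True)
class Assignment:
    """An operator-state assignment {user, operator-bundle state, entity}."""

    user: str
    target: str
    bundle: str
    state: str


@dataclass(frozen=True)
class Violation:
    """One broken invariant, reported by :func:`validate_store`."""

    code: str
    severity: str  # "error" | "warning"
    message: str
    uris: tuple[str, ...] = ()


class Store:
    """A single-deployment graph of entities and typed relations.

    The deployment is the root; exactly one may exist. URIs are minted
    sequentially per kind under ``base_uri`` (``<base>/I1``, ``<base>/I2``,
    ...) so that replaying the same construction sequence reproduces the
    same identifiers; ``uri_style="random"`` switches to seeded random
    hexadecimal suffixes instead.
    """

    def __init__(self, base_uri: str, *, uri_style: str = "sequential",
                 random_seed: int = 0):
        if uri_style not in ("sequential", "random"):
            raise S3DBError(f"unknown uri_style {uri_style!r}")
        self.base_uri = base_uri.rstrip("/")
        self.uri_style = uri_style
        self._rng = _random.Random(random_seed)
        self.entities: dict[str, Entity] = {}
        self.relations: set[RelationInstance] = set()
        self.rules: dict[str, Rule] = {}
        self.statements: dict[str, Statement] = {}
        self.assignments: list[Assignment] = []
        self._counters: dict[EntityKind, int] = {k: 0 for k in EntityKind}

    # -- construction ------------------------------------------------------

    @classmethod
    def new(cls, base_uri: str, **kw) -> "Store":
        """Create a store and mint its deployment root."""
        store = cls(base_uri, **kw)
        store.create_entity(EntityKind.DEPLOYMENT)
        return store

    @property
    def deployment(self) -> Optional[Entity]:
        for e in self.entities.values():
            if e.kind is EntityKind.DEPLOYMENT:
                return e
        return None

    def mint_uri(self, kind: EntityKind) -> str:
        if self.uri_style == "random":
            while True:
                uri = f"{self.base_uri}/{kind.initial}{self._rng.getrandbits(48):012x}"
                if uri not in self.entities:
                    return uri
        while True:
            self._counters[kind] += 1
            uri = f"{self.base_uri}/{kind.initial}{self._counters[kind]}"
            if uri not in self.entities:
                return uri

    def create_entity(self, kind: EntityKind, label: Optional[str] = None, *,
                      uri: Optional[str] = None,
                      creator: Optional[str] = None) -> Entity:
        if kind is EntityKind.DEPLOYMENT and self.deployment is not None:
            raise DuplicateRootError(
                f"store {self.base_uri} already has a deployment root")
        if uri is None:
            uri = self.mint_uri(kind)
        elif uri in self.entities:
            raise S3DBError(f"URI already in use: {uri}")
        ent = Entity(uri=uri, kind=kind, label=label, creator=creator)
        self.entities[uri] = ent
        logger.info("created %s %s", kind.kind_name, uri)
        return ent

    def external_resource(self, ref: str) -> Entity:
        """Register (or fetch) an external resource record for ``ref``."""
        existing = self.entities.get(ref)
        if existing is not None:
            if not existing.external:
                raise S3DBError(f"{ref} already names a non-external entity")
            return existing
        ent = Entity(uri=ref, kind=None, label=ref, external=True)
        self.entities[ref] = ent
        return ent

    # -- resolution helpers ------------------------------------------------

    def _resolve(self, e: Union[Entity, str]) -> Entity:
        uri = e.uri if isinstance(e, Entity) else e
        try:
            return self.entities[uri]
        except KeyError:
            raise S3DBError(f"entity not in store: {uri}") from None

    def members(self, collection: Union[Entity, str]) -> list[Entity]:
        c = self._resolve(collection)
        return [self.entities[r.object] for r in self.relations
                if r.relation is RelationKind.CI and r.subject == c.uri]

    def is_member(self, item: Union[Entity, str],
                  collection: Union[Entity, str]) -> bool:
        i, c = self._resolve(item), self._resolve(collection)
        return RelationInstance(c.uri, RelationKind.CI, i.uri) in self.relations

    # -- relations ---------------------------------------------------------

    def assert_relation(self, subject: Union[Entity, str], relation: RelationKind,
                        obj: Union[Entity, str]) -> RelationInstance:
        s, o = self._resolve(subject), self._resolve(obj)
        self._check_typing(s, relation, o)
        inst = RelationInstance(s.uri, relation, o.uri)
        self.relations.add(inst)
        return inst

    @staticmethod
    def _check_typing(s: Entity, relation: RelationKind, o: Entity) -> None:
        # external resources are admitted only as Robject subjects: a rule
        # may point at any resource, which is not itself a store entity
        if s.external:
            if relation is not RelationKind.ROBJECT:
                raise DomainViolation(
                    f"external resource {s.uri} may only subject Robject "
                    f"(violates relationship {relation.index} {relation.rel_name})")
        elif s.kind is not relation.domain_kind:
            raise DomainViolation(
                f"{relation.rel_name} (relationship {relation.index}) requires a "
                f"{relation.domain_kind.kind_name} subject, got "
                f"{s.kind.kind_name} {s.uri}")
        if o.external or o.kind is not relation.range_kind:
            raise RangeViolation(
                f"{relation.rel_name} (relationship {relation.index}) requires a "
                f"{relation.range_kind.kind_name} object, got "
                f"{o.kind.kind_name if o.kind else 'external'} {o.uri}")

    # -- rules and statements ---------------------------------------------

    def add_rule(self, project: Union[Entity, str],
                 subject_collection: Union[Entity, str],
                 predicate_item: Union[Entity, str],
                 obj: Union[Entity, str], *, label: Optional[str] = None,
                 uri: Optional[str] = None,
                 creator: Optional[str] = None) -> Rule:
        """Describe a piece of domain: subject collection, predicate item, object.

        ``obj`` may be a collection entity, or any string naming an external
        resource (a foreign URI such as ``foaf:firstName``, or a literal
        name); in the latter case an external-resource record is created.
        """
        p = self._resolve(project)
        c = self._resolve(subject_collection)
        i = self._resolve(predicate_item)
        if isinstance(obj, Entity) or obj in self.entities:
            o = self._resolve(obj)
            if o.external:
                obj_is_collection = False
            elif o.kind is EntityKind.COLLECTION:
                obj_is_collection = True
            else:
                raise RangeViolation(
                    f"rule object must be a collection or external resource, "
                    f"got {o.kind.kind_name} {o.uri}")
        else:
            o = self.external_resource(obj)
            obj_is_collection = False
        rule_ent = self.create_entity(EntityKind.RULE, label, uri=uri,
                                      creator=creator)
        self.assert_relation(p, RelationKind.PR, rule_ent)
        self.assert_relation(c, RelationKind.RSUBJECT, rule_ent)
        self.assert_relation(i, RelationKind.RPREDICATE, rule_ent)
        self.assert_relation(o, RelationKind.ROBJECT, rule_ent)
        rule = Rule(uri=rule_ent.uri, subject_collection=c.uri,
                    predicate_item=i.uri, object=o.uri,
                    object_is_collection=obj_is_collection)
        self.rules[rule.uri] = rule
        return rule

    def add_statement(self, rule: Union[Rule, str],
                      subject_item: Union[Entity, str],
                      obj: Union[Entity, str], *,
                      uri: Optional[str] = None,
                      creator: Optional[str] = None) -> Statement:
        """Instantiate a rule with one observation.

        The subject must be an item of the rule's subject collection.  If the
        rule's object is a collection, ``obj`` must be an item of it;
        otherwise ``obj`` is stored as an opaque literal value.
        """
        r = rule if isinstance(rule, Rule) else self.rules[rule]
        s = self._resolve(subject_item)
        if s.kind is not EntityKind.ITEM:
            raise DomainViolation(
                f"statement subject must be an item, got "
                f"{s.kind.kind_name if s.kind else 'external'} {s.uri}")
        if not self.is_member(s, r.subject_collection):
            raise MembershipError(
                f"{s.uri} is not a CI-member of the rule's subject "
                f"collection {r.subject_collection}")
        obj_is_item = isinstance(obj, Entity) or (
            isinstance(obj, str) and obj in self.entities
            and not self.entities[obj].external)
        if r.object_is_collection:
            if not obj_is_item:
                raise ObjectTypeError(
                    f"rule {r.uri} has a collection object; the statement "
                    f"object must be an item, got literal {obj!r}")
            o = self._resolve(obj)
            if o.kind is not EntityKind.ITEM:
                raise ObjectTypeError(
                    f"statement object must be an item, got "
                    f"{o.kind.kind_name if o.kind else 'external'} {o.uri}")
            if not self.is_member(o, r.object):
                raise MembershipError(
                    f"{o.uri} is not a CI-member of the rule's object "
                    f"collection {r.object}")
            obj_value, is_item = o.uri, True
        else:
            if obj_is_item:
                raise ObjectTypeError(
                    f"rule {r.uri} has a non-collection object; the statement "
                    f"object must be a literal, got entity {self._resolve(obj).uri}")
            obj_value, is_item = str(obj), False
        stmt_ent = self.create_entity(EntityKind.STATEMENT, uri=uri,
                                      creator=creator)
        self.assert_relation(s, RelationKind.SSUBJECT, stmt_ent)
        self.assert_relation(self.entities[r.uri], RelationKind.SPREDICATE, stmt_ent)
        if is_item:
            self.assert_relation(self.entities[obj_value],
                                 RelationKind.SOBJECT, stmt_ent)
        stmt = Statement(uri=stmt_ent.uri, subject_item=s.uri, rule=r.uri,
                         object=obj_value, object_is_item=is_item)
        self.statements[stmt.uri] = stmt
        return stmt

    def update_rule_object(self, rule: Union[Rule, str], new_resource: str) -> Rule:
        """Re-point a rule's external object; dependent statements are untouched.

        Only non-collection objects can be edited: re-pointing a collection
        object would orphan the item objects of existing statements.
        """
        r = rule if isinstance(rule, Rule) else self.rules[rule]
        if r.object_is_collection:
            raise UnsupportedEditError(
                f"rule {r.uri} has a collection object; re-pointing it would "
                f"orphan the item objects of its statements")
        if new_resource == r.object:
            return r
        old = r.object
        self.relations.discard(
            RelationInstance(old, RelationKind.ROBJECT, r.uri))
        new_ent = self.external_resource(new_resource)
        self.assert_relation(new_ent, RelationKind.ROBJECT, r.uri)
        if not any(rl.object == old for rl in self.rules.values() if rl.uri != r.uri):
            # external record no longer referenced by any rule
            if old in self.entities and self.entities[old].external:
                del self.entities[old]
        new_rule = replace(r, object=new_resource)
        self.rules[r.uri] = new_rule
        logger.info("rule %s object re-pointed %r -> %r", r.uri, old, new_resource)
        return new_rule

    # -- assignments -------------------------------------------------------

    def assign(self, user: Union[Entity, str], target: Union[Entity, str],
               state: str, bundle: str = "default") -> Assignment:
        u, t = self._resolve(user), self._resolve(target)
        if u.kind is not EntityKind.USER:
            raise DomainViolation(f"assignment subject must be a user, got {u.uri}")
        a = Assignment(user=u.uri, target=t.uri, bundle=bundle, state=state)
        self.assignments.append(a)
        return a

    # -- deletion ----------------------------------------------------------

    def _dependents(self, uri: str) -> set[str]:
        deps: set[str] = set()
        for r in self.relations:
            if r.subject == uri:
                deps.add(r.object)
        for rl in self.rules.values():
            if uri in (rl.subject_collection, rl.predicate_item, rl.object):
                deps.add(rl.uri)
        for st in self.statements.values():
            if uri in (st.subject_item, st.rule) or (st.object_is_item and st.object == uri):
                deps.add(st.uri)
        deps.discard(uri)
        return deps

    def delete_entity(self, uri: str, *, cascade: bool = False) -> None:
        """Remove an entity; refuses while dependents exist unless ``cascade``."""
        self._resolve(uri)
        deps = self._dependents(uri)
        if deps and not cascade:
            raise DependentsExistError(
                f"{uri} has {len(deps)} dependents; pass cascade=True to remove")
        for d in sorted(deps):
            if d in self.entities:
                self.delete_entity(d, cascade=True)
        self.relations = {r for r in self.relations
                          if uri not in (r.subject, r.object)}
        self.rules.pop(uri, None)
        self.statements.pop(uri, None)
        self.assignments = [a for a in self.assignments
                            if uri not in (a.user, a.target)]
        self.entities.pop(uri, None)


def validate_store(store: Store) -> list[Violation]:
    """Check every core-model invariant; empty list means the store is valid.

    Errors cover domain/range typing, rule/statement structure, membership
    of statement endpoints, and the single-deployment root.  Predicate items
    that belong to no collection are reported as warnings only.
    """
    out: list[Violation] = []
    roots = [e for e in store.entities.values()
             if e.kind is EntityKind.DEPLOYMENT]
    if len(roots) > 1:
        out.append(Violation("E_DUP_ROOT", "error",
                             f"{len(roots)} deployment roots",
                             tuple(e.uri for e in roots)))
    elif not roots:
        out.append(Violation("E_NO_ROOT", "error", "store has no deployment root"))

    for ent in store.entities.values():
        if ent.creator is not None:
            cu = store.entities.get(ent.creator)
            if cu is None or cu.kind is not EntityKind.USER:
                out.append(Violation("E_CREATOR", "error",
                                     f"creator {ent.creator} of {ent.uri} is not "
                                     f"a user in the store", (ent.uri,)))

    for rel in store.relations:
        s = store.entities.get(rel.subject)
        o = store.entities.get(rel.object)
        if s is None or o is None:
            out.append(Violation("E_DANGLING", "error",
                                 f"relation {rel.relation.rel_name} references a "
                                 f"missing entity", (rel.subject, rel.object)))
            continue
        try:
            Store._check_typing(s, rel.relation, o)
        except DomainViolation as e:
            out.append(Violation("E_DOMAIN", "error", str(e),
                                 (rel.subject, rel.object)))
        except RangeViolation as e:
            out.append(Violation("E_RANGE", "error", str(e),
                                 (rel.subject, rel.object)))

    for rule in store.rules.values():
        for rel, end in ((RelationKind.RSUBJECT, rule.subject_collection),
                         (RelationKind.RPREDICATE, rule.predicate_item),
                         (RelationKind.ROBJECT, rule.object)):
            if RelationInstance(end, rel, rule.uri) not in store.relations:
                out.append(Violation("E_RULE_LINK", "error",
                                     f"rule {rule.uri} lacks its {rel.rel_name} "
                                     f"link from {end}", (rule.uri, end)))
        pred = store.entities.get(rule.predicate_item)
        if pred is None or pred.kind is not EntityKind.ITEM:
            out.append(Violation("E_DOMAIN", "error",
                                 f"rule {rule.uri} predicate "
                                 f"{rule.predicate_item} is not an item",
                                 (rule.uri,)))
        elif not any(r.relation is RelationKind.CI and r.object == pred.uri
                     for r in store.relations):
            out.append(Violation("W_PREDICATE_NO_COLLECTION", "warning",
                                 f"predicate item {pred.uri} belongs to no "
                                 f"collection", (pred.uri,)))
        obj = store.entities.get(rule.object)
        if rule.object_is_collection:
            if obj is None or obj.kind is not EntityKind.COLLECTION:
                out.append(Violation("E_RANGE", "error",
                                     f"rule {rule.uri} object {rule.object} is "
                                     f"not a collection", (rule.uri,)))
        elif obj is None or not obj.external:
            out.append(Violation("E_RANGE", "error",
                                 f"rule {rule.uri} external object "
                                 f"{rule.object} is not registered",
                                 (rule.uri,)))

    for stmt in store.statements.values():
        rule = store.rules.get(stmt.rule)
        if rule is None:
            out.append(Violation("E_STMT_RULE", "error",
                                 f"statement {stmt.uri} references missing rule "
                                 f"{stmt.rule}", (stmt.uri,)))
            continue
        if not store.is_member(stmt.subject_item, rule.subject_collection):
            out.append(Violation("E_MEMBERSHIP", "error",
                                 f"statement {stmt.uri} subject "
                                 f"{stmt.subject_item} is not a member of "
                                 f"{rule.subject_collection}",
                                 (stmt.uri, stmt.subject_item)))
        if rule.object_is_collection:
            if not stmt.object_is_item:
                out.append(Violation("E_OBJECT_TYPE", "error",
                                     f"statement {stmt.uri} holds a literal for "
                                     f"a collection-object rule", (stmt.uri,)))
            elif not store.is_member(stmt.object, rule.object):
                out.append(Violation("E_MEMBERSHIP", "error",
                                     f"statement {stmt.uri} object {stmt.object} "
                                     f"is not a member of {rule.object}",
                                     (stmt.uri, stmt.object)))
        elif stmt.object_is_item:
            out.append(Violation("E_OBJECT_TYPE", "error",
                                 f"statement {stmt.uri} holds an item for a "
                                 f"literal-object rule", (stmt.uri,)))
    return out


def build_mary_fixture(store: Store) -> Store:
    """Populate a fresh store with the worked 'Mary lives in Houston' example.

    Builds: project P_example; collections of people and places; items Mary,
    Houston, lives_in, has; the rule "people live in places" instantiated by
    the statement linking Mary to Houston; and the rule "people have names"
    whose object is the external resource ``foaf:firstName``, instantiated by
    a statement carrying the literal value "Mary".
    """
    if set(store.entities) - {store.deployment.uri if store.deployment else None}:
        raise FixtureCollisionError("fixture requires a fresh store")
    if store.deployment is None:
        store.create_entity(EntityKind.DEPLOYMENT)
    b = store.base_uri

    def u(name: str) -> str:
        return f"{b}/{name}"

    p = store.create_entity(EntityKind.PROJECT, "example", uri=u("P_example"))
    c_person = store.create_entity(EntityKind.COLLECTION, "person",
                                   uri=u("C_person"))
    c_places = store.create_entity(EntityKind.COLLECTION, "places",
                                   uri=u("C_places"))
    store.assert_relation(p, RelationKind.PC, c_person)
    store.assert_relation(p, RelationKind.PC, c_places)

    i_mary = store.create_entity(EntityKind.ITEM, "Mary", uri=u("I_Mary"))
    i_houston = store.create_entity(EntityKind.ITEM, "Houston",
                                    uri=u("I_Houston"))
    i_lives_in = store.create_entity(EntityKind.ITEM, "lives_in",
                                     uri=u("I_lives_in"))
    i_has = store.create_entity(EntityKind.ITEM, "has", uri=u("I_has"))
    store.assert_relation(c_person, RelationKind.CI, i_mary)
    store.assert_relation(c_places, RelationKind.CI, i_houston)

    r_lives = store.add_rule(p, c_person, i_lives_in, c_places,
                             label="people live in places",
                             uri=u("R_people_in_places"))
    r_names = store.add_rule(p, c_person, i_has, "foaf:firstName",
                             label="people have names",
                             uri=u("R_people_have_names"))
    store.add_statement(r_lives, i_mary, i_houston)
    store.add_statement(r_names, i_mary, "Mary")
    return store
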