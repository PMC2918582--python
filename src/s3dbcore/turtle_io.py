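"""Turtle/N3 serialization of stores.

Two styles are emitted:

* ``reified`` — the normative interchange dialect.  Every entity gets an
  ``rdf:type`` triple in the ``s3db:`` vocabulary, every relation instance
  one triple with its relationship-kind predicate (``s3db:CI``,
  ``s3db:Rsubject``, ...).  Literal rule objects are carried on the rule as
  ``s3db:RobjectLiteral`` and literal statement objects on the statement as
  ``s3db:SobjectLiteral``, since a bare name cannot be an RDF subject.
  Operator assignments are packed into one datatyped literal per assignment,
  ``<user> s3db:operator "bundle|state|target"^^s3db:assignment``.

* ``compact`` — additionally writes each statement the way a reader would:
  one triple whose predicate is the rule URI, e.g.
  ``:I_Mary :R_people_in_places :I_Houston`` or
  ``:I_Mary :R_people_have_names "Mary"``.  Compact triples are a derived
  convenience view; alone they could not round-trip statement URIs, so only
  the reified dialect is accepted on import.
"""

from __future__ import annotations

import logging
import re

from rdflib import Graph, Literal, Namespace, RDF, RDFS, OWL, URIRef

from .errors import ImportError_, S3DBError
from .model import (
    Assignment,
    Entity,
    EntityKind,
    RelationInstance,
    RelationKind,
    Rule,
    Statement,
    Store,
    validate_store,
)

logger = logging.getLogger(__name__)

#: Placeholder vocabulary namespace (the published schema gives none).
S3DB_NS = "http://s3db.example.org/core#"
S3DB = Namespace(S3DB_NS)

#: Well-known external prefixes expanded on export and contracted on import.
PREFIXES = {
    "foaf": "http://xmlns.com/foaf/0.1/",
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "owl": str(OWL),
}

_CURIE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9+.\-]*):(\S+)$")


def _expand(ref: str):
    """Map an external ref to an RDF node: URIRef when URI-like, else None."""
    m = _CURIE_RE.match(ref)
    if not m:
        return None
    prefix, local = m.groups()
    if prefix in PREFIXES:
        return URIRef(PREFIXES[prefix] + local)
    return URIRef(ref)


def _contract(uri: str) -> str:
    for prefix, base in PREFIXES.items():
        if uri.startswith(base):
            return f"{prefix}:{uri[len(base):]}"
    return uri


def to_graph(store: Store, style: str = "reified") -> Graph:
    """Build the rdflib graph for a store in the given style."""
    if style not in ("reified", "compact"):
        raise S3DBError(f"unknown export style {style!r}")
    g = Graph()
    g.bind("s3db", S3DB)
    g.bind("foaf", PREFIXES["foaf"])
    g.bind("owl", OWL)
    g.bind("", Namespace(store.base_uri + "/"))

    dep = store.deployment
    if dep is not None:
        g.add((URIRef(dep.uri), S3DB.baseURI, Literal(store.base_uri)))

    for ent in store.entities.values():
        if ent.external:
            continue
        node = URIRef(ent.uri)
        g.add((node, RDF.type, S3DB[ent.kind.kind_name]))
        if ent.label is not None:
            g.add((node, RDFS.label, Literal(ent.label)))
        if ent.creator is not None:
            g.add((node, S3DB.createdBy, URIRef(ent.creator)))

    for rel in store.relations:
        subj_ent = store.entities.get(rel.subject)
        if subj_ent is not None and subj_ent.external:
            node = _expand(rel.subject)
            if node is None:
                continue  # literal-named external: carried as RobjectLiteral
            g.add((node, S3DB[rel.relation.rel_name], URIRef(rel.object)))
        else:
            g.add((URIRef(rel.subject), S3DB[rel.relation.rel_name],
                   URIRef(rel.object)))

    for rule in store.rules.values():
        if not rule.object_is_collection and _expand(rule.object) is None:
            g.add((URIRef(rule.uri), S3DB.RobjectLiteral, Literal(rule.object)))

    for stmt in store.statements.values():
        if not stmt.object_is_item:
            g.add((URIRef(stmt.uri), S3DB.SobjectLiteral, Literal(stmt.object)))

    for a in store.assignments:
        payload = f"{a.bundle}|{a.state}|{a.target}"
        g.add((URIRef(a.user), S3DB.operator,
               Literal(payload, datatype=S3DB.assignment)))

    if style == "compact":
        for stmt in store.statements.values():
            obj = (URIRef(stmt.object) if stmt.object_is_item
                   else Literal(stmt.object))
            g.add((URIRef(stmt.subject_item), URIRef(stmt.rule), obj))
    return g


def export_turtle(store: Store, style: str = "reified") -> str:
    """Serialize a store to Turtle text."""
    g = to_graph(store, style)
    if len(g) == 0:
        # rdflib drops unused prefixes; an empty store still documents them
        return "".join(f"@prefix {p}: <{ns}> .\n"
                       for p, ns in sorted(g.namespaces()))
    return g.serialize(format="turtle")


_REL_BY_NAME = {rk.rel_name: rk for rk in RelationKind}
_KIND_BY_NAME = {k.kind_name: k for k in EntityKind}


def import_turtle(source: str | None = None, *, data: str | None = None,
                  strict: bool = False) -> Store:
    """Reconstruct a store from a reified-dialect Turtle document.

    Triples violating the core-model typing raise an import error listing
    the offenders.  Unknown predicates and foreign (non-vocabulary) triples
    are skipped with a warning — their objects become external-resource
    records — unless ``strict`` is set, in which case they are errors too.
    """
    g = Graph()
    if data is not None:
        g.parse(data=data, format="turtle")
    elif source is not None:
        g.parse(source, format="turtle")
    else:
        raise S3DBError("import_turtle needs a path or data")

    deployments = list(g.subjects(RDF.type, S3DB.deployment))
    if len(deployments) != 1:
        raise ImportError_(
            f"document must declare exactly one s3db:deployment, found "
            f"{len(deployments)}", offenders=[str(d) for d in deployments])
    dep_uri = str(deployments[0])
    base = g.value(deployments[0], S3DB.baseURI)
    base_uri = str(base) if base is not None else dep_uri.rsplit("/", 1)[0]

    store = Store(base_uri)
    offenders: list[str] = []

    # pass 1: typed entities
    typed: dict[str, EntityKind] = {}
    for s, o in g.subject_objects(RDF.type):
        kind_name = str(o)[len(S3DB_NS):] if str(o).startswith(S3DB_NS) else None
        if kind_name in _KIND_BY_NAME:
            typed[str(s)] = _KIND_BY_NAME[kind_name]
        elif strict:
            offenders.append(f"{s} rdf:type {o}")
        else:
            logger.warning("skipping unknown type %s for %s", o, s)
    for uri, kind in sorted(typed.items(), key=lambda kv: kv[1].ordinal):
        node = URIRef(uri)
        label = g.value(node, RDFS.label)
        creator = g.value(node, S3DB.createdBy)
        store.create_entity(kind, str(label) if label is not None else None,
                            uri=uri,
                            creator=str(creator) if creator is not None else None)

    # pass 2: relation instances
    for s, p, o in g:
        pred = str(p)
        if not pred.startswith(S3DB_NS):
            if pred in (str(RDF.type), str(RDFS.label)):
                continue
            msg = f"foreign triple {s} {p} {o}"
            if strict:
                offenders.append(msg)
            else:
                logger.warning("%s: object kept as external resource", msg)
                if isinstance(o, URIRef) and _contract(str(o)) not in store.entities:
                    store.external_resource(_contract(str(o)))
            continue
        name = pred[len(S3DB_NS):]
        if name in ("baseURI", "createdBy", "RobjectLiteral", "SobjectLiteral",
                    "operator"):
            continue
        if name not in _REL_BY_NAME:
            msg = f"unknown vocabulary predicate s3db:{name}"
            if strict:
                offenders.append(msg)
            else:
                logger.warning("%s: skipped", msg)
            continue
        rel = _REL_BY_NAME[name]
        subj_uri = _contract(str(s))
        if subj_uri not in store.entities:
            store.external_resource(subj_uri)
        try:
            store.assert_relation(subj_uri, rel, str(o))
        except S3DBError as e:
            offenders.append(f"{subj_uri} s3db:{name} {o}: {e}")

    if offenders:
        raise ImportError_(
            f"{len(offenders)} triples violate the core-model typing",
            offenders=offenders)

    # pass 3: rules and statements from their reified links
    for ent in list(store.entities.values()):
        if ent.kind is EntityKind.RULE:
            node = URIRef(ent.uri)
            subj = _one_incoming(store, ent.uri, RelationKind.RSUBJECT)
            pred = _one_incoming(store, ent.uri, RelationKind.RPREDICATE)
            lit = g.value(node, S3DB.RobjectLiteral)
            if lit is not None:
                store.external_resource(str(lit))
                store.relations.add(
                    RelationInstance(str(lit), RelationKind.ROBJECT, ent.uri))
                obj, is_coll = str(lit), False
            else:
                obj = _one_incoming(store, ent.uri, RelationKind.ROBJECT)
                is_coll = (obj is not None and obj in store.entities
                           and not store.entities[obj].external)
            if None in (subj, pred, obj):
                raise ImportError_(
                    f"rule {ent.uri} is missing subject/predicate/object links",
                    offenders=[ent.uri])
            store.rules[ent.uri] = Rule(
                uri=ent.uri, subject_collection=subj, predicate_item=pred,
                object=obj, object_is_collection=is_coll)
    for ent in list(store.entities.values()):
        if ent.kind is EntityKind.STATEMENT:
            node = URIRef(ent.uri)
            subj = _one_incoming(store, ent.uri, RelationKind.SSUBJECT)
            rule = _one_incoming(store, ent.uri, RelationKind.SPREDICATE)
            lit = g.value(node, S3DB.SobjectLiteral)
            if lit is not None:
                obj, is_item = str(lit), False
            else:
                obj = _one_incoming(store, ent.uri, RelationKind.SOBJECT)
                is_item = True
            if None in (subj, rule, obj):
                raise ImportError_(
                    f"statement {ent.uri} is missing subject/predicate/object "
                    f"links", offenders=[ent.uri])
            store.statements[ent.uri] = Statement(
                uri=ent.uri, subject_item=subj, rule=rule, object=obj,
                object_is_item=is_item)

    # pass 4: assignments
    for s, o in g.subject_objects(S3DB.operator):
        parts = str(o).split("|", 2)
        if len(parts) != 3:
            raise ImportError_(f"malformed assignment literal {o}",
                               offenders=[str(o)])
        bundle, state, target = parts
        store.assignments.append(Assignment(
            user=str(s), target=target, bundle=bundle, state=state))

    # keep sequential minting clear of imported URIs
    pat = re.compile(re.escape(store.base_uri) + r"/([A-Z])(\d+)$")
    for uri in store.entities:
        m = pat.match(uri)
        if m:
            for kind in EntityKind:
                if kind.initial == m.group(1):
                    store._counters[kind] = max(store._counters[kind],
                                                int(m.group(2)))

    errors = [v for v in validate_store(store) if v.severity == "error"]
    if errors:
        raise ImportError_(
            f"imported store violates {len(errors)} core-model invariants",
            offenders=[f"{v.code}: {v.message}" for v in errors])
    return store


def _one_incoming(store: Store, target: str, rel: RelationKind):
    for r in store.relations:
        if r.relation is rel and r.object == target:
            return r.subject
    return None


def store_to_dict(store: Store) -> dict:
    """Plain-JSON dump of a store (entities, relations, rules, statements,
    assignments)."""
    return {
        "base_uri": store.base_uri,
        "entities": [
            {"uri": e.uri,
             "kind": e.kind.kind_name if e.kind else None,
             "label": e.label, "creator": e.creator, "external": e.external}
            for e in sorted(store.entities.values(), key=lambda e: e.uri)],
        "relations": [
            {"subject": r.subject, "relation": r.relation.rel_name,
             "object": r.object}
            for r in sorted(store.relations,
                            key=lambda r: (r.relation.index, r.subject, r.object))],
        "rules": [vars(r) | {} for r in
                  sorted(store.rules.values(), key=lambda r: r.uri)],
        "statements": [vars(s) | {} for s in
                       sorted(store.statements.values(), key=lambda s: s.uri)],
        "assignments": [vars(a) | {} for a in store.assignments],
    }
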