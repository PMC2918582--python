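"""Fixed-point percolation of operator states over instance graphs.

States assigned to an entity migrate along every relationship instance whose
(domain kind, range kind) cell is true in a Boolean transition matrix — for
the stock model, from the domain description down to its instantiation
(deployment to projects and users, projects to collections and rules,
collections to their items and to the rules they subject/object, items to
the rules they predicate and to the statements they subject/object, rules to
their statements, and users to users).  Percolation repeats migration until
no entity's pooled states change; the effective state of each entity is then
the merge of the first-tuple symbols of everything pooled there.

Pools keep the full set of migrated strings rather than collapsing them to a
merged symbol at each step: plural strings are depth-indexed (tuple i
governs depth-i descendants) and premature merging would destroy that.  The
two readings agree on the effective states at the fixed point for singular
states.

Termination: every pooled string is a suffix of whole m-tuples of some
finitely-many assignment strings, and a fully migrated (length-m) string
migrates to itself, so set-closure is reached on every finite store — cycles
(user-to-user links) included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np

from .errors import ConfigError, S3DBError
from .model import EntityKind, RelationKind, Store
from .states import (
    OperatorBundle,
    StateString,
    StateSymbol,
    default_bundle,
    merge,
    migrate,
    normalize,
    parse_state_string,
)

logger = logging.getLogger(__name__)

#: Sentinel for "no state reached this entity".
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TransitionMatrix:
    """A Boolean kind-by-kind mask saying which relationship directions
    carry state migration, with per-cell provenance (the relationship
    indexes licensing each true cell).

    Generic over any ordered kind alphabet: a different core model only
    needs a different matrix, the propagation machinery is unchanged.
    """

    kinds: tuple
    cells: tuple  # row-major tuple of tuples of bool
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        k = len(self.kinds)
        if any(len(row) != k for row in self.cells) or len(self.cells) != k:
            raise S3DBError("transition matrix must be square over its kinds")

    @property
    def size(self) -> int:
        return len(self.kinds)

    def as_array(self) -> np.ndarray:
        return np.array(self.cells, dtype=bool)

    def _idx(self, kind) -> int:
        try:
            return self.kinds.index(kind)
        except ValueError:
            raise S3DBError(f"kind {kind!r} not in matrix alphabet") from None

    def allows(self, domain_kind, range_kind) -> bool:
        return self.cells[self._idx(domain_kind)][self._idx(range_kind)]

    def licensing(self, domain_kind, range_kind) -> tuple[int, ...]:
        return self.provenance.get((domain_kind, range_kind), ())

    @classmethod
    def from_edges(cls, kinds: Sequence, edges: Iterable[tuple]) -> "TransitionMatrix":
        """Build from (domain, range, licence-index) triples."""
        kinds = tuple(kinds)
        k = len(kinds)
        grid = [[False] * k for _ in range(k)]
        prov: dict = {}
        for d, r, idx in edges:
            grid[kinds.index(d)][kinds.index(r)] = True
            prov.setdefault((d, r), [])
            prov[(d, r)].append(idx)
        prov = {key: tuple(sorted(v)) for key, v in prov.items()}
        return cls(kinds=kinds, cells=tuple(tuple(row) for row in grid),
                   provenance=prov)


def s3db_transition_matrix() -> TransitionMatrix:
    """The stock 7x7 matrix over [D, P, C, R, I, S, U], derived directly
    from the twelve relationship kinds' domain/range pairs."""
    kinds = EntityKind.canonical_order()
    edges = [(rk.domain_kind, rk.range_kind, rk.index) for rk in RelationKind]
    return TransitionMatrix.from_edges(kinds, edges)


def instance_graph(store: Store,
                   matrix: Optional[TransitionMatrix] = None) -> nx.DiGraph:
    """Directed graph over entity URIs with an edge for every relation
    instance whose kind-level cell is true in the matrix.  External
    resources carry no states and are excluded."""
    if matrix is None:
        matrix = s3db_transition_matrix()
    g = nx.DiGraph()
    for ent in store.entities.values():
        if not ent.external:
            g.add_node(ent.uri)
    for rel in store.relations:
        s = store.entities.get(rel.subject)
        o = store.entities.get(rel.object)
        if s is None or o is None or s.external or o.external:
            continue
        if matrix.allows(rel.relation.domain_kind, rel.relation.range_kind):
            g.add_edge(rel.subject, rel.object)
    return g


class StatePool:
    """Per-entity sets of pooled state strings for one (user, bundle) run."""

    def __init__(self, bundle: OperatorBundle):
        self.bundle = bundle
        self._pool: dict[str, set[StateString]] = {}

    def add(self, uri: str, s: StateString) -> bool:
        bucket = self._pool.setdefault(uri, set())
        if s in bucket:
            return False
        bucket.add(s)
        return True

    def strings_at(self, uri: str) -> frozenset[StateString]:
        return frozenset(self._pool.get(uri, ()))

    def texts_at(self, uri: str) -> frozenset[str]:
        return frozenset(s.text(self.bundle) for s in self.strings_at(uri))

    def entities(self) -> tuple[str, ...]:
        return tuple(sorted(u for u, b in self._pool.items() if b))

    def as_dict(self) -> dict[str, list[str]]:
        return {u: sorted(self.texts_at(u)) for u in self.entities()}

    def __eq__(self, other) -> bool:
        if not isinstance(other, StatePool):
            return NotImplemented
        mine = {u: b for u, b in self._pool.items() if b}
        theirs = {u: b for u, b in other._pool.items() if b}
        return mine == theirs

    def __len__(self) -> int:
        return sum(len(b) for b in self._pool.values())


def _uu_spread_assignments(store: Store, bundle: OperatorBundle,
                           user: str) -> list[tuple[str, StateString]]:
    """Migrate other users' assignments to ``user`` along user-to-user links.

    User-to-user links form their own percolation problem: a linked user's
    (target, state) assignments migrate hop by hop toward the requesting
    user, the string shedding one m-tuple per hop exactly as over entity
    edges.  Disabled by default; the stock configuration does not propagate
    between users.
    """
    m = bundle.m
    uu = nx.DiGraph()
    users = [e.uri for e in store.entities.values()
             if e.kind is EntityKind.USER]
    uu.add_nodes_from(users)
    for rel in store.relations:
        if rel.relation is RelationKind.UU:
            uu.add_edge(rel.subject, rel.object)
    # pools of (target, string) per user, closed under UU migration
    pools: dict[str, set[tuple[str, StateString]]] = {u: set() for u in users}
    work: list[str] = []
    for a in store.assignments:
        if a.user in pools:
            s = normalize(parse_state_string(a.state, bundle), m)
            if (a.target, s) not in pools[a.user]:
                pools[a.user].add((a.target, s))
                work.append(a.user)
    while work:
        u = work.pop()
        for v in uu.successors(u):
            for target, s in list(pools[u]):
                t = migrate(s, m)
                if (target, t) not in pools[v]:
                    pools[v].add((target, t))
                    work.append(v)
    return sorted(pools.get(user, ()),
                  key=lambda p: (p[0], p[1].text(bundle)))


def percolate(store: Store, user: str,
              bundle: Optional[OperatorBundle] = None,
              matrix: Optional[TransitionMatrix] = None, *,
              enable_uu: bool = False,
              edge_order: Optional[Sequence[tuple[str, str]]] = None) -> StatePool:
    """Propagate one user's assigned states to the fixed point.

    Pools start from the user's (normalized) assignment strings at their
    targets; every instance-graph edge then carries one-step migrations of
    everything pooled at its source, repeated to set-closure.  The result is
    independent of edge processing order (``edge_order`` exists to let tests
    demonstrate that confluence).
    """
    if bundle is None:
        bundle = default_bundle()
    if matrix is None:
        matrix = s3db_transition_matrix()
    m = bundle.m
    g = instance_graph(store, matrix)
    pool = StatePool(bundle)

    if enable_uu:
        seeds = _uu_spread_assignments(store, bundle, user)
    else:
        seeds = [(a.target, normalize(parse_state_string(a.state, bundle), m))
                 for a in store.assignments if a.user == user]
    for target, s in seeds:
        pool.add(target, s)

    edges = list(edge_order) if edge_order is not None else list(g.edges())
    iterations = 0
    changed = True
    while changed:
        changed = False
        iterations += 1
        for u, v in edges:
            for s in list(pool.strings_at(u)):
                if pool.add(v, migrate(s, m)):
                    changed = True
    logger.info("percolated user=%s: %d entities, %d iterations, %d pooled "
                "strings", user, len(pool.entities()), iterations, len(pool))
    return pool


def effective_state(pool: StatePool, entity: str,
                    bundle: Optional[OperatorBundle] = None,
                    operator_index: int = 1) -> Union[StateSymbol, str]:
    """Merge operator j's first-tuple symbols over everything pooled at
    ``entity``; returns :data:`UNASSIGNED` on an empty pool."""
    if bundle is None:
        bundle = pool.bundle
    j = operator_index
    if not 1 <= j <= bundle.m:
        raise ConfigError(f"operator index {j} out of range 1..{bundle.m}")
    strings = pool.strings_at(entity)
    if not strings:
        return UNASSIGNED
    return merge(s[j - 1] for s in strings)


def is_allowed(store: Store, pool: StatePool, user: str, entity: str,
               operator_name: str) -> bool:
    """Map the effective permission state to an allow/deny decision.

    Index 1 ('all') allows, index 3 ('none') denies, index 2 ('self')
    allows only on entities the requesting user created.  An unassigned
    entity falls back to the bundle's configured default (deny unless the
    bundle says otherwise).
    """
    bundle = pool.bundle
    j = bundle.operator_index(operator_name)
    eff = effective_state(pool, entity, bundle, j)
    if eff == UNASSIGNED:
        return bundle.default_allow
    if eff.index == 1:
        return True
    if eff.index == 2:
        ent = store.entities.get(entity)
        return ent is not None and ent.creator == user
    return False
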