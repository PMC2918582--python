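"""Shared fixtures and the independent brute-force percolation oracle."""

from __future__ import annotations

from collections import defaultdict

import networkx as nx
import pytest

from s3dbcore import (
    OperatorBundle,
    OperatorSpec,
    Store,
    build_mary_fixture,
    instance_graph,
    migrate,
    normalize,
    parse_state_string,
)

BASE = "http://example.org/deploy"


@pytest.fixture
def fresh_store() -> Store:
    return Store.new(BASE)


@pytest.fixture
def mary_store() -> Store:
    return build_mary_fixture(Store.new(BASE))


@pytest.fixture
def bcd_bundle() -> OperatorBundle:
    """Single operator whose three states use the letters b, c, d."""
    spec = OperatorSpec("f", ("s1", "s2", "s3"), ("b", "c", "d"))
    return OperatorBundle((spec,))


def oracle_pools(store: Store, user: str, bundle: OperatorBundle) -> dict:
    """Path-enumeration oracle for percolation, independent of the worklist
    implementation.

    For each assignment, enumerate walk lengths k = 0, 1, 2, ... from the
    target: every node reachable by a walk of exactly k edges pools the
    k-times-migrated string.  Once the string is fully migrated (one tuple
    per operator) it migrates to itself, so every descendant of the nodes at
    that last distinct depth pools the terminal string — which bounds the
    enumeration on cyclic graphs.
    """
    g = instance_graph(store)
    m = bundle.m
    pools: dict[str, set] = defaultdict(set)
    for a in store.assignments:
        if a.user != user:
            continue
        s = normalize(parse_state_string(a.state, bundle), m)
        stages = [s]
        while len(stages[-1]) > m:
            stages.append(migrate(stages[-1], m))
        frontier = {a.target}
        for k, stage in enumerate(stages):
            for node in frontier:
                pools[node].add(stage)
            if k == len(stages) - 1:
                break
            frontier = set().union(
                *(set(g.successors(n)) for n in frontier)) if frontier else set()
        terminal = stages[-1]
        for node in frontier:
            for desc in nx.descendants(g, node):
                pools[desc].add(terminal)
    return {u: b for u, b in pools.items() if b}
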