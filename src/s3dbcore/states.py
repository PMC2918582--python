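"""Dominant/recessive operator states: the merge and migrate primitives.

An *operator* is a discrete variable with n ordered states describing the
relationship between a user and an entity (e.g. a "view" permission with
states all/self/none).  Each state can be asserted in a dominant form
(upper-case symbol) or a recessive form (lower-case symbol).  Dominance
matters only when several assigned states are *merged* into one effective
state; the operator itself responds to the state's position in the ordered
alphabet, not to its case.

Merge resolution: if any dominant state is assigned, the dominant state of
minimum index wins; otherwise the recessive state of maximum index wins.
With index 1 the most permissive state, recessive assignments therefore
combine restrictively, while a dominant assignment can override them — and
among dominants the most permissive one prevails.

Migration passes states along licensed edges of the instance graph.  A
*plural* state string packs several m-tuples (m = number of operators
sharing the alphabet): the first tuple is the effective state at the source
and only the remaining tuples are passed on; a singular (length-m) string
passes unchanged.  A string whose length is not a multiple of m is completed
by borrowing each missing symbol from the operator immediately to its left,
i.e. by repeating the last given symbol.
"""

from __future__ import annotations

import string as _string
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import yaml

from .errors import ConfigError, MergeUndefinedError, S3DBError, StateParseError


@dataclass(frozen=True)
class StateSymbol:
    """One state of an operator: a 1-based index plus a dominance flag.

    Two symbols denote the same *state* iff their indexes are equal; the
    case/dominance flag only steers merge resolution.
    """

    index: int
    dominant: bool = False

    def same_state(self, other: "StateSymbol") -> bool:
        return self.index == other.index


@dataclass(frozen=True)
class OperatorSpec:
    """A named operator over an ordered alphabet of n states.

    ``letters`` holds the lower-case (recessive) symbol for each state, in
    index order; the upper-case form is the dominant variant of the same
    state.
    """

    name: str
    states: tuple[str, ...]
    letters: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.states:
            raise ConfigError(f"operator {self.name!r} needs at least one state")
        letters = self.letters or tuple(_string.ascii_lowercase[: len(self.states)])
        object.__setattr__(self, "letters", letters)
        if len(self.letters) != len(self.states):
            raise ConfigError(
                f"operator {self.name!r}: {len(self.letters)} letters for "
                f"{len(self.states)} states")
        low = [c.lower() for c in self.letters]
        if len(set(low)) != len(low) or any(len(c) != 1 for c in low):
            raise ConfigError(
                f"operator {self.name!r}: symbols must be unique single "
                f"characters ignoring case")

    @property
    def n(self) -> int:
        return len(self.states)

    def symbol(self, char: str) -> StateSymbol:
        try:
            idx = self.letters.index(char.lower()) + 1
        except ValueError:
            raise StateParseError(
                f"{char!r} not in alphabet {''.join(self.letters)!r}") from None
        return StateSymbol(index=idx, dominant=char.isupper())

    def char(self, sym: StateSymbol) -> str:
        if not 1 <= sym.index <= self.n:
            raise S3DBError(f"state index {sym.index} out of range 1..{self.n}")
        c = self.letters[sym.index - 1]
        return c.upper() if sym.dominant else c

    def label(self, sym: StateSymbol) -> str:
        return self.states[sym.index - 1]


@dataclass(frozen=True)
class OperatorBundle:
    """m operators sharing one ordered state alphabet.

    Sharing the alphabet is what makes the vectorized m-tuple migration
    meaningful: a single state string spans all m operators, tuple position
    j belonging to operator j.
    """

    operators: tuple[OperatorSpec, ...]
    default_allow: bool = False  # decision when no state reaches an entity

    def __post_init__(self):
        if not self.operators:
            raise ConfigError("bundle needs at least one operator")
        first = self.operators[0]
        for op in self.operators[1:]:
            if op.letters != first.letters or op.n != first.n:
                raise ConfigError(
                    "all operators in a bundle must share one state alphabet")

    @property
    def m(self) -> int:
        return len(self.operators)

    @property
    def alphabet(self) -> OperatorSpec:
        return self.operators[0]

    def operator_index(self, name: str) -> int:
        """1-based position of the named operator."""
        for j, op in enumerate(self.operators, start=1):
            if op.name == name:
                return j
        raise ConfigError(f"no operator named {name!r} in bundle")

    @classmethod
    def generic(cls, m: int = 1, n: int = 4) -> "OperatorBundle":
        """An anonymous bundle with alphabet a, b, c, ... — handy for tests."""
        spec = OperatorSpec(name="f", states=tuple(f"s{i}" for i in range(1, n + 1)))
        ops = tuple(
            OperatorSpec(name=f"f{j}", states=spec.states, letters=spec.letters)
            for j in range(1, m + 1))
        return cls(operators=ops)


class StateString(tuple):
    """An immutable sequence of :class:`StateSymbol` of length >= 1."""

    def __new__(cls, symbols: Iterable[StateSymbol]):
        syms = tuple(symbols)
        if not syms:
            raise StateParseError("state string must have length >= 1")
        return super().__new__(cls, syms)

    def text(self, bundle: OperatorBundle) -> str:
        return "".join(bundle.alphabet.char(s) for s in self)


def parse_state_string(text: str, bundle: OperatorBundle) -> StateString:
    """Map each character of ``text`` to a state symbol of the bundle's alphabet."""
    if not text:
        raise StateParseError("state string must have length >= 1")
    syms = []
    for pos, ch in enumerate(text, start=1):
        try:
            syms.append(bundle.alphabet.symbol(ch))
        except StateParseError:
            raise StateParseError(
                f"unknown state symbol {ch!r} at position {pos}",
                position=pos) from None
    return StateString(syms)


def merge(assigned: Iterable[StateSymbol]) -> StateSymbol:
    """Resolve a set of assigned states to one effective state.

    Any dominant assignment overrides all recessive ones, and among dominant
    states the minimum index (most permissive) wins; among purely recessive
    states the maximum index (most restrictive) wins.  The winning symbol's
    case is preserved so that merged results can feed further merges.
    Order-independent by construction.
    """
    syms = list(assigned)
    if not syms:
        raise MergeUndefinedError("merge over an empty state set is undefined")
    dominants = [s for s in syms if s.dominant]
    if dominants:
        return min(dominants, key=lambda s: s.index)
    return max(syms, key=lambda s: s.index)


def normalize(s: StateString, m: int) -> StateString:
    """Right-pad ``s`` by repeating its last symbol until its length is a
    multiple of m (left-borrowing: an unspecified operator position takes the
    symbol of the operator immediately to its left)."""
    if m < 1:
        raise S3DBError(f"operator count m must be >= 1, got {m}")
    syms = list(s)
    while len(syms) % m != 0:
        syms.append(syms[-1])
    return StateString(syms)


def migrate(s: StateString, m: int = 1) -> StateString:
    """Pass a state string one step along a licensed edge.

    After normalization to whole m-tuples, a singular string (one tuple per
    operator) migrates unchanged; a plural string leaves its first m-tuple
    behind — it is the effective state at the source — and only the
    remaining tuples move on.  Operator j's migrating subsequence is thus
    positions j, j+m, j+2m, ... of the normalized string.
    """
    s = normalize(s, m)
    if len(s) == m:
        return s
    return StateString(s[m:])


def migrate_text(text: str, m: int = 1,
                 bundle: Optional[OperatorBundle] = None) -> str:
    """Convenience wrapper: migrate a textual state string, e.g.
    ``migrate_text('abcb', 3) == 'bbb'``."""
    if bundle is None:
        bundle = OperatorBundle.generic(m=m, n=26)
    return migrate(parse_state_string(text, bundle), m).text(bundle)


# --- the stock permission configuration -----------------------------------

#: Ordered permission states, index 1 the most permissive.  The prototype
#: this models calls them none/self/all in one place and yes/self/no in
#: another; display names are configurable, indexes are canonical.
PERMISSION_STATES = ("all", "self", "none")
PERMISSION_LETTERS = ("a", "s", "n")


def default_bundle(*, default_allow: bool = False) -> OperatorBundle:
    """The stock View/Edit/Use permission bundle: three operators sharing
    the three ordered states (all, self, none) = indexes (1, 2, 3)."""
    ops = tuple(
        OperatorSpec(name=name, states=PERMISSION_STATES,
                     letters=PERMISSION_LETTERS)
        for name in ("view", "edit", "use"))
    return OperatorBundle(operators=ops, default_allow=default_allow)


def bundle_to_dict(bundle: OperatorBundle) -> dict:
    return {
        "letters": list(bundle.alphabet.letters),
        "default_decision": "allow" if bundle.default_allow else "deny",
        "operators": [{"name": op.name, "states": list(op.states)}
                      for op in bundle.operators],
    }


def bundle_from_dict(data: dict) -> OperatorBundle:
    try:
        letters = tuple(data.get("letters", ()))
        ops = tuple(
            OperatorSpec(name=o["name"], states=tuple(o["states"]),
                         letters=letters)
            for o in data["operators"])
        default_allow = data.get("default_decision", "deny") == "allow"
    except (KeyError, TypeError) as e:
        raise ConfigError(f"malformed bundle configuration: {e}") from None
    return OperatorBundle(operators=ops, default_allow=default_allow)


def load_bundle(path: str) -> OperatorBundle:
    """Read an operator-bundle configuration from a YAML (or JSON) file."""
    with open(path) as fh:
        return bundle_from_dict(yaml.safe_load(fh))


def save_bundle(bundle: OperatorBundle, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(bundle_to_dict(bundle), fh, sort_keys=False)
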