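"""Error hierarchy with machine-readable codes.

Every validation failure carries a stable ``code`` string so callers (and the
CLI) can branch on the violated constraint rather than on message text.
"""

from __future__ import annotations


class S3DBError(Exception):
    """Base class for all errors raised by this package."""

    code: str = "E_GENERIC"

    def __init__(self, message: str, *, code: str | None = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class DomainViolation(S3DBError):
    """Relation subject has the wrong entity kind for its relationship."""

    code = "E_DOMAIN"


class RangeViolation(S3DBError):
    """Relation object has the wrong entity kind for its relationship."""

    code = "E_RANGE"


class MembershipError(S3DBError):
    """A statement endpoint is not a member of the required collection."""

    code = "E_MEMBERSHIP"


class ObjectTypeError(S3DBError):
    """Statement object is a literal where an item is required, or vice versa."""

    code = "E_OBJECT_TYPE"


class DuplicateRootError(S3DBError):
    """A store may hold exactly one deployment entity."""

    code = "E_DUP_ROOT"


class UnsupportedEditError(S3DBError):
    """The requested edit would corrupt instantiated data and is refused."""

    code = "E_EDIT_UNSUPPORTED"


class DependentsExistError(S3DBError):
    """Deletion refused while dependent entities or relations remain."""

    code = "E_HAS_DEPENDENTS"


class StateParseError(S3DBError):
    """A state string contains a character outside the operator alphabet."""

    code = "E_PARSE"

    def __init__(self, message: str, *, position: int | None = None):
        super().__init__(message)
        self.position = position


class MergeUndefinedError(S3DBError):
    """merge() over an empty set; callers map this to 'unassigned'."""

    code = "E_MERGE_EMPTY"


class ConfigError(S3DBError):
    """Malformed operator-bundle configuration or unknown operator name."""

    code = "E_CONFIG"


class GeneratorParameterError(S3DBError):
    """Impossible synthetic-store shape (e.g. statements without rules)."""

    code = "E_PARAMS"


class ImportError_(S3DBError):
    """Turtle document violates the core-model typing on import."""

    code = "E_IMPORT"

    def __init__(self, message: str, *, offenders: list | None = None):
        super().__init__(message)
        self.offenders = offenders or []


class FixtureCollisionError(S3DBError):
    """Worked-example fixture requested on a non-fresh store."""

    code = "E_FIXTURE_COLLISION"
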