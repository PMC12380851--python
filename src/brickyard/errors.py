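"""Typed error hierarchy.

Every error carries an ``exit_code`` so the CLI can map failures onto its
documented exit-code contract: 2 user error, 3 registry error, 4 integrity
error.
"""

from __future__ import annotations


class BrickyardError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class UserError(BrickyardError):
    """Bad input from the user: malformed refs, config, dependency files."""

    exit_code = 2


class BrickParseError(UserError):
    """A brick reference string could not be parsed."""


class DependencyFileError(UserError):
    """A dependency file is malformed; message names the line number."""


class ManifestError(UserError):
    """An asset manifest violates its invariants."""


class CollisionError(UserError):
    """Two distinct commits share a 5-char library path prefix."""


class RegistryError(BrickyardError):
    """Failures talking to a registry backend."""

    exit_code = 3


class BrickNotFoundError(RegistryError):
    """The requested brick does not exist in the searched registry."""


class AuthError(RegistryError):
    """The backend requires a token and none was configured."""


class UnresolvedDependencyError(RegistryError):
    """A transitive dependency could not be resolved; message names the chain."""


class CycleError(RegistryError):
    """The dependency graph contains a cycle."""


class IntegrityError(BrickyardError):
    """Content does not hash to its recorded key."""

    exit_code = 4


class TamperError(IntegrityError):
    """Brick metadata does not match its commit fingerprint."""


class MissingObjectError(IntegrityError):
    """A content key is absent from the store or object pool."""
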