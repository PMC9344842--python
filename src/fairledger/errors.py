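"""Exception hierarchy for the platform."""

from __future__ import annotations


class FairledgerError(Exception):
    """Base class for all package errors."""

    kind = "error"


class SchemaError(FairledgerError):
    """Malformed template document or violated template invariant."""

    kind = "schema-error"


class TemplateResolutionError(SchemaError):
    """An extension references a base template that is not registered."""

    kind = "template-resolution-error"


class SerializationError(FairledgerError):
    """A record could not be canonically serialized (non-text value)."""

    kind = "serialization-error"


class LedgerAppendError(FairledgerError):
    """A block append would violate a chain invariant."""

    kind = "ledger-append-error"


class ConfigError(FairledgerError):
    """Invalid topology or storage configuration."""

    kind = "config-error"


class ProposalRejected(FairledgerError):
    """The endorsement lifecycle did not reach a commit decision."""

    kind = "proposal-rejected"

    def __init__(self, reason: str, violations: tuple = ()):  # type: ignore[type-arg]
        super().__init__(reason)
        self.reason = reason
        self.violations = tuple(violations)


class ResyncError(FairledgerError):
    """No consistent peer replica was available to resynchronize from."""

    kind = "resync-error"

    def __init__(self, message: str, reports=None):
        super().__init__(message)
        self.reports = reports or {}


class PlacementError(FairledgerError):
    """Shard placement across storage nodes is infeasible."""

    kind = "placement-error"


class InsufficientShardsError(FairledgerError):
    """Fewer valid shards than the reconstruction threshold k."""

    kind = "insufficient-shards"

    def __init__(self, have: int, need: int):
        super().__init__(
            f"reconstruction needs {need} valid shards, only {have} available "
            f"({need - have} missing)"
        )
        self.have = have
        self.need = need


class DataUnavailableError(FairledgerError):
    """Too few reachable valid shards to recover the payload."""

    kind = "data-unavailable"


class AuthenticationError(FairledgerError):
    """Unknown user or wrong credential."""

    kind = "authentication-error"


class PermissionDeniedError(FairledgerError):
    """Authenticated user lacks the right to perform the operation."""

    kind = "permission-denied"


class NotFoundError(FairledgerError):
    """Unknown DID, version or node."""

    kind = "not-found"
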