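"""Exception hierarchy for palaeopsin."""


class PalaeopsinError(Exception):
    """Base class for all palaeopsin errors."""


class TreeParseError(PalaeopsinError):
    """Raised when tree text cannot be parsed; carries position info when known."""


class TreeValidationError(PalaeopsinError):
    """Raised when a tree violates structural or chronological invariants."""


class AgeTableError(PalaeopsinError):
    """Raised for malformed or conflicting node-age table rows."""


class ReconciliationError(PalaeopsinError):
    """Raised when gene/species trees or the tip map are inconsistent."""


class NomenclatureError(PalaeopsinError):
    """Raised for unknown paralogue names or non-nested duplication events."""


class ChronologyError(PalaeopsinError):
    """Raised when a complement/bracketing query cannot be answered."""


class SimulationError(PalaeopsinError):
    """Raised when a simulation cannot satisfy its conditioning constraints."""
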