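"""Exception hierarchy.

Every error raised by the library derives from :class:`McganmError`, so
callers (and the CLI) can distinguish user/input problems from genuine bugs
with a single ``except`` clause.
"""


class McganmError(Exception):
    """Base class for all library errors."""


class PDBFormatError(McganmError):
    """A fixed-column PDB line could not be parsed; names the line number."""


class SelectorError(McganmError):
    """A chain/residue selector matched nothing or is malformed."""


class FieldOverflowError(McganmError):
    """A value does not fit its fixed-width PDB column."""


class LookupKeyError(McganmError):
    """An unknown residue key or element was requested."""


class SelectionError(McganmError):
    """An empty or invalid spatial selection (e.g. empty HR region)."""


class ModelError(McganmError):
    """The mixed-resolution model cannot be constructed as requested."""


class GeometryError(McganmError):
    """Degenerate geometry, e.g. a bonded node pair at zero separation."""


class DiagnosticError(McganmError):
    """A physical sanity check failed (wrong rigid-body mode count, ...)."""


class StatisticsError(McganmError):
    """Too few or degenerate data for the requested statistic."""


class RangeError(McganmError):
    """A mode rank or count outside the computed spectrum."""


class ConsistencyError(McganmError):
    """Conformer, model and structure do not describe the same system."""


class ReferenceError_(McganmError):
    """A distance reference (ligand or point) cannot be resolved."""


class SpecError(McganmError):
    """An invalid fixture or schedule specification."""
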