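"""Exception hierarchy for the pipeline.

Every error raised deliberately by this package derives from
:class:`VirofitError`, so callers (and the CLI) can distinguish bad input
from genuine bugs.
"""


class VirofitError(Exception):
    """Base class for all package errors."""


class FormatError(VirofitError):
    """A file does not conform to its declared dialect (missing columns,
    duplicate identifiers, malformed header)."""


class StructureError(VirofitError):
    """A parsed object violates a structural invariant (unresolvable
    parent, cycle, broken reference)."""


class ConsistencyError(VirofitError):
    """Cross-file or cross-stage inconsistency (e.g. a cluster member with
    no abundance entry)."""


class DesignError(VirofitError):
    """An infeasible simulation design."""
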