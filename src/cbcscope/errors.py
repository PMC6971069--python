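"""Exception hierarchy.

Every error the toolkit raises on bad input derives from :class:`CbcscopeError`
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class CbcscopeError(Exception):
    """Base class for all cbcscope domain errors."""


class FormatError(CbcscopeError):
    """A file or in-memory record violates its format contract."""


class RegionLookupError(CbcscopeError, KeyError):
    """A named region/tip/clade is absent from the annotations."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class PseudoknotError(FormatError):
    """A base-pair set contains crossing pairs; only nested structures are supported."""


class ConsistencyError(CbcscopeError):
    """A structure and a sequence/alignment disagree (length, identity)."""


class ParameterError(CbcscopeError, ValueError):
    """A parameter value is outside its admissible range."""


class CapacityError(ParameterError):
    """A synthetic-data request does not fit in the available positions."""


class TopologyError(CbcscopeError):
    """A queried clade is not monophyletic in the supplied tree."""


class UndefinedDistanceError(CbcscopeError, ZeroDivisionError):
    """A distance denominator is empty after masking/gap removal."""


class UnresolvableBoundaryError(CbcscopeError):
    """A spacer boundary cannot be located (no annotation, no usable flanks)."""
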