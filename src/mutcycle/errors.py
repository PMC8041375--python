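"""Exception hierarchy shared across the package."""


class MutcycleError(Exception):
    """Base class for all package-specific failures."""


class EstimationError(MutcycleError):
    """A free-energy estimator could not produce a value."""


class OverlapError(EstimationError):
    """Forward and reverse work distributions do not overlap enough to
    bracket the Bennett self-consistency root."""


class MissingEdgeError(MutcycleError, KeyError):
    """A required (reference, target) entry is absent from a DDGTable."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class DuplicateEdgeError(MutcycleError):
    """An edge was added twice to a DDGTable."""


class NoPathError(MutcycleError):
    """No chain of table edges connects the requested states."""


class StructureError(MutcycleError):
    """Structure parsing or residue/atom lookup failed."""


class ScanError(MutcycleError):
    """A positional scan could not be carried out."""


class BenchmarkError(MutcycleError):
    """Benchmark input is inconsistent (lengths, distances, bin edges)."""


class InputError(MutcycleError):
    """A file or CSV table is malformed; the message carries the location."""
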