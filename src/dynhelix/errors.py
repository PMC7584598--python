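"""Exception hierarchy for dynhelix.

Every error raised on a violated contract derives from :class:`DynhelixError`
so callers (and the CLI) can distinguish data problems from genuine bugs.
"""


class DynhelixError(Exception):
    """Base class for all dynhelix errors."""


class FormatError(DynhelixError):
    """A structure file could not be parsed under the named standard."""


class ConsistencyError(DynhelixError):
    """Monomer sets or numbering differ across models of one ensemble."""


class CapacityError(DynhelixError):
    """The requested output format cannot index this many monomers."""


class SelectionError(DynhelixError):
    """A residue/atom selection resolved to nothing."""


class TopologyError(DynhelixError):
    """Assembly topology could not be established."""


class DegenerateGeometryError(DynhelixError):
    """Zero-length vector or collinear points where an angle/axis is needed."""


class ResolutionError(DynhelixError):
    """Operation requires full-atom input but got coarse-grained (or vice versa)."""


class WindowError(DynhelixError):
    """Analysis window empty or unsatisfiable."""


class RadiiTableError(DynhelixError):
    """No radius known for an atom/bead name."""


class SpecError(DynhelixError):
    """Invalid generator or run specification."""


class SampleSizeError(DynhelixError):
    """Too few observations for the requested statistical comparison."""
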