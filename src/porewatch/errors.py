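"""Exception hierarchy shared across the pipeline."""


class PorewatchError(Exception):
    """Base class for all package errors."""


class FormatError(PorewatchError):
    """A file could not be parsed under the declared dialect."""


class ConfigurationError(PorewatchError):
    """An option or parameter combination is invalid."""


class TopologyError(PorewatchError):
    """Structure and trajectory disagree (atom counts, Cα matching)."""


class SelectionError(PorewatchError):
    """A species selection resolved no molecules."""


class ValidationError(PorewatchError):
    """Input data violates an invariant (NaN coordinates, unsorted times)."""


class GeometryError(PorewatchError):
    """Degenerate geometry (collinear or coincident point sets)."""


class InputError(PorewatchError):
    """Invalid analysis input (empty trajectory, mismatched bins, ...)."""
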