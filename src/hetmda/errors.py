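"""Exception hierarchy shared across the pipeline."""


class HetmdaError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(HetmdaError):
    """A text input could not be parsed; the message names the offending line."""


class LabelError(HetmdaError):
    """A label is unknown, duplicated, or outside a supplied universe."""


class CycleError(HetmdaError):
    """The child->parent edge list contains a cycle."""


class AlignmentError(HetmdaError):
    """Two labelled matrices do not share the required labels/shape."""


class ParameterError(HetmdaError):
    """A pipeline parameter is outside its legal range."""


class StructureError(HetmdaError):
    """An ancestor closure is internally inconsistent."""


class InputError(HetmdaError):
    """An input object is empty or otherwise unusable."""


class NumericalError(HetmdaError):
    """Non-finite values appeared during iteration."""
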