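"""Exception hierarchy."""


class ProsfoldError(Exception):
    """Base class for all package errors."""


class ParseError(ProsfoldError):
    """A structure file could not be parsed."""


class EmptyStructureError(ProsfoldError):
    """A structure file contained no polymer chain."""


class MappingError(ProsfoldError):
    """Segment could not be mapped between model and experimental chains."""


class RangeError(ProsfoldError):
    """A requested residue range falls outside the chain."""


class FeatureError(ProsfoldError):
    """A feature could not be computed; carries the feature name."""

    def __init__(self, feature: str, message: str):
        self.feature = feature
        super().__init__(f"{feature}: {message}")


class GenerationError(ProsfoldError):
    """Synthetic structure generation failed (e.g. persistent clashes)."""
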