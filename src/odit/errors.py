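"""Exception hierarchy for the odit package."""


class OditError(Exception):
    """Base class for all odit errors."""


class InvalidConfigurationError(OditError):
    """Raised when parameters are internally inconsistent or incompatible
    with the data (e.g. fewer reference points than requested neighbors)."""


class InputFormatError(OditError):
    """Raised for malformed input data: ragged rows, non-numeric cells,
    non-finite values, or dimension mismatches."""


class ModelFormatError(OditError):
    """Raised when a saved model archive is missing, corrupted, or violates
    its structural invariants."""
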