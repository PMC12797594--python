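"""Exception hierarchy for circastat."""


class CircastatError(Exception):
    """Base class for all circastat errors."""


class CSVFormatError(CircastatError, ValueError):
    """The input CSV does not follow the expected layout (index label, header row)."""


class CSVParseError(CircastatError, ValueError):
    """A data cell could not be parsed as a number."""


class TimeOrderError(CircastatError, ValueError):
    """Time indices are not strictly increasing."""


class EmptyStudyError(CircastatError, ValueError):
    """No series in the reference slot; nothing to group."""


class SingularFitError(CircastatError, ValueError):
    """The regression design matrix is rank deficient."""


class ScanError(CircastatError, RuntimeError):
    """Every candidate in a period/lag scan failed to fit."""


class TemplateSpecError(CircastatError, ValueError):
    """Invalid reference-waveform parameters."""


class IrregularSamplingError(CircastatError, ValueError):
    """Operation requires regularly spaced time points."""
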