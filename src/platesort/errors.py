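"""Exception hierarchy shared across the package."""


class PlatesortError(Exception):
    """Base class for all package-specific errors."""


class UnrecognizedFormatError(PlatesortError):
    """A file header cannot be mapped onto the instrument fields."""


class EmptyPlateError(PlatesortError):
    """A file contains a header but no object records (or nothing at all)."""


class InvalidCutoffError(PlatesortError):
    """Cutoff bounds are inverted or otherwise unusable."""


class InsufficientTrainingDataError(PlatesortError):
    """A training plate for the bubble classifier is empty."""


class FeatureMissingError(PlatesortError):
    """A classifier feature is absent from the plate it is applied to."""


class InvalidMetadataError(PlatesortError):
    """A strain or dose vector does not have exactly 96 entries."""


class CorruptSummaryError(PlatesortError):
    """A summarized plate contains duplicate well entries."""


class InsufficientDataError(PlatesortError):
    """A statistical routine received too little non-missing data."""


class UnknownTraitError(PlatesortError):
    """A requested trait or column is not present in the data."""


class InvalidScenarioError(PlatesortError):
    """A synthetic-plate scenario has out-of-range parameters."""
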