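"""Exception hierarchy for the MR pipeline."""


class MRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRError):
    """Invalid configuration: bad column map, missing mandatory column, bad grid config."""


class ValidationError(MRError):
    """A value violates a domain invariant (bad allele, non-positive SE, ...)."""


class NoUsableInstrumentsError(MRError):
    """Harmonization left zero instruments; estimators must not receive N=0."""


class InsufficientInstrumentsError(MRError):
    """An estimator or sensitivity test was given fewer instruments than it requires."""


class DegenerateInstrumentError(MRError):
    """Wald ratio on an instrument with zero effect on the exposure."""


class CollinearityError(MRError):
    """Degenerate regression design (e.g. all variant-exposure effects equal)."""


class UnknownVariantError(MRError, KeyError):
    """A variant was not found in a summary-statistics set or LD provider."""


class UndefinedLDError(MRError):
    """LD is undefined (zero-variance dosage vector)."""


class DegenerateCorrectionError(MRError):
    """MR-PRESSO flagged so many outliers that no corrected estimate is possible."""
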