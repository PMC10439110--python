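"""Exception hierarchy shared across the package."""


class PhageGeoError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PhageGeoError, ValueError):
    """A generator or model was configured with impossible parameters."""


class SchemaError(PhageGeoError, ValueError):
    """An input table or profile violates the expected schema."""


class DegenerateControlError(PhageGeoError, ValueError):
    """Control wells have non-positive mean; normalization undefined."""


class InsufficientDataError(PhageGeoError, ValueError):
    """Too few distinct concentrations (or replicates) to fit."""


class UnstableFitError(PhageGeoError, RuntimeError):
    """More than half of bootstrap refits failed."""


class PairingError(PhageGeoError, ValueError):
    """Fits from different ions were paired for a threshold call."""


class MissingIonError(PhageGeoError, KeyError):
    """An ion was requested that a profile does not contain."""


class MissingTaxonError(PhageGeoError, KeyError):
    """A taxon with nonzero abundance is absent from the capability table."""


class OutOfDomainError(PhageGeoError, ValueError):
    """A model was evaluated outside its physical domain."""


class UndefinedThresholdError(PhageGeoError, ValueError):
    """A no-inhibition fit has no half-maximal concentration to convert."""


class InsufficientReplicationError(PhageGeoError, ValueError):
    """A (carbon source, phage) group has fewer than two replicates."""
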