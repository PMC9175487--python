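"""Exception hierarchy shared across the package."""


class NCMinerError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NCMinerError):
    """Malformed input table, missing column, or invalid configuration."""


class EmptyDatasetError(NCMinerError):
    """An ingest or filter step produced a dataset with no usable rows."""


class FingerprintError(NCMinerError):
    """A SMILES string could not be parsed / fingerprinted."""

    def __init__(self, smiles: str, message: str | None = None):
        self.smiles = smiles
        super().__init__(message or f"cannot fingerprint SMILES: {smiles!r}")


class DimensionError(NCMinerError):
    """Vector or matrix shapes are incompatible."""


class SpecMismatchError(NCMinerError):
    """Fingerprint spec of data does not match the spec a model was trained with."""


class SamplingExhaustedError(NCMinerError):
    """Rejection sampling failed to produce a valid pair within the attempt cap."""


class CheckpointError(NCMinerError):
    """A model checkpoint is corrupt, incomplete, or of an unknown version."""
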