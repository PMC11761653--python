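"""Exception hierarchy shared across the package."""


class HybridforgeError(Exception):
    """Base class for all package errors."""


class InvalidMoleculeError(HybridforgeError):
    """A SMILES string could not be parsed into a molecule."""


class ChargeComputationError(HybridforgeError):
    """Partial charges could not be computed for a molecule."""


class UnalignableSequenceError(HybridforgeError):
    """A protein sequence could not be aligned to the reference."""


class EncodingError(HybridforgeError):
    """A sequence contains characters outside the supported alphabet."""


class BackendUnavailableError(HybridforgeError):
    """A requested embedding backend is not installed."""


class ConfigurationError(HybridforgeError):
    """Inconsistent or invalid configuration / input data."""


class AssemblyError(HybridforgeError):
    """A monomer could not be incorporated into a core molecule."""
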