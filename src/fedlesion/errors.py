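"""Exception hierarchy used across the simulator."""


class FedLesionError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FedLesionError, ValueError):
    """A user-supplied configuration value is invalid."""


class InputError(FedLesionError, ValueError):
    """Runtime data (images, labels, batches) violates a contract."""


class StructuralError(FedLesionError, ValueError):
    """Parameter arrays are incongruent with the expected architecture."""


class StateError(FedLesionError, RuntimeError):
    """Internal bookkeeping (timestamps, caches) is corrupted."""
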