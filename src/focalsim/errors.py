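"""Exception types shared across the package."""


class FocalsimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FocalsimError, ValueError):
    """A scene, protocol, or task configuration is internally inconsistent."""


class StateError(FocalsimError, RuntimeError):
    """An operation was requested in a state that does not permit it."""
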