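"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`FociquantError` so callers can catch
pipeline failures without masking programming errors.
"""


class FociquantError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(FociquantError, ValueError):
    """A configuration value violates its invariant (fraction outside [0,1], ...)."""


class ChannelRoleError(FociquantError, ValueError):
    """A channel role is missing or maps to an out-of-range channel index."""


class DegenerateImageError(FociquantError, ValueError):
    """An image is constant (or otherwise degenerate) where structure is required."""


class EmptyFieldError(FociquantError, ValueError):
    """No nucleus was found in any z-slice of a stack."""


class NoBaselineError(FociquantError, ValueError):
    """No untransfected cell is available to serve as the background/normalization baseline."""


class GateFittingError(FociquantError, ValueError):
    """The DAPI histogram is unimodal; 2N/4N gates cannot be placed."""
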