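"""Exception hierarchy.

Two broad families matter to callers (and to the CLI exit codes):

* :class:`InputError` — the request itself was malformed (bad geometry,
  missing data, out-of-range prediction).  CLI exit code 3.
* :class:`QCError` — the data were read fine but do not support the
  requested inference (flat profile, too few cycles, unreliable fit).
  These are scientific verdicts, not crashes.  CLI exit code 2.
"""


class ShutterLumError(Exception):
    """Base class for all package errors."""


class InputError(ShutterLumError):
    """Malformed input, configuration or request."""


class ShapeError(InputError):
    """Array shapes inconsistent with the sensor/scene geometry."""


class ChannelError(InputError):
    """Image does not have the expected RGB channel structure."""


class GeometryError(InputError):
    """A requested region lies outside the image."""


class DataError(InputError):
    """Too few or degenerate data points for the requested fit."""


class ExtrapolationError(InputError):
    """Observable outside the calibrated response range."""


class QCError(ShutterLumError):
    """Data fail a quality-control criterion of the analysis."""


class FlatProfileError(QCError):
    """No banding detected: the steady-state-illumination verdict."""


class InsufficientCyclesError(QCError):
    """Fewer than the minimum number of complete strobe cycles."""


class UnreliableFitError(QCError):
    """Decay fit did not converge or its uncertainty exceeds the estimate."""


class NoLifetimeError(QCError):
    """Every off-band decay fit was rejected; no lifetime can be reported."""


class AmbiguousMatchError(QCError):
    """Several library species match the estimated lifetime."""

    def __init__(self, candidates):
        self.candidates = list(candidates)
        super().__init__(
            "ambiguous species match: " + ", ".join(self.candidates)
        )


class ModelMisfitError(QCError):
    """Fitted calibration model violates its structural assumptions."""


class ModelMisfitWarning(UserWarning):
    """Fitted calibration parameters are physically implausible."""
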