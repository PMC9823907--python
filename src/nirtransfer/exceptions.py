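"""Exception hierarchy.

The CLI maps these onto process exit codes (parameter -> 2, data format -> 3,
shape/pairing -> 4), so every error raised by the library should derive from
:class:`NIRTransferError`.
"""


class NIRTransferError(Exception):
    """Base class for all errors raised by nirtransfer."""


class ParameterError(NIRTransferError, ValueError):
    """An argument value is outside its admissible range."""


class RangeError(ParameterError):
    """A wavelength selection or interpolation request falls outside the axis."""


class DegenerateResponseError(ParameterError):
    """The response vector carries no variance, so no regression is defined."""


class FormatError(NIRTransferError, ValueError):
    """A spectral matrix file violates the expected text dialect."""


class ShapeError(NIRTransferError, ValueError):
    """Matrix/axis dimensions are inconsistent with the fitted model."""


class PairingError(NIRTransferError, ValueError):
    """Transfer-set spectra from the two instruments are not sample-paired."""


class ConditioningWarning(UserWarning):
    """The transfer-set matrix is numerically near rank deficiency."""


class TransferSetSizeWarning(UserWarning):
    """The transfer set is smaller than recommended practice."""


class LeverageWarning(UserWarning):
    """Spectra being transferred lie far outside the transfer set's span."""
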