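"""Exception types shared across the package."""


class BoostCDError(Exception):
    """Base class for all package-specific errors."""


class BasisError(BoostCDError):
    """An operation received a T-matrix or coefficient vector in the wrong basis."""


class GeometryError(BoostCDError):
    """A wave was not in the supported axial (-z) geometry."""


class ParseError(BoostCDError):
    """A polarizability table or T-matrix store could not be parsed."""


class WindowError(BoostCDError):
    """No lab-frame wavelength maps into the tabulated rest-frame grid."""
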