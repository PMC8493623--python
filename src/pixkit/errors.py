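"""Exception hierarchy.

``PixkitError`` is the base for all data-level failures (CLI exit code 2).
Usage errors are left to the CLI layer (exit code 1).
"""


class PixkitError(Exception):
    """Base class for all pixkit data errors."""


class CifParseError(PixkitError):
    """A CIF document could not be parsed; names the offending item."""

    def __init__(self, message: str, item: str | None = None, position: int | None = None):
        self.item = item
        self.position = position
        detail = message
        if item is not None:
            detail += f" (item: {item})"
        if position is not None:
            detail += f" (position: {position})"
        super().__init__(detail)


class SymopParseError(CifParseError):
    """A symmetry-operation xyz string is malformed."""


class DegenerateCellError(PixkitError):
    """Unit-cell parameters do not define a positive-volume lattice."""


class DisorderError(PixkitError):
    """Structure contains partially occupied sites and disorder was not allowed."""


class PolymericError(PixkitError):
    """Molecule completion never reached closure (infinite connectivity)."""

    def __init__(self, message: str, bridging_bond: tuple[str, str] | None = None):
        self.bridging_bond = bridging_bond
        if bridging_bond is not None:
            message += f" (bridging bond: {bridging_bond[0]} - {bridging_bond[1]})"
        super().__init__(message)


class CapacityError(PixkitError):
    """Molecule or residue count exceeds the Pixel-export limits."""


class CubeFormatError(PixkitError):
    """An electron-density cube file is malformed."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message += f" (line {position})"
        super().__init__(message)


class TableParseError(PixkitError):
    """An interaction-energy table could not be parsed."""


class MissingEnergyError(PixkitError):
    """A pair required for an energy sum has no attached energy."""
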