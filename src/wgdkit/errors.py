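"""Exception hierarchy shared across the toolkit."""


class WGDKitError(Exception):
    """Base class for all toolkit errors."""


class NewickParseError(WGDKitError):
    """Malformed Newick/NHX input; carries the parser's position message."""


class TreeValidationError(WGDKitError):
    """Structurally valid Newick that violates a toolkit invariant
    (non-ultrametric species tree, WGD time outside its branch, ...)."""


class LeafMappingError(WGDKitError):
    """A gene-tree leaf label could not be resolved to a species."""


class UndefinedStatisticError(WGDKitError):
    """The retention ratio is undefined for the given counts.

    ``code`` distinguishes the degenerate cases:

    - ``"no_rr_data"``:  rr_possible == 0 (no retained-retained denominators)
    - ``"no_lr_data"``:  lr_possible == 0 (no lost-retained denominators)
    - ``"zero_lr_rate"``: lr_possible > 0 but lr_copies == 0 (division by zero)
    """

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


class BootstrapFailureError(WGDKitError):
    """Bootstrap resampling produced undefined statistics in too many draws."""

    def __init__(self, message: str, n_valid: int, n_undefined: int):
        super().__init__(message)
        self.n_valid = n_valid
        self.n_undefined = n_undefined
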