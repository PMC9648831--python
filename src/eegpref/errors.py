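"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration field is invalid; the message names the field."""


class BoundsError(ValueError):
    """A requested time span falls outside the available recording."""


class ShapeError(ValueError):
    """An array does not have the expected dimensions."""


class EmptyDatasetError(ValueError):
    """No usable subjects/samples remain after filtering."""


class SingleClassError(ValueError):
    """An operation requiring both classes was given one class only."""


class DegenerateCellError(ArithmeticError):
    """Baseline statistics coincide at a cell; normalisation is undefined."""


class LeakageError(RuntimeError):
    """Test or validation subject data leaked into a training set."""
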