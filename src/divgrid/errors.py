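"""Exception hierarchy shared across the pipeline."""


class DivgridError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(DivgridError, ValueError):
    """A configuration value violates its documented range or combination."""


class EmptyInputError(DivgridError, ValueError):
    """An operation received an input with no usable records."""


class TreeParseError(DivgridError, ValueError):
    """A newick string could not be parsed or failed validation."""


class LookupLabelError(DivgridError, KeyError):
    """A species label was not found where required (tree leaf, trait row)."""


class IncomparablePairError(DivgridError, ValueError):
    """A species pair shares no non-missing, positively weighted trait."""


class DegenerateDesignError(DivgridError, ValueError):
    """A regression design has no usable variation."""


class InsufficientDataError(DivgridError, ValueError):
    """Too few usable observations for the requested fit."""


class SearchFailureError(DivgridError, RuntimeError):
    """A bandwidth search found no admissible candidate on its interval."""
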