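"""Exception hierarchy for :mod:`bcfkit`.

All errors raised by the library derive from :class:`BcfkitError` so callers
can catch the whole family; the concrete subclasses also derive from the
closest builtin (``ValueError``/``KeyError``) for drop-in compatibility.
"""


class BcfkitError(Exception):
    """Base class for all bcfkit errors."""


class InvalidInputError(BcfkitError, ValueError):
    """A numeric argument is out of its physical domain (negative rate,
    non-finite pKa, ...)."""


class InvalidConfigError(BcfkitError, ValueError):
    """A configuration value is inconsistent (e.g. LOQ below LOD)."""


class InsufficientDataError(BcfkitError, ValueError):
    """Too few usable (uncensored) observations to run the requested
    computation."""


class UndefinedPlateauError(InvalidInputError):
    """Kinetic BCF requested with a zero elimination rate: the uptake curve
    has no plateau and k1/k2 is undefined."""


class LinkageError(BcfkitError, KeyError):
    """A series refers to an analyte missing from the compound table, or a
    metabolite lacks a resolvable parent."""
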