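"""Exception hierarchy.

Every described failure mode raises a subclass of :class:`OntoThreshError`,
so callers (and the CLI) can distinguish user errors from bugs.
"""


class OntoThreshError(Exception):
    """Base class for all described errors."""


class FormatError(OntoThreshError):
    """An input file could not be parsed in its declared format."""


class IntegrityError(OntoThreshError):
    """The ontology violates a structural invariant (e.g. a cycle)."""


class UnknownTermError(OntoThreshError, KeyError):
    """A term identifier does not resolve in the ontology."""

    def __str__(self) -> str:  # KeyError quotes its repr; keep the message plain
        return Exception.__str__(self)


class NamespaceMismatchError(OntoThreshError):
    """Two terms or term sets belong to different namespaces."""


class EmptyCorpusError(OntoThreshError):
    """No annotation rows survived parsing and filtering."""


class EmptyAnnotationError(OntoThreshError):
    """A set-level measure received an empty term set."""


class UndefinedInformativenessError(OntoThreshError, KeyError):
    """A term has no defined IC / informativeness value."""

    def __str__(self) -> str:
        return Exception.__str__(self)


class ConfigurationError(OntoThreshError):
    """Invalid run configuration (too few groups, infeasible spec, ...)."""


class DegenerateInputError(OntoThreshError):
    """A statistical routine received input it cannot handle (e.g. zero variance)."""


class WelchGateError(OntoThreshError):
    """The similar / non-similar distributions are not significantly different."""
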