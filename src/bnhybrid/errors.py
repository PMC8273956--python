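"""Exception hierarchy shared across the package."""


class BnHybridError(Exception):
    """Base class for all package-specific errors."""


class CycleError(BnHybridError):
    """A directed cycle was found where a DAG was required.

    Carries ``cycle``: one offending node sequence (closed walk).
    """

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"directed cycle: {' -> '.join(map(str, self.cycle))}")


class UnknownNodeError(BnHybridError, KeyError):
    pass


class UnknownEdgeError(BnHybridError, KeyError):
    pass


class UnknownFixtureError(BnHybridError, KeyError):
    pass


class InconsistentUniverseError(BnHybridError):
    """Per-node neighbourhood results do not share one node universe."""


class NodeSetMismatchError(BnHybridError):
    """Two graphs being compared are defined over different node sets."""


class NegativeComponentError(BnHybridError, ValueError):
    """A structural-error component was negative."""


class DegenerateError(BnHybridError):
    """A contingency-table computation met a constant (single-level) variable."""


class ZeroProbabilityEvidenceError(BnHybridError):
    """The supplied evidence configuration has probability zero under the network."""


class SeparationError(BnHybridError):
    """Complete or quasi-complete separation stalls logistic maximum likelihood."""


class NonConvergenceError(BnHybridError):
    """Iteratively reweighted least squares failed to converge."""


class ParseError(BnHybridError):
    """A file did not parse; carries line (1-based) when known."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(BnHybridError):
    """A parsed object violates a semantic invariant (e.g. CPT rows not normalised)."""


class SchemaViolationError(BnHybridError):
    """Dataset values fall outside the declared variable levels.

    Carries ``violations``: list of (row, column, value).
    """

    def __init__(self, violations):
        self.violations = list(violations)
        head = ", ".join(f"(row {r}, {c}={v!r})" for r, c, v in self.violations[:5])
        more = "" if len(self.violations) <= 5 else f" … {len(self.violations)} total"
        super().__init__(f"values outside declared levels: {head}{more}")
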