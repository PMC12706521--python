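"""Exception hierarchy shared across the package."""


class PhylogridError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PhylogridError, ValueError):
    """A parameter violates its documented precondition."""


class InvalidInputError(PhylogridError, ValueError):
    """Input data are malformed (degenerate polygon, non-ultrametric tree, ...)."""


class MissingTaxonError(PhylogridError, KeyError):
    """Community species absent from the phylogeny; carries the offending names."""

    def __init__(self, names):
        self.names = sorted(names)
        super().__init__(f"species missing from tree: {', '.join(self.names)}")


class NewickParseError(PhylogridError, ValueError):
    """Newick text could not be parsed or fails tree invariants."""


class UndefinedMetricError(PhylogridError, ValueError):
    """Metric undefined for this input (all-zero matrix, constant variable, ...)."""


class NumericalFailureError(PhylogridError, ArithmeticError):
    """A linear solve or likelihood optimization failed."""
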