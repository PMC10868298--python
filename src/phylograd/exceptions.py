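"""Exception hierarchy.

Errors map onto the CLI exit-code convention: input/parameter problems
(`InvalidParameterError`, `ParseError`, ...) exit with code 2, runtime
numerical failures (`NumericalError`) with code 1.
"""


class PhylogradError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PhylogradError, ValueError):
    """A model, tree, or configuration parameter violates its preconditions."""


class UnsupportedCodeError(InvalidParameterError):
    """Requested genetic code is not available."""


class ParseError(PhylogradError, ValueError):
    """Malformed input file (Newick, FASTA, config)."""


class UnsupportedTopologyError(ParseError):
    """Tree is not strictly bifurcating."""

    def __init__(self, message, node=None):
        super().__init__(message)
        self.node = node


class AlignmentError(PhylogradError, ValueError):
    """Sequences do not form a rectangular alignment."""


class EncodingError(PhylogradError, ValueError):
    """A character cannot be mapped to the model state space."""

    def __init__(self, message, taxon=None, column=None):
        super().__init__(message)
        self.taxon = taxon
        self.column = column


class InvalidStateError(PhylogradError, RuntimeError):
    """An operation was called before its prerequisites completed."""


class NumericalError(PhylogradError, ArithmeticError):
    """Non-finite or impossible values encountered during computation.

    ``patterns`` lists offending site-pattern indices when applicable.
    """

    def __init__(self, message, patterns=None, node=None):
        super().__init__(message)
        self.patterns = patterns
        self.node = node
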