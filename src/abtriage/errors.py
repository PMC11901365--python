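"""Exception hierarchy for the triage pipeline.

Stage *decisions* (a record failing a filter) are never exceptions; these
classes cover malformed input, broken invariants and unavailable backends.
"""


class AbtriageError(Exception):
    """Base class for all package errors."""


# -- numbering ---------------------------------------------------------------

class UnnumberableSequence(AbtriageError):
    """Sequence cannot be assigned scheme position labels.

    Carries a machine-readable ``reason`` code (``bad-alphabet``,
    ``length-out-of-range``, ``missing-anchor``, ``framework-insertion``,
    ``too-many-insertions``).
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


class GridOverflow(AbtriageError):
    """Chain uses an insertion label outside the canonical grid."""


class MissingRegion(AbtriageError):
    """No residue falls inside the requested CDR window."""


# -- physchem ----------------------------------------------------------------

class UnknownResidue(AbtriageError):
    """Residue letter absent from a physicochemical table."""


class NonConvergence(AbtriageError):
    """Iterative solver failed to reach tolerance."""


class DegenerateInput(AbtriageError):
    """Statistical comparison requested on an empty group."""


class InsufficientData(AbtriageError):
    """Too few records to compute reference statistics."""


# -- encoding ----------------------------------------------------------------

class PadMismatch(AbtriageError):
    """Chain pair was padded with a different encoder's pad character."""


class AdapterUnavailable(AbtriageError):
    """Requested language-model adapter package is not importable."""


# -- layer1 ------------------------------------------------------------------

class DegenerateKernel(AbtriageError):
    """Centered kernel matrix has rank below the requested components."""


class DimensionMismatch(AbtriageError):
    """Feature dimension differs from the fitted model."""


class DegenerateEllipse(AbtriageError):
    """Ellipse endpoints coincide (zero major radius)."""


class InsufficientReference(AbtriageError):
    """Fewer than three reference points for ellipse construction."""


class EmptyGroup(AbtriageError):
    """Capture rate requested for an empty group."""


# -- layer2 ------------------------------------------------------------------

class SingleClassLabels(AbtriageError):
    """Training labels contain a single class."""


class ConvergenceFailure(AbtriageError):
    """Classifier optimiser did not converge."""


class TooFewSamples(AbtriageError):
    """Not enough samples for the requested number of CV folds."""


class UnknownIndex(AbtriageError):
    """Selected feature index missing from the encoder layout map."""


# -- pipeline_io -------------------------------------------------------------

class ParseError(AbtriageError):
    """Unparseable input file; carries an optional line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


class IOFailure(AbtriageError):
    """Report could not be written."""
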