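"""Exception hierarchy shared across the pipeline stages."""


class IfnScopeError(Exception):
    """Base class for all errors raised by this package."""


class CoordinateOrderError(IfnScopeError):
    """Gene start coordinate exceeds its end coordinate."""


class GffParseError(IfnScopeError):
    """A GFF3 file could not be parsed into gene records."""


class HitParseError(IfnScopeError):
    """A tabular homology-hit file row is malformed."""


class FrameError(IfnScopeError):
    """A hit span is not congruent to a single reading frame."""


class SequenceLookupError(IfnScopeError):
    """A chromosome is absent from the sequence store."""


class AlphabetError(IfnScopeError):
    """A sequence contains symbols outside the expected alphabet."""


class InternalStopError(IfnScopeError):
    """A coding sequence contains an in-frame stop before its last codon."""


class SequenceTooShortError(IfnScopeError):
    """A protein is too short for the requested correlation tier."""


class DegenerateScaleError(IfnScopeError):
    """An amino-acid property scale has zero variance."""


class DegenerateDenominatorError(IfnScopeError):
    """The pseudo-composition normalizing denominator is numerically zero."""


class DegenerateLabelsError(IfnScopeError):
    """A training set contains fewer than two classes."""


class EmptyModelError(IfnScopeError):
    """Feature pruning would retain no features."""


class FeatureShapeError(IfnScopeError):
    """Feature vectors do not match the model's expected dimensionality."""


class StratificationError(IfnScopeError):
    """A class is too small for the requested number of CV folds."""


class EmptyEvalError(IfnScopeError):
    """Evaluation was requested on an empty set of predictions."""


class AlignmentError(IfnScopeError):
    """Aligned sequences do not share a common length."""


class LabelingError(IfnScopeError):
    """A sequence identifier has no group label."""


class EmptySummaryError(IfnScopeError):
    """A locus summary was requested for zero assignments."""


class ConfigError(IfnScopeError):
    """A simulation or run configuration is internally inconsistent."""
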