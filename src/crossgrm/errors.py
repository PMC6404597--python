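"""Exception hierarchy.

Every validation rule raises a distinct, named error so callers (and the
CLI) can report precisely which contract was violated.
"""


class CrossGRMError(Exception):
    """Base class for all crossgrm errors."""


# --- pedigree -----------------------------------------------------------


class PedigreeError(CrossGRMError):
    """Base class for pedigree validation errors."""


class DuplicateIdError(PedigreeError):
    """The same individual id occurs more than once."""


class UnknownParentError(PedigreeError):
    """A parent reference does not resolve to any individual."""


class HalfKnownParentError(PedigreeError):
    """Exactly one parent is recorded; only founders may lack parents."""


class SexInconsistencyError(PedigreeError):
    """A sire reference points to a female, or a dam reference to a male."""


class UnknownSexError(PedigreeError):
    """Sex code is not one of the accepted male/female encodings."""


class PedigreeCycleError(PedigreeError):
    """An individual is its own ancestor."""


class MissingLineLabelError(PedigreeError):
    """A founder has no line-of-origin label."""


class InvalidLineLabelError(PedigreeError):
    """A non-founder carries a line label (lines belong to founders only)."""


class SelfingError(PedigreeError):
    """Sire and dam are the same individual."""


# --- genotypes ----------------------------------------------------------


class GenotypeError(CrossGRMError):
    """Base class for founder-genotype errors."""


class MissingFounderGenotypeError(GenotypeError):
    """A pedigree founder has no row in the genotype file."""


class MissingGenotypeError(GenotypeError):
    """A genotype call is missing and imputation was not requested."""


class MaleHeterozygousXError(GenotypeError):
    """A male founder has a heterozygous call at an X-linked locus."""


# --- moments / matrices -------------------------------------------------


class WeightError(CrossGRMError):
    """Line weights are negative or do not sum to one."""


class ZeroHeterozygosityError(CrossGRMError):
    """The scaling factor S = 2·Σ p̄(1−p̄) is zero; no relationship scale exists."""


class LabelMismatchError(CrossGRMError):
    """Two matrices (or a matrix and a pedigree) disagree on individual labels."""


class SingularMatrixError(CrossGRMError):
    """A matrix that must be inverted is numerically singular."""


class NotTwoLinesError(CrossGRMError):
    """An operation defined only for a two-line cross was requested for L ≠ 2."""


# --- fixtures -----------------------------------------------------------


class FixtureError(CrossGRMError):
    """The fixture specification cannot be realized."""
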