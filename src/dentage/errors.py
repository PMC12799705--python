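"""Exception hierarchy.

Every domain error derives from :class:`DentageError` so callers (and the
command line) can distinguish bad input from genuine bugs.
"""


class DentageError(Exception):
    """Base class for all domain errors raised by dentage."""


# -- chart / table validation -------------------------------------------------

class MissingTooth(DentageError):
    """A dental chart does not cover all seven left mandibular teeth."""

    def __init__(self, fdi_codes):
        self.fdi_codes = tuple(sorted(fdi_codes))
        super().__init__(f"chart is missing teeth (FDI): {', '.join(map(str, self.fdi_codes))}")


class InvalidStage(DentageError):
    """A stage label outside A-H."""


class SchemaError(DentageError):
    """A reference-table file does not match the expected JSON schema."""


class InvariantViolation(DentageError):
    """A structurally valid file carries values that break a table invariant."""


# -- scoring / conversion -----------------------------------------------------

class StageBelowCoverage(DentageError):
    """A tooth's stage is earlier than the reference table's first scored stage.

    This signals a subject younger than the reference population supports; it
    is deliberately not scored as zero, which would corrupt years-scaled sums.
    """

    def __init__(self, sex, fdi, stage, first_stage):
        self.sex, self.fdi, self.stage, self.first_stage = sex, fdi, stage, first_stage
        super().__init__(
            f"tooth {fdi} ({sex}) observed at stage {stage}, below the table's "
            f"first scored stage {first_stage}"
        )


class AgeOutOfRange(DentageError):
    """Requested age is outside the conversion grid's 6-16 year window."""


class FitDiverged(DentageError):
    """The logistic fit failed to converge (or too few anchors were supplied)."""


class NonMonotoneAnchors(DentageError):
    """Anchor ages or scores are not strictly increasing."""


# -- calibration --------------------------------------------------------------

class EmptyCohort(DentageError):
    """No usable subjects."""


class NoStageHCoverage(DentageError):
    """A tooth has no stage-H data, so the derived table cannot score mature subjects."""


class SparseBin(DentageError):
    """An integer-age bin has fewer subjects than the configured minimum."""


# -- evaluation ---------------------------------------------------------------

class LengthMismatch(DentageError):
    """Paired vectors of unequal length."""


class ConstantInput(DentageError):
    """A correlation coefficient is undefined for a constant vector."""


class PerfectExpectedAgreement(DentageError):
    """Chance agreement is 1 (single shared category), so kappa is undefined."""


class SubjectMismatch(DentageError):
    """Two rating sets do not cover the same subjects."""


class CoverageError(DentageError):
    """A reference-table set cannot score some observed (tooth, stage)."""


# -- simulation ---------------------------------------------------------------

class SingleStageTooth(DentageError):
    """Entry thresholds cannot be derived from a single scored stage."""


# -- file ingest --------------------------------------------------------------

class ParseError(DentageError):
    """Malformed rows in a staging CSV; the message lists line numbers."""


class ContradictoryAge(DentageError):
    """A row's age column disagrees with its birth/exam dates by more than 0.02 yr."""
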