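"""Exception hierarchy used across frailtykit."""


class FrailtyKitError(Exception):
    """Base class for all frailtykit errors."""


class ConfigError(FrailtyKitError):
    """An invalid simulation-configuration field. Carries the field name."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class DictionaryError(FrailtyKitError):
    """A malformed coding rule, or a rule applied with the wrong kind."""


class SchemaError(FrailtyKitError):
    """A cohort table that does not match the data dictionary."""


class CalibrationError(FrailtyKitError):
    """Mortality-intercept calibration could not bracket the target."""


class DegenerateSampleError(FrailtyKitError):
    """A model sample with no rows, or a single outcome class."""


class UndefinedAUCError(DegenerateSampleError):
    """AUC requested with fewer than one event or one non-event."""


class DegenerateComparisonError(FrailtyKitError):
    """AUC difference has zero estimated variance but unequal AUCs."""


class AlignmentError(FrailtyKitError):
    """Score vectors of mismatched length in a correlated-AUC comparison."""


class GroupingError(FrailtyKitError):
    """A BH family containing mixed contrast labels or panels."""


class DesignError(FrailtyKitError):
    """A rank-deficient or otherwise unusable regression design."""
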