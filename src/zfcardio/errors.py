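"""Exception hierarchy for the zfcardio pipeline."""


class ZfcardioError(Exception):
    """Base class for all package errors."""


class DomainError(ZfcardioError):
    """An indicator formula was evaluated outside its mathematical domain."""


class AnalysisFailure(ZfcardioError):
    """A per-fish analysis step failed (too few cycles, no valid frames, ...).

    Pipeline code catches this, records the fish in the exclusion report and
    continues; it never aborts a whole run.
    """


class CanvasOverflowError(ZfcardioError):
    """The requested image canvas cannot contain the diastolic ellipse."""


class ConfigurationError(ZfcardioError):
    """A cohort or pipeline configuration is inconsistent (e.g. missing the
    control or model group)."""
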