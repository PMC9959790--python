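"""Exception hierarchy for honeynmr."""


class HoneyNMRError(Exception):
    """Base class for all honeynmr errors."""


class PanelValidationError(HoneyNMRError, ValueError):
    """An analyte panel (or one of its entries) violates an invariant."""


class SpectrumFormatError(HoneyNMRError, ValueError):
    """A spectrum file could not be parsed or fails basic sanity checks."""


class CalibrationError(HoneyNMRError, RuntimeError):
    """Internal-standard calibration is impossible (e.g. TMSP area <= 0)."""
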