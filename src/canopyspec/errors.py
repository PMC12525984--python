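"""Exception hierarchy shared across the package."""


class CanopySpecError(Exception):
    """Base class for all canopyspec errors."""


class InvalidProfileError(CanopySpecError):
    """A stress profile with non-physical parameters (e.g. gain <= 0)."""


class CalibrationError(CanopySpecError):
    """Radiometric calibration is ill-posed (white <= dark somewhere)."""


class PreprocessError(CanopySpecError):
    """A preprocessing operator hit a degenerate row or bad parameters."""


class ProvenanceError(CanopySpecError):
    """Preprocessing provenance of the data does not match the model."""
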