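"""Exception hierarchy for the respstage pipeline."""


class RespStageError(Exception):
    """Base class for all respstage errors."""


class InvalidParameterError(RespStageError, ValueError):
    """A parameter or input violates a precondition."""


class NoSignalError(RespStageError):
    """A window contains no usable signal (no spectral peak, no breath peaks)."""


class FeatureExtractionError(RespStageError):
    """Feature extraction failed on a specific window.

    Carries the window index so a long recording can be debugged.
    """

    def __init__(self, window_index: int, message: str):
        self.window_index = window_index
        super().__init__(f"window {window_index}: {message}")


class AlignmentError(RespStageError):
    """Predicted and true hypnograms do not align."""


class LabelingError(RespStageError):
    """Cluster-to-stage labeling failed."""


class AmbiguousLabelError(LabelingError):
    """A label tie or duplicate stage claim in strict mode."""


class EmptyClusterError(LabelingError):
    """A cluster received no labeled points."""


class InvalidModelError(RespStageError):
    """A centroid set is unusable (e.g. unlabeled) for classification."""
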