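"""Exception hierarchy shared across the pipeline stages."""


class MosquitoSDMError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MosquitoSDMError):
    """Invalid configuration (bad proportions, unknown feature names, ...)."""


class InputError(MosquitoSDMError, ValueError):
    """Invalid data handed to an operation (wrong length, non-finite, ...)."""


class GenerationError(MosquitoSDMError):
    """Synthetic generation cannot satisfy its constraints."""


class FitError(MosquitoSDMError):
    """A model fit failed beyond recoverable fallbacks."""


class PredictionError(MosquitoSDMError):
    """Prediction could not be carried out (e.g. missing feature raster)."""


class PipelineError(MosquitoSDMError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
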