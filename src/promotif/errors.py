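"""Exception hierarchy used across the pipeline.

Configuration problems (bad thresholds, impossible layouts) are distinct
from input problems (malformed or inconsistent data) so the CLI can map
them to different exit codes (2 and 3 respectively).
"""


class PromotifError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PromotifError, ValueError):
    """A parameter or configuration value violates its documented range."""


class InputError(PromotifError, ValueError):
    """Input data is malformed or inconsistent with other inputs."""


class StageError(PromotifError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
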