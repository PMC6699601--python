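"""Exception hierarchy.

``ConfigError`` marks problems detectable before any computation (bad
parameters, malformed configuration); the CLI maps it to exit code 2.
Everything else raised by the library is a ``TeamNeuroError`` (exit code 1)
or a plain ``ValueError`` from argument validation at function boundaries.
"""


class TeamNeuroError(Exception):
    """Base class for runtime failures inside the pipeline."""


class ConfigError(TeamNeuroError):
    """Invalid configuration or precondition, detected before computing."""


class AlignmentError(TeamNeuroError):
    """Recordings or tensors cannot be placed on a common task clock."""
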