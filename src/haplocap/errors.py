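"""Exception hierarchy for haplocap."""


class HaplocapError(Exception):
    """Base class for all haplocap errors."""


class ConfigError(HaplocapError):
    """Invalid or inconsistent configuration."""


class ValidationError(HaplocapError):
    """Input data violates a documented precondition."""


class DesignInfeasibleError(HaplocapError):
    """Probe design cannot proceed (e.g. no candidate probes at all)."""


class AlignmentParseError(HaplocapError):
    """A PAF/SAM alignment file could not be parsed."""
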