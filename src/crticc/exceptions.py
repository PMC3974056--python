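"""Exception hierarchy for crticc."""


class CRTICCError(Exception):
    """Base class for all crticc errors."""


class InputError(CRTICCError, ValueError):
    """Malformed input data (missing columns, impossible counts, bad domain)."""


class ConsistencyError(CRTICCError, ValueError):
    """Internally inconsistent data, e.g. a cluster assigned to two arms."""


class DegenerateDataError(CRTICCError, ValueError):
    """Data carry no information about the ICC (zero variance everywhere).

    Carries a ``reason`` attribute describing the degeneracy.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class ConvergenceError(CRTICCError, RuntimeError):
    """An iterative fit (or too many bootstrap refits) failed to converge."""


class ConfigError(CRTICCError, ValueError):
    """Invalid simulation or estimator configuration."""
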