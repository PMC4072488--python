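"""Exception hierarchy for cutscan."""


class CutscanError(Exception):
    """Base class for all cutscan errors."""


class ConfigError(CutscanError, ValueError):
    """Invalid configuration; the message names the offending field."""


class SchemaError(CutscanError, ValueError):
    """Input table is missing or mistyping a required column."""


class DegenerateDesignError(CutscanError, ValueError):
    """Design matrix is degenerate (constant column or singular information)."""


class ConvergenceError(CutscanError, RuntimeError):
    """An operation requires a converged fit but the fit did not converge."""


class DegenerateCutError(CutscanError, ValueError):
    """A dichotomization cutoff put every subject on one side."""


class ScanFailureError(CutscanError, RuntimeError):
    """Fewer than four usable cutpoints survived the scan."""
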