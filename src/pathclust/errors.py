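"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config errors -> 2, data errors -> 3),
so library code should raise the most specific class that applies.
"""


class PathclustError(Exception):
    """Base class for all package errors."""


class ConfigError(PathclustError):
    """A parameter or configuration value is invalid."""


class DataError(PathclustError):
    """Input data is malformed or violates a precondition."""


class NonMonotoneCostError(PathclustError):
    """A path-cost functional decreased while extending a path.

    Dijkstra's correctness requires the accumulated path cost to be
    non-decreasing under extension; a functional that violates this
    contract must be rejected loudly rather than produce silently
    wrong clusters.
    """
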