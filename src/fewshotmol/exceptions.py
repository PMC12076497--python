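"""Exception hierarchy.

Every error class carries a distinct ``exit_code`` so the command-line
front end can map failures to stable process exit statuses.
"""


class FewshotError(Exception):
    """Base class for all package errors."""

    exit_code = 1


# --- molecule / feature errors -------------------------------------------
class InvalidSmiles(FewshotError):
    """SMILES string could not be parsed into a molecule."""

    exit_code = 3


class EmptyInput(FewshotError):
    """Blank or whitespace-only input where a SMILES was expected."""

    exit_code = 3


class FeaturizationError(FewshotError):
    """Descriptor or fingerprint computation failed for a valid parse."""

    exit_code = 3


# --- I/O errors ------------------------------------------------------------
class MissingColumn(FewshotError):
    exit_code = 7


class EmptyFile(FewshotError):
    exit_code = 7


# --- model errors -----------------------------------------------------------
class DimensionMismatch(FewshotError):
    exit_code = 4


class EmptyContext(FewshotError):
    exit_code = 4


class ZeroVector(FewshotError):
    """A zero-norm embedding makes cosine similarity undefined."""

    exit_code = 4


class EmptySupportClass(FewshotError):
    """A support set must contain at least one active and one inactive."""

    exit_code = 4


class OneClassSupport(EmptySupportClass):
    """Baseline fit received a single-class support set."""


# --- benchmark / training errors -------------------------------------------
class InsufficientTask(FewshotError):
    """Task too small to satisfy the requested support composition."""

    exit_code = 5


class NoTasksSurvive(FewshotError):
    exit_code = 6


class NoValidTasks(FewshotError):
    exit_code = 6


class NonFiniteLoss(FewshotError):
    exit_code = 6


class ConfigError(FewshotError):
    exit_code = 8


class TooFewMolecules(FewshotError):
    exit_code = 5


# --- metric errors -----------------------------------------------------------
class OneClassOnly(FewshotError):
    """Metric requires both classes among the evaluated labels."""

    exit_code = 4


class TooFewPairs(FewshotError):
    exit_code = 4


class AllZeroDifferences(FewshotError):
    """Paired test undefined: every paired difference is exactly zero."""

    exit_code = 4
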