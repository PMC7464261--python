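"""Exception hierarchy.

Every failure mode the model can hit maps to a distinct exception so that
callers (and the CLI) can fail fast with a message naming the offending
score, regimen or graph gap rather than a bare KeyError.
"""


class AfacsError(Exception):
    """Base class for all package errors."""


class MissingScoreError(AfacsError, KeyError):
    """A CHA2DS2-VASc score absent from a risk table (no silent extrapolation)."""

    def __init__(self, score: int, table_name: str = "risk table"):
        self.score = score
        super().__init__(f"score {score} not present in {table_name}")

    def __str__(self) -> str:  # KeyError quotes its repr otherwise
        return self.args[0]


class ChainMismatchError(AfacsError):
    """A treatment-effect chain whose comparator does not match the preceding regimen."""

    def __init__(self, expected: str, found: str):
        self.expected = expected
        self.found = found
        super().__init__(
            f"effect chain broken: expected comparator {expected!r}, found {found!r}"
        )


class UnknownRegimenError(AfacsError, KeyError):
    def __init__(self, name: str):
        self.name = name
        super().__init__(f"regimen {name!r} is not registered for this endpoint")

    def __str__(self) -> str:
        return self.args[0]


class CalibrationError(AfacsError):
    """Calibration anchors implying an invalid (e.g. non-monotone) rate table."""


class PathBrokenError(AfacsError):
    """A hazard-ratio path with no direct edge between two consecutive regimens."""

    def __init__(self, a: str, b: str):
        self.gap = (a, b)
        super().__init__(f"no direct comparison between {a!r} and {b!r}")


class NoPathError(AfacsError):
    """Two regimens in disconnected components of the hazard-ratio graph."""


class InsufficientRangeError(AfacsError):
    """A trade-off curve too short to locate an equipoise score."""


class DomainError(AfacsError, ValueError):
    """A parameter outside the mathematical domain of a formula."""


class ScenarioValidationError(AfacsError):
    """Invalid scenario configuration; collects every missing key at once."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid scenario: " + "; ".join(self.problems))
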