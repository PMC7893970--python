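"""Exception taxonomy.

Validation problems (bad input data, broken referential integrity, malformed
cells) derive from :class:`ValidationError`; everything that goes wrong during
computation (rank-deficient designs, failed fits, pipeline stages) derives from
:class:`ComputationError`.  The CLI maps the two branches to exit codes 1 and 2.
"""

from __future__ import annotations


class FancfidError(Exception):
    """Base class for all package errors."""


class ValidationError(FancfidError):
    """Invalid domain data: a record or cohort violates an invariant."""


class ParseError(ValidationError):
    """A malformed cell in a delimited input file.

    Carries the offending row (0-based data row, header excluded) and column
    so survey files can be fixed in place.
    """

    def __init__(self, message: str, *, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)


class ReferentialIntegrityError(ValidationError):
    """A woman references a cluster_id with no matching cluster record."""


class ConfigError(FancfidError):
    """Invalid generator or pipeline configuration."""


class ComputationError(FancfidError):
    """A numerical or model-building step failed."""


class RankError(ComputationError):
    """Design matrix is rank deficient."""


class ModelSpecificationError(ComputationError):
    """A model term does not resolve to a usable column."""


class PipelineError(ComputationError):
    """A pipeline stage failed; names the stage and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")
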