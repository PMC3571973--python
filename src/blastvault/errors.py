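"""Exception hierarchy shared by all blastvault layers.

Every error raised on purpose by the package derives from
:class:`BlastVaultError`, so callers embedding the library in a pipeline can
catch one base class.  Parse-level problems carry the (approximate) line
number of the offending block so diagnostics stay actionable on multi-
gigabyte reports.
"""

from __future__ import annotations


class BlastVaultError(Exception):
    """Base class for all blastvault errors."""


class NotABlastReportError(BlastVaultError):
    """The input contains no ``Query=`` anchor and cannot be a BLAST report."""


class CorruptBlockError(BlastVaultError):
    """A query block is malformed (truncated, mangled, or missing a section).

    In the default skip-and-diagnose mode the report parser converts this
    into a diagnostic and moves to the next block; in strict mode it
    propagates.
    """

    def __init__(self, message: str, line_number: int = 0):
        super().__init__(message)
        self.line_number = line_number


class StorageIOError(BlastVaultError):
    """The store file cannot be created, written or read."""


class IncompatibleStoreError(BlastVaultError):
    """The file is not a blastvault store or has an unsupported format tag."""


class MissingQueryError(BlastVaultError, KeyError):
    """No record for the requested query id."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message.
        return BlastVaultError.__str__(self)


class ClosedStoreError(BlastVaultError):
    """Operation attempted on a closed store handle."""


class CorruptModelError(BlastVaultError):
    """A model object violates its structural invariants."""


class InvalidThresholdError(BlastVaultError, ValueError):
    """A filter threshold is outside its legal range."""


class InvalidSpecError(BlastVaultError, ValueError):
    """A fixture GeneratorSpec is infeasible or out of range."""
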