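"""Exception hierarchy with stable CLI exit codes.

Exit-code contract: 0 success, 1 user/input error, 2 data-integrity
error, 3 not-found.  Every exception raised by the library maps to
exactly one code via its class.
"""


class RefsmithError(Exception):
    """Base class; user/input errors (exit code 1)."""

    exit_code = 1


class FormatError(RefsmithError):
    """Malformed input file (bad FASTA layout, bad GTF line, ...)."""


class QueryError(RefsmithError):
    """Invalid search query (empty/whitespace-only)."""


class FieldError(RefsmithError):
    """Unknown column/attribute field requested."""


class SchemeError(RefsmithError):
    """Unknown contig-naming scheme label."""


class BoundsError(RefsmithError):
    """Region exceeds contig bounds; no silent clamping."""


class PatternError(RefsmithError):
    """Regex pattern failed to compile."""


class SamplingError(RefsmithError):
    """No valid start position exists for random region sampling."""


class SpecError(RefsmithError):
    """Infeasible fixture specification."""


class IntegrityError(RefsmithError):
    """Internal consistency violated: duplicates, overlaps, ambiguous
    mappings, cyclic Parent links (exit code 2)."""

    exit_code = 2


class NotFoundError(RefsmithError):
    """Assembly/provider/contig not found (exit code 3)."""

    exit_code = 3


class LookupFailure(NotFoundError):
    """Unknown contig name in an index lookup."""


class ProviderUnavailableError(NotFoundError):
    """Provider metadata table missing from the cache root."""


class InstallExistsError(RefsmithError):
    """Refusing to overwrite an existing install without --force."""
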