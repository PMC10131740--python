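"""Exception hierarchy for the harmonization pipeline.

Data-quality failures discovered during validation are *data*, not
exceptions (they become ValidationReports); exceptions are reserved for
contract violations: malformed inputs, misconfiguration, broken identity.
"""


class TabfhirError(Exception):
    """Base class for all package errors."""


class SchemaError(TabfhirError):
    """A table does not match its declared schema (missing/extra columns,
    missing join key)."""


class TableIntegrityError(TabfhirError):
    """Duplicate primary-key tuple within a source table."""


class ParseError(TabfhirError):
    """A non-nullable cell failed to parse as its declared value kind."""


class UnknownTableError(TabfhirError, KeyError):
    """A table name is not registered / not present."""


class IdentityError(TabfhirError):
    """A resource id or reference cannot be minted (null key component)."""


class UnknownVocabularyError(TabfhirError, KeyError):
    """Coding-system lookup for an unregistered vocabulary."""


class ConfigurationError(TabfhirError):
    """Invalid run/export/cohort configuration, or a missing profile."""


class ExportError(TabfhirError):
    """Flat export failed (unresolvable feature name, I/O failure)."""


class StorageError(TabfhirError):
    """Document store could not serialize or persist a resource."""


class StageOrderError(TabfhirError):
    """A pipeline stage was invoked before its prerequisite artifacts exist."""


class UnknownStageError(TabfhirError, KeyError):
    """run_stage called with a name outside the five pipeline stages."""


class UnknownDefectError(ConfigurationError):
    """Defect injection requested an unregistered defect kind."""
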