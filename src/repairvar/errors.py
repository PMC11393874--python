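"""Exception hierarchy. Everything raised on purpose derives from RepairVarError."""


class RepairVarError(Exception):
    """Base class for all package errors."""


class InputError(RepairVarError):
    """A value violates a domain invariant (negative CADD, AF outside [0,1], ...)."""


class SchemaError(RepairVarError):
    """The VCF CSQ meta-line is missing or lacks a required field."""


class RecordError(RepairVarError):
    """A VCF record or CSQ entry could not be parsed."""


class TableError(RepairVarError):
    """A flat TSV table has unknown columns or an unparseable cell."""


class PanelError(RepairVarError):
    """The gene panel is inconsistent (duplicate symbol, conflicting ids)."""


class MergeError(RepairVarError):
    """Caller callsets cannot be intersected (e.g. mixed reference builds)."""


class CohortError(RepairVarError):
    """Patient records are inconsistent (duplicate id, dangling variant ref)."""


class ConfigError(RepairVarError):
    """A filter or simulation configuration violates its invariants."""


class FixtureIntegrityError(RepairVarError):
    """A packaged fixture does not match its recorded checksum."""
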