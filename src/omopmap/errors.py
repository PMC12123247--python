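"""Exception hierarchy shared across the package."""


class OmopMapError(Exception):
    """Base class for all package errors."""


class InputError(OmopMapError):
    """A required input file is missing or unreadable."""


class SchemaError(OmopMapError):
    """A file does not carry the mandatory columns/headers; names the culprit."""


class IntegrityError(OmopMapError):
    """Cross-record consistency violated (duplicate ids, dangling references)."""


class ContractError(OmopMapError):
    """A caller violated an operation precondition (dimension mismatch, gold gaps)."""
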