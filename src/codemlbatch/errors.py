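"""Exception hierarchy shared across the package."""


class CodemlBatchError(Exception):
    """Base class for all package errors."""


class ParseError(CodemlBatchError):
    """A filename, control file, tree or result file failed to parse."""


class ValidationError(CodemlBatchError):
    """An input violated a documented constraint."""
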