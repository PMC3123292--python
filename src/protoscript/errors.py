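"""Exception hierarchy for the protoscript engine."""

from __future__ import annotations


class ProtoScriptError(Exception):
    """Base class for all protoscript errors."""


class ScriptSyntaxError(ProtoScriptError):
    """Malformed protocol-script text. Carries the 1-based line/column."""

    def __init__(self, message: str, line: int | None = None, col: int | None = None):
        self.line = line
        self.col = col
        if line is not None:
            message = f"line {line}, col {col}: {message}"
        super().__init__(message)


class OptionError(ProtoScriptError):
    """Missing or unconvertible tag option."""


class ValidationError(ProtoScriptError):
    """Script-level structural violation (top tag, required sections)."""


class RegistryError(ProtoScriptError):
    pass


class UnknownComponentError(RegistryError):
    """No creator registered under the requested name."""


class DuplicateRegistrationError(RegistryError):
    pass


class NotImplementedComponentError(RegistryError):
    """The name is recognized (it appears in published protocols) but the
    component is not part of this engine; it can be supplied as a plugin."""


class DataMapError(ProtoScriptError):
    pass


class DataMapKeyError(DataMapError):
    pass


class DataMapTypeError(DataMapError):
    """Stored object kind does not match the requested kind."""


class StructureError(ProtoScriptError):
    pass


class PDBFormatError(StructureError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TaskError(ProtoScriptError):
    pass


class ResfileError(TaskError):
    pass


class ProtocolError(ProtoScriptError):
    pass
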