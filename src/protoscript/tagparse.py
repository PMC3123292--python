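"""Parser for the XML-like protocol-script dialect.

The dialect is deliberately *not* XML.  A script is a single recursive tag
tree; anything outside ``<...>`` brackets is free comment text and is
ignored.  Option values may be bare tokens with whitespace permitted around
the ``=`` sign (``name = design``), or double-quoted strings which may
contain whitespace (``native="inputs/native.pdb"``).  Because of these
relaxations, published protocol scripts are rejected by strict XML parsers,
so a dedicated recursive-descent parser is used here.

Grammar (EBNF)::

    Tag    := '<' Name Option* '>' Tag* '</' Name '>'  |  '<' Name Option* '/>'
    Option := Name '=' Value
    Name   := token without whitespace or any of  < > = / "
    Value  := bare token  |  '"' text without quotes or angle brackets '"'

All syntax errors report a 1-based line and column.
"""

from __future__ import annotations

import bisect
from typing import Callable, Iterable, Iterator, Sequence, TypeVar, overload

from .errors import OptionError, ScriptSyntaxError, ValidationError

__all__ = [
    "Tag",
    "ScriptModel",
    "parse_script",
    "write_tag",
    "RECOGNIZED_SECTIONS",
]

T = TypeVar("T")

_NAME_FORBIDDEN = set('<>=/"')
_WS = " \t\r\n"

_MISSING = object()


def _check_token(token: str, what: str) -> str:
    if not token:
        raise ValueError(f"{what} must be non-empty")
    if any(c in _NAME_FORBIDDEN or c in _WS for c in token):
        raise ValueError(
            f"{what} {token!r} contains whitespace or one of the characters <>=/\""
        )
    return token


def _flag(text: str) -> bool:
    low = text.strip().lower()
    if low in ("1", "true"):
        return True
    if low in ("0", "false"):
        return False
    raise ValueError(f"{text!r} is not a flag (expected 0/1/true/false)")


def _converter(as_type: type) -> Callable[[str], object]:
    if as_type is bool:
        return _flag
    if as_type is int:
        return lambda s: int(s.strip(), 10)
    if as_type is float:
        return lambda s: float(s.strip())
    if as_type is str:
        return lambda s: s
    raise TypeError(f"unsupported option type {as_type!r}")


class Tag:
    """A node of the script syntax tree.

    ``options`` is an ordered mapping of option key to raw string value;
    ``subtags`` is the ordered list of child tags.  Keys are unique within a
    tag; a self-closing tag simply has no subtags.
    """

    __slots__ = ("name", "_options", "subtags", "line", "col")

    def __init__(
        self,
        name: str,
        options: Iterable[tuple[str, object]] | dict | None = None,
        subtags: Sequence["Tag"] | None = None,
        line: int | None = None,
        col: int | None = None,
    ):
        self.name = _check_token(name, "tag name")
        self._options: dict[str, str] = {}
        pairs = options.items() if isinstance(options, dict) else (options or [])
        for key, value in pairs:
            _check_token(key, "option key")
            value = str(value)
            if any(c in '<>"' for c in value):
                raise ValueError(
                    f"option {key}={value!r}: values may not contain quotes or angle brackets"
                )
            if key in self._options:
                raise ValueError(f"duplicate option key {key!r} in tag <{name}>")
            self._options[key] = value
        self.subtags: list[Tag] = list(subtags or [])
        self.line = line
        self.col = col

    # -- options ---------------------------------------------------------

    @property
    def options(self) -> dict[str, str]:
        """Ordered key -> raw value mapping (do not mutate)."""
        return self._options

    def has_option(self, key: str) -> bool:
        return key in self._options

    @overload
    def get_option(self, key: str) -> str: ...
    @overload
    def get_option(self, key: str, as_type: type[T]) -> T: ...
    @overload
    def get_option(self, key: str, as_type: type[T], default: T | None) -> T | None: ...

    def get_option(self, key, as_type=str, default=_MISSING):
        """Typed access to one option.

        ``as_type`` is one of ``str``, ``int``, ``float`` or ``bool``
        (flags accept 0/1/true/false).  A missing key returns ``default``
        when given and raises :class:`OptionError` otherwise.
        """
        if key not in self._options:
            if default is not _MISSING:
                return default
            raise OptionError(
                f"tag <{self.name}> has no option {key!r}"
                + (f" (line {self.line})" if self.line else "")
            )
        raw = self._options[key]
        try:
            return _converter(as_type)(raw)
        except ValueError as exc:
            raise OptionError(
                f"option {key}={raw!r} of tag <{self.name}>: {exc}"
            ) from exc

    def get_option_list(self, key, as_type=str, default=_MISSING, sep=","):
        """Comma-separated list variant of :meth:`get_option`."""
        if key not in self._options:
            if default is not _MISSING:
                return default
            raise OptionError(f"tag <{self.name}> has no option {key!r}")
        conv = _converter(as_type)
        raw = self._options[key]
        try:
            return [conv(part) for part in raw.split(sep) if part.strip() != ""]
        except ValueError as exc:
            raise OptionError(
                f"option {key}={raw!r} of tag <{self.name}>: {exc}"
            ) from exc

    # -- subtags ---------------------------------------------------------

    def get_tags(self, name: str) -> list["Tag"]:
        """Direct children named ``name``, in document order."""
        return [t for t in self.subtags if t.name == name]

    def get_tag(self, name: str) -> "Tag | None":
        """First direct child named ``name``, or None."""
        for t in self.subtags:
            if t.name == name:
                return t
        return None

    # -- identity and output --------------------------------------------

    def __eq__(self, other) -> bool:
        """Structural equality: name, ordered options, ordered subtags."""
        if not isinstance(other, Tag):
            return NotImplemented
        return (
            self.name == other.name
            and list(self._options.items()) == list(other._options.items())
            and self.subtags == other.subtags
        )

    def __hash__(self):
        return hash((self.name, tuple(self._options.items()), tuple(self.subtags)))

    def __repr__(self):
        return f"Tag({self.name!r}, {len(self._options)} options, {len(self.subtags)} subtags)"

    def write(self, indent: int = 0) -> str:
        """Canonical text form: one tag per line, two-space indent,
        every value double-quoted."""
        pad = "  " * indent
        opts = "".join(f' {k}="{v}"' for k, v in self._options.items())
        if not self.subtags:
            return f"{pad}<{self.name}{opts}/>"
        lines = [f"{pad}<{self.name}{opts}>"]
        lines.extend(t.write(indent + 1) for t in self.subtags)
        lines.append(f"{pad}</{self.name}>")
        return "\n".join(lines)


def write_tag(tag: Tag) -> str:
    """Serialize a tag tree to canonical text; ``parse_script(write_tag(t))``
    is structurally equal to ``t``."""
    return tag.write() + "\n"


# ---------------------------------------------------------------------------
# recursive-descent parser


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.n = len(text)
        self.i = 0
        self._line_starts = [0]
        for idx, ch in enumerate(text):
            if ch == "\n":
                self._line_starts.append(idx + 1)

    def _lc(self, idx: int) -> tuple[int, int]:
        row = bisect.bisect_right(self._line_starts, idx) - 1
        return row + 1, idx - self._line_starts[row] + 1

    def error(self, message: str, idx: int | None = None) -> ScriptSyntaxError:
        line, col = self._lc(self.i if idx is None else idx)
        return ScriptSyntaxError(message, line, col)

    def skip_ws(self) -> None:
        while self.i < self.n and self.text[self.i] in _WS:
            self.i += 1

    def read_name(self, what: str) -> str:
        start = self.i
        while self.i < self.n:
            c = self.text[self.i]
            if c in _WS or c in _NAME_FORBIDDEN:
                break
            self.i += 1
        token = self.text[start : self.i]
        if not token:
            raise self.error(f"expected {what}", start)
        return token

    def read_value(self, key: str, tagname: str) -> str:
        text, n = self.text, self.n
        if self.i < n and text[self.i] == '"':
            start = self.i
            self.i += 1
            vstart = self.i
            while self.i < n and text[self.i] != '"':
                if text[self.i] in "<>":
                    raise self.error(
                        f"angle bracket inside quoted value of option {key!r}"
                    )
                self.i += 1
            if self.i >= n:
                raise self.error(
                    f"unterminated quoted value for option {key!r} of tag <{tagname}>",
                    start,
                )
            value = text[vstart : self.i]
            self.i += 1  # closing quote
            return value
        start = self.i
        while self.i < n:
            c = text[self.i]
            if c in _WS or c in '>"':
                break
            if c == "<":
                raise self.error(f"'<' inside value of option {key!r}")
            if c == "/" and self.i + 1 < n and text[self.i + 1] == ">":
                break
            self.i += 1
        value = text[start : self.i]
        if not value:
            raise self.error(f"empty value for option {key!r} of tag <{tagname}>", start)
        return value

    def parse_tag(self) -> Tag:
        assert self.text[self.i] == "<"
        open_idx = self.i
        line, col = self._lc(open_idx)
        self.i += 1
        self.skip_ws()
        name = self.read_name("tag name after '<'")
        options: list[tuple[str, str]] = []
        seen: set[str] = set()
        while True:
            self.skip_ws()
            if self.i >= self.n:
                raise self.error(f"unterminated tag <{name}>", open_idx)
            c = self.text[self.i]
            if c == "/":
                self.i += 1
                self.skip_ws()
                if self.i >= self.n or self.text[self.i] != ">":
                    raise self.error(f"expected '>' after '/' in tag <{name}>")
                self.i += 1
                return Tag(name, options, [], line=line, col=col)
            if c == ">":
                self.i += 1
                subtags = self.parse_body(name, open_idx)
                return Tag(name, options, subtags, line=line, col=col)
            if c in '<>="':
                raise self.error(f"unexpected {c!r} in tag <{name}>")
            key_idx = self.i
            key = self.read_name("option key")
            self.skip_ws()
            if self.i >= self.n or self.text[self.i] != "=":
                raise self.error(
                    f"option {key!r} of tag <{name}> is missing '='", key_idx
                )
            self.i += 1
            self.skip_ws()
            value = self.read_value(key, name)
            if key in seen:
                raise self.error(
                    f"duplicate option key {key!r} in tag <{name}>", key_idx
                )
            seen.add(key)
            options.append((key, value))

    def parse_body(self, name: str, open_idx: int) -> list[Tag]:
        subtags: list[Tag] = []
        while True:
            nxt = self.text.find("<", self.i)
            if nxt == -1:
                raise self.error(
                    f"tag <{name}> is never closed (missing </{name}>)", open_idx
                )
            self.i = nxt
            # closing tag?
            j = nxt + 1
            while j < self.n and self.text[j] in _WS:
                j += 1
            if j < self.n and self.text[j] == "/":
                self.i = j + 1
                self.skip_ws()
                close_idx = self.i
                close_name = self.read_name("closing tag name")
                self.skip_ws()
                if self.i >= self.n or self.text[self.i] != ">":
                    raise self.error(f"expected '>' after closing tag </{close_name}")
                self.i += 1
                if close_name != name:
                    raise self.error(
                        f"closing tag </{close_name}> does not match opening tag <{name}>",
                        close_idx,
                    )
                return subtags
            subtags.append(self.parse_tag())


def parse_script(text: str) -> Tag:
    """Parse protocol-script text into its single top-level :class:`Tag`.

    Text outside ``<...>`` brackets is treated as comments and discarded.
    Raises :class:`ScriptSyntaxError` (with line/column) on mismatched or
    unterminated tags, options without ``=``, duplicate option keys, or
    more than one top-level tag.
    """
    parser = _Parser(text)
    first = text.find("<")
    if first == -1:
        raise ScriptSyntaxError("no tag found in script text")
    parser.i = first
    tag = parser.parse_tag()
    trailing = text.find("<", parser.i)
    if trailing != -1:
        parser.i = trailing
        raise parser.error("more than one top-level tag")
    return tag


# ---------------------------------------------------------------------------
# script-level structure

RECOGNIZED_SECTIONS = (
    "SCOREFXNS",
    "TASKOPERATIONS",
    "FILTERS",
    "MOVERS",
    "PROTOCOLS",
)

#: required sections; everything else is optional
REQUIRED_SECTIONS = ("MOVERS", "PROTOCOLS")


class ScriptModel:
    """A validated protocol script: the ROSETTASCRIPTS root tag, the
    recognized top-level sections, and any pass-through extra sections
    (e.g. LIGAND_AREAS)."""

    def __init__(self, root: Tag):
        if root.name != "ROSETTASCRIPTS":
            raise ValidationError(
                f"top-level tag must be <ROSETTASCRIPTS>, got <{root.name}>"
            )
        self.root = root
        self.sections: dict[str, Tag] = {}
        self.extras: list[Tag] = []
        for sub in root.subtags:
            if sub.name in RECOGNIZED_SECTIONS:
                if sub.name in self.sections:
                    raise ValidationError(f"section <{sub.name}> appears twice")
                self.sections[sub.name] = sub
            else:
                self.extras.append(sub)
        for required in REQUIRED_SECTIONS:
            if required not in self.sections:
                raise ValidationError(f"required section <{required}> is missing")

    @classmethod
    def from_text(cls, text: str) -> "ScriptModel":
        return cls(parse_script(text))

    def section(self, name: str) -> Tag | None:
        return self.sections.get(name)

    def extra_section(self, name: str) -> Tag | None:
        for t in self.extras:
            if t.name == name:
                return t
        return None

    def __repr__(self):
        return f"ScriptModel(sections={sorted(self.sections)}, extras={[t.name for t in self.extras]})"
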