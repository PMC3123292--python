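"""Two-level named registry shared between components during parsing.

The DataMap is a map from category strings to maps from object names to
*shared* handles: every retrieval of the same ``(category, name)`` returns
the same object, so a mutation made through one handle is observed through
all others.  Conventional categories used by the built-ins are
``"scorefxns"`` and ``"task_operations"``, but categories are free-form.

The DataMap itself only lives through parsing; components keep the handles
they captured, so executing a protocol after the DataMap is discarded works.
"""

from __future__ import annotations

from .errors import DataMapKeyError, DataMapTypeError

__all__ = ["DataMap"]


class DataMap:
    def __init__(self):
        self._data: dict[str, dict[str, object]] = {}

    def put(self, category: str, name: str, obj: object) -> None:
        """Store a handle; duplicate ``(category, name)`` pairs are an error."""
        cat = self._data.setdefault(category, {})
        if name in cat:
            raise DataMapKeyError(
                f"({category!r}, {name!r}) already holds a "
                f"{type(cat[name]).__name__}"
            )
        cat[name] = obj

    def put_default(self, category: str, name: str, obj: object) -> bool:
        """Store only if absent; returns True when stored."""
        cat = self._data.setdefault(category, {})
        if name in cat:
            return False
        cat[name] = obj
        return True

    def get(self, category: str, name: str, expected_kind: type | None = None):
        """Retrieve the shared handle, with an optional kind check that
        reports the stored kind against the requested one."""
        if category not in self._data:
            raise DataMapKeyError(
                f"no category {category!r} (have {sorted(self._data)})"
            )
        cat = self._data[category]
        if name not in cat:
            raise DataMapKeyError(
                f"no object {name!r} in category {category!r} (have {sorted(cat)})"
            )
        obj = cat[name]
        if expected_kind is not None and not isinstance(obj, expected_kind):
            raise DataMapTypeError(
                f"({category!r}, {name!r}) holds a {type(obj).__name__}, "
                f"not the requested {expected_kind.__name__}"
            )
        return obj

    def has(self, category: str, name: str) -> bool:
        return name in self._data.get(category, {})

    def categories(self) -> list[str]:
        return list(self._data)

    def names(self, category: str) -> list[str]:
        return list(self._data.get(category, {}))

    def __repr__(self):
        inner = {c: sorted(m) for c, m in self._data.items()}
        return f"DataMap({inner})"
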