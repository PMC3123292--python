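"""Factory / creator / registrator scheme for components named in scripts.

Three singleton factories (movers, filters, task operations) each hold a map
from a component's key name to a :class:`Creator`.  Instantiating a component
never parses its options: ``create()`` returns a fresh, unconfigured
instance, and the caller invokes ``parse_my_tag`` separately.

Third-party components join the engine at run time::

    from protoscript import registry

    class CountingMover(Mover):
        key_name = "CountingMover"
        def apply(self, pose):
            self.count += 1
            return Status.SUCCESS

    registry.register_creator(registry.mover_factory,
                              registry.Creator("CountingMover", CountingMover))

after which any script may declare ``<CountingMover name = c/>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .errors import (
    DuplicateRegistrationError,
    NotImplementedComponentError,
    UnknownComponentError,
)

__all__ = [
    "Creator",
    "Factory",
    "register_creator",
    "create",
    "mover_factory",
    "filter_factory",
    "task_operation_factory",
    "init_builtins",
]


@dataclass(frozen=True)
class Creator:
    """Binds a unique key name to a nullary constructor of one component."""

    key_name: str
    make: Callable[[], object]


def levenshtein(a: str, b: str) -> int:
    """Plain edit distance (insert/delete/substitute, unit costs)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@dataclass
class Factory:
    """One registry per component category; all lookups in a run share it."""

    category: str
    _creators: dict[str, Creator] = field(default_factory=dict)

    def register(self, creator: Creator) -> None:
        if not creator.key_name:
            raise DuplicateRegistrationError("creator key name must be non-empty")
        existing = self._creators.get(creator.key_name)
        if existing is not None:
            raise DuplicateRegistrationError(
                f"{self.category} name {creator.key_name!r} is already registered "
                f"(by {existing.make!r})"
            )
        self._creators[creator.key_name] = creator

    def create(self, name: str) -> object:
        """Fresh instance per call; unknown names list the closest
        registered names by edit distance."""
        creator = self._creators.get(name)
        if creator is None:
            close = sorted(
                (n for n in self._creators if levenshtein(name, n) <= 3),
                key=lambda n: (levenshtein(name, n), n),
            )[:5]
            hint = f"; did you mean one of {close}?" if close else ""
            raise UnknownComponentError(
                f"no {self.category} named {name!r} is registered{hint}"
            )
        return creator.make()

    def names(self) -> list[str]:
        return list(self._creators)

    def __contains__(self, name: str) -> bool:
        return name in self._creators

    def __len__(self) -> int:
        return len(self._creators)


def register_creator(factory: Factory, creator: Creator) -> None:
    factory.register(creator)


def create(factory: Factory, name: str):
    return factory.create(name)


def placeholder_creator(name: str, category: str) -> Creator:
    """Creator for a name that appears in published protocols but whose
    component is outside this engine; instantiation fails loudly at
    declaration time with a pointer to the plugin API."""

    def make():
        raise NotImplementedComponentError(
            f"{category} {name!r} is recognized but not implemented in this "
            f"engine; supply it as a plugin by registering your own Creator "
            f"under this name (see protoscript.registry)"
        )

    return Creator(name, make)


mover_factory = Factory("mover")
filter_factory = Factory("filter")
task_operation_factory = Factory("task_operation")

_initialized = False


def init_builtins() -> None:
    """Register every built-in mover, filter and task operation.

    Must be called before parsing any script; idempotent, so libraries and
    entry points may all call it defensively.
    """
    global _initialized
    if _initialized:
        return
    from .packing import taskops as _taskops
    from .protocol import builtins as _builtins

    _builtins.register_builtins(mover_factory, filter_factory)
    _taskops.register_builtins(task_operation_factory)
    _initialized = True


def _reset_for_testing() -> None:
    """Clear all factories (test isolation only)."""
    global _initialized
    mover_factory._creators.clear()
    filter_factory._creators.clear()
    task_operation_factory._creators.clear()
    _initialized = False
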