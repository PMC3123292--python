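"""ParsedProtocol: the ordered mover/filter sequence of one trajectory.

Each step applies its mover (if any) and then evaluates its filter (if any)
through the confidence gate.  A mover failure or a filter failure aborts
the remaining steps and returns ``FAIL_RETRY`` -- the job distributor then
restarts the trajectory from a freshly loaded structure.  A ParsedProtocol
is itself a mover, so protocols may be aggregated and nested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ..datamap import DataMap
from ..errors import ProtocolError, ValidationError
from ..registry import filter_factory, mover_factory
from ..tagparse import Tag
from .base import Filter, Mover, Status, filter_gate, pose_rng

__all__ = [
    "ProtocolStep",
    "ParsedProtocol",
    "parse_movers_and_filters",
    "parse_protocols",
]

log = logging.getLogger("protoscript")


@dataclass
class ProtocolStep:
    mover: Mover | None = None
    filter: Filter | None = None

    def __post_init__(self):
        if self.mover is None and self.filter is None:
            raise ProtocolError("a protocol step needs a mover or a filter")


def _resolve_step(tag: Tag, movers: dict, filters: dict) -> ProtocolStep:
    """Build one step from an <Add .../> tag; both option spellings
    mover/mover_name and filter/filter_name are accepted."""
    mover_name = tag.get_option("mover", str, None) or tag.get_option(
        "mover_name", str, None
    )
    filter_name = tag.get_option("filter", str, None) or tag.get_option(
        "filter_name", str, None
    )
    mover = filt = None
    if mover_name is not None:
        if mover_name not in movers:
            raise ProtocolError(
                f"<Add> refers to undeclared mover {mover_name!r} "
                f"(declared: {sorted(movers)})"
            )
        mover = movers[mover_name]
    if filter_name is not None:
        if filter_name not in filters:
            raise ProtocolError(
                f"<Add> refers to undeclared filter {filter_name!r} "
                f"(declared: {sorted(filters)})"
            )
        filt = filters[filter_name]
    return ProtocolStep(mover=mover, filter=filt)


class ParsedProtocol(Mover):
    key_name = "ParsedProtocol"

    def __init__(self, steps: list[ProtocolStep] | None = None):
        super().__init__()
        self.steps: list[ProtocolStep] = list(steps or [])

    def parse_my_tag(self, tag, data, filters, movers):
        self.steps = [_resolve_step(sub, movers, filters) for sub in tag.get_tags("Add")]

    def apply(self, pose) -> Status:
        if not self.steps:
            raise ProtocolError(f"protocol {self.name or ''} has no steps")
        for k, step in enumerate(self.steps, 1):
            if step.mover is not None:
                status = step.mover.apply(pose)
                log.info(
                    "step %d mover %s -> %s",
                    k,
                    step.mover.name or step.mover.key_name,
                    status.value,
                )
                if status is Status.FAIL_RETRY:
                    return Status.FAIL_RETRY
            if step.filter is not None:
                passed = filter_gate(step.filter, pose, pose_rng(pose))
                log.info(
                    "step %d filter %s -> %s",
                    k,
                    step.filter.name or step.filter.key_name,
                    "pass" if passed else "fail",
                )
                if not passed:
                    return Status.FAIL_RETRY
        return Status.SUCCESS

    def iter_movers(self):
        yield self
        for step in self.steps:
            if step.mover is not None:
                yield from step.mover.iter_movers()

    def filters(self) -> list[Filter]:
        return [s.filter for s in self.steps if s.filter is not None]


def parse_movers_and_filters(
    model, data: DataMap
) -> tuple[dict[str, Mover], dict[str, Filter]]:
    """Instantiate the FILTERS and MOVERS sections.

    Each subtag is dispatched through its factory by tag name; the
    mandatory ``name`` option keys the instance into the returned maps.
    ``parse_my_tag`` receives the DataMap plus both maps, so components can
    capture references to previously declared instances.
    """
    movers: dict[str, Mover] = {}
    filters: dict[str, Filter] = {}
    filters_section = model.section("FILTERS")
    if filters_section is not None:
        for sub in filters_section.subtags:
            instance = filter_factory.create(sub.name)
            name = _require_name(sub)
            if name in filters:
                raise ValidationError(f"duplicate filter instance name {name!r}")
            instance.name = name
            instance.parse_my_tag(sub, data, filters, movers)
            filters[name] = instance
    movers_section = model.section("MOVERS")
    if movers_section is not None:
        for sub in movers_section.subtags:
            instance = mover_factory.create(sub.name)
            name = _require_name(sub)
            if name in movers:
                raise ValidationError(f"duplicate mover instance name {name!r}")
            instance.name = name
            instance.parse_my_tag(sub, data, filters, movers)
            movers[name] = instance
    return movers, filters


def _require_name(tag: Tag) -> str:
    name = tag.get_option("name", str, None)
    if name is None:
        raise ValidationError(
            f"tag <{tag.name}> (line {tag.line}) requires a 'name' option"
        )
    return name


def parse_protocols(
    section: Tag, movers: dict[str, Mover], filters: dict[str, Filter]
) -> ParsedProtocol:
    """Build the top-level ParsedProtocol from the PROTOCOLS section."""
    if section.name != "PROTOCOLS":
        raise ValidationError(f"expected <PROTOCOLS>, got <{section.name}>")
    protocol = ParsedProtocol(
        [_resolve_step(sub, movers, filters) for sub in section.get_tags("Add")]
    )
    protocol.name = "PROTOCOLS"
    return protocol
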