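"""Mover/Filter contracts and the filter confidence gate.

Movers modify a pose in place and report success or ``FAIL_RETRY`` (which
aborts the trajectory and sends the job back to a fresh start).  Filters
evaluate a pose -- never modifying it -- returning a pass/fail verdict and
a reportable numeric value.  A filter's *confidence* gates how strictly the
verdict is enforced: 1 means strictly, 0 means report-only (the value is
still computed), and intermediate values enforce the verdict with that
probability per evaluation.
"""

from __future__ import annotations

import enum
import logging

import numpy as np

from ..datamap import DataMap
from ..errors import ProtocolError
from ..structure.pose import Pose
from ..tagparse import Tag

__all__ = ["Status", "Mover", "Filter", "filter_gate", "pose_rng"]

log = logging.getLogger("protoscript")


class Status(enum.Enum):
    SUCCESS = "success"
    FAIL_RETRY = "fail_retry"


def pose_rng(pose: Pose) -> np.random.Generator:
    """The trajectory's random source; a fixed default when the pose was
    not dispatched by the job distributor."""
    if pose.rng is None:
        pose.rng = np.random.default_rng(0)
    return pose.rng


class Mover:
    """Base class; subclasses set ``key_name`` and implement ``apply``."""

    key_name: str = ""

    def __init__(self):
        self.name: str | None = None
        #: numeric extras reported to the scorefile after a successful job
        self.extras: dict[str, float] = {}

    def parse_my_tag(
        self,
        tag: Tag,
        data: DataMap,
        filters: dict[str, "Filter"],
        movers: dict[str, "Mover"],
    ) -> None:
        pass

    def apply(self, pose: Pose) -> Status:
        raise NotImplementedError

    def iter_movers(self):
        """This mover and any sub-movers (overridden by composites)."""
        yield self


class Filter:
    key_name: str = ""

    def __init__(self):
        self.name: str | None = None
        self.confidence: float = 1.0

    def parse_confidence(self, tag: Tag) -> None:
        self.confidence = tag.get_option("confidence", float, 1.0)
        if not 0.0 <= self.confidence <= 1.0:
            raise ProtocolError(
                f"filter {self.name or self.key_name}: confidence "
                f"{self.confidence} outside [0, 1]"
            )

    def parse_my_tag(
        self,
        tag: Tag,
        data: DataMap,
        filters: dict[str, "Filter"],
        movers: dict[str, "Mover"],
    ) -> None:
        self.parse_confidence(tag)

    def apply(self, pose: Pose) -> bool:
        raise NotImplementedError

    def report_value(self, pose: Pose) -> float:
        raise NotImplementedError


def filter_gate(filt: Filter, pose: Pose, rng: np.random.Generator) -> bool:
    """Evaluate a filter through its confidence gate.

    The verdict is always computed (so the value is reportable); it blocks
    execution always at confidence 1, never at confidence 0, and with
    probability equal to the confidence in between.
    """
    if not 0.0 <= filt.confidence <= 1.0:
        raise ProtocolError(
            f"filter {filt.name or filt.key_name}: confidence "
            f"{filt.confidence} outside [0, 1]"
        )
    verdict = bool(filt.apply(pose))
    if filt.confidence >= 1.0:
        return verdict
    if filt.confidence <= 0.0:
        return True
    enforced = rng.random() < filt.confidence
    return verdict if enforced else True
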