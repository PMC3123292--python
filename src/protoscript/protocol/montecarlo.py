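"""Composite control-flow movers: GenericMonteCarlo and LoopOver."""

from __future__ import annotations

import numpy as np

from ..errors import ProtocolError
from ..structure.scorefxn import ScoreFunction, score
from .base import Filter, Mover, Status, filter_gate, pose_rng

__all__ = ["GenericMonteCarlo", "LoopOver"]


class GenericMonteCarlo(Mover):
    """Metropolis iteration of a sub-mover against a scalar objective.

    Each trial applies the sub-mover to a copy of the current pose and
    accepts or rejects the result on the objective (lower is better; a
    failed sub-mover counts as a rejected trial).  The pose ends at the
    best-seen state.  The objective is either a score function
    (``scorefxn_name``) or a filter's reported value (``filter_name``).
    """

    key_name = "GenericMonteCarlo"

    def __init__(
        self,
        mover: Mover | None = None,
        sfx: ScoreFunction | None = None,
        objective_filter: Filter | None = None,
        trials: int = 10,
        temperature: float = 0.6,
    ):
        super().__init__()
        self.mover = mover
        self.sfx = sfx
        self.objective_filter = objective_filter
        self.trials = trials
        self.temperature = temperature

    def parse_my_tag(self, tag, data, filters, movers):
        mover_name = tag.get_option("mover_name", str, None) or tag.get_option("mover")
        if mover_name not in movers:
            raise ProtocolError(
                f"GenericMonteCarlo refers to undeclared mover {mover_name!r}"
            )
        self.mover = movers[mover_name]
        self.trials = tag.get_option("trials", int, 10)
        self.temperature = tag.get_option("temperature", float, 0.6)
        sfx_name = tag.get_option("scorefxn_name", str, None)
        filter_name = tag.get_option("filter_name", str, None)
        if sfx_name is not None:
            self.sfx = data.get("scorefxns", sfx_name, ScoreFunction)
        elif filter_name is not None:
            if filter_name not in filters:
                raise ProtocolError(
                    f"GenericMonteCarlo refers to undeclared filter {filter_name!r}"
                )
            self.objective_filter = filters[filter_name]
        else:
            raise ProtocolError(
                "GenericMonteCarlo needs an objective: scorefxn_name or filter_name"
            )

    def _objective(self, pose) -> float:
        if self.sfx is not None:
            return score(pose, self.sfx).total
        if self.objective_filter is not None:
            return self.objective_filter.report_value(pose)
        raise ProtocolError("GenericMonteCarlo has no objective")

    def apply(self, pose) -> Status:
        if self.trials < 0:
            raise ProtocolError("trials must be >= 0")
        if self.trials == 0:
            return Status.SUCCESS
        rng = pose_rng(pose)
        current = pose.copy()
        current_value = self._objective(current)
        best = current.copy()
        best_value = current_value
        for _ in range(self.trials):
            candidate = current.copy()
            status = self.mover.apply(candidate)
            if status is Status.FAIL_RETRY:
                continue  # rejected trial
            value = self._objective(candidate)
            delta = value - current_value
            if delta < 0 or (
                self.temperature > 0
                and rng.random() < np.exp(-delta / self.temperature)
            ):
                current, current_value = candidate, value
                if value < best_value:
                    best, best_value = candidate.copy(), value
        pose.assign(best)
        return Status.SUCCESS

    def iter_movers(self):
        yield self
        if self.mover is not None:
            yield from self.mover.iter_movers()


class LoopOver(Mover):
    """Repeat a sub-mover until an iteration budget is exhausted or a
    user-supplied filter passes (whichever comes first)."""

    key_name = "LoopOver"

    def __init__(
        self,
        mover: Mover | None = None,
        filt: Filter | None = None,
        iterations: int = 1,
    ):
        super().__init__()
        self.mover = mover
        self.filter = filt
        self.iterations = iterations

    def parse_my_tag(self, tag, data, filters, movers):
        mover_name = tag.get_option("mover_name", str, None) or tag.get_option("mover")
        if mover_name not in movers:
            raise ProtocolError(f"LoopOver refers to undeclared mover {mover_name!r}")
        self.mover = movers[mover_name]
        filter_name = tag.get_option("filter_name", str, None) or tag.get_option(
            "filter", str, None
        )
        if filter_name is not None:
            if filter_name not in filters:
                raise ProtocolError(
                    f"LoopOver refers to undeclared filter {filter_name!r}"
                )
            self.filter = filters[filter_name]
        self.iterations = tag.get_option("iterations", int, 1)

    def apply(self, pose) -> Status:
        if self.iterations < 1:
            raise ProtocolError("LoopOver iterations must be >= 1")
        rng = pose_rng(pose)
        for _ in range(self.iterations):
            status = self.mover.apply(pose)
            if status is Status.FAIL_RETRY:
                return Status.FAIL_RETRY
            if self.filter is not None and filter_gate(self.filter, pose, rng):
                break
        return Status.SUCCESS

    def iter_movers(self):
        yield self
        if self.mover is not None:
            yield from self.mover.iter_movers()
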