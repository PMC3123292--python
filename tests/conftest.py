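"""Shared fixtures: registry initialisation, synthetic poses, plugin movers."""

from __future__ import annotations

import numpy as np
import pytest

from protoscript import registry
from protoscript.errors import DuplicateRegistrationError
from protoscript.protocol.base import Mover, Status
from protoscript.structure import make_fixture


@pytest.fixture(autouse=True)
def builtins_registered():
    """Every test sees fully registered factories (init is idempotent)."""
    registry.init_builtins()
    yield


class CountingMover(Mover):
    """Plugin mover that counts its applications and can be told to fail
    or to push the pose energy up (for Monte-Carlo tests)."""

    key_name = "CountingMover"
    #: class-level log of apply() calls per instance name
    calls: dict[str, int] = {}

    def __init__(self):
        super().__init__()
        self.fail = False
        self.shift = 0.0  # translate chain A by this much +x per apply

    def parse_my_tag(self, tag, data, filters, movers):
        self.fail = tag.get_option("fail", bool, False)
        self.shift = tag.get_option("shift", float, 0.0)

    def apply(self, pose):
        key = self.name or "anonymous"
        CountingMover.calls[key] = CountingMover.calls.get(key, 0) + 1
        if self.shift:
            pose.translate_chain(pose.chains()[0], np.array([self.shift, 0.0, 0.0]))
        return Status.FAIL_RETRY if self.fail else Status.SUCCESS


def ensure_counting_mover():
    try:
        registry.register_creator(
            registry.mover_factory,
            registry.Creator(CountingMover.key_name, CountingMover),
        )
    except DuplicateRegistrationError:
        pass


@pytest.fixture
def counting_mover_registered():
    ensure_counting_mover()
    CountingMover.calls.clear()
    return CountingMover


@pytest.fixture
def helix8():
    return make_fixture("helix", 8, seed=1)


@pytest.fixture
def helix30_mixed():
    # mixed polar/nonpolar sequence, long enough for residues 20..24
    seq = "ADKLFSTAVEIGMNQRHWYCADKLFSTAVE"
    return make_fixture("helix", 30, seed=2, sequence=seq)


@pytest.fixture
def dimer():
    return make_fixture("dimer", 10, seed=3)


@pytest.fixture
def ligand_complex():
    return make_fixture("ligand_complex", 16, seed=5)
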