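from __future__ import annotations

import numpy as np
import pytest

from rnassf import ENGINES, RnaSequence, ScoringScheme, random_sequence


@pytest.fixture(scope="session")
def default_scheme() -> ScoringScheme:
    return ScoringScheme.default()


@pytest.fixture(scope="session")
def d3_scheme() -> ScoringScheme:
    """A 3-discrete scheme: beta_max = 2, difference alphabet {0,1,2}."""
    return ScoringScheme.from_pairs({"GC": 2, "AU": 1, "GU": 1})


@pytest.fixture(scope="session")
def block_engines():
    """Engines that take epsilon/q parameters."""
    return {k: v for k, v in ENGINES.items() if k in ("fr", "sfr", "parallel-sim")}


def seqs_for(ns, seeds) -> list[RnaSequence]:
    return [random_sequence(n, 1000 * n + s) for n in ns for s in seeds]


def assert_same_L(res, base) -> None:
    __tracebackhide__ = True
    assert np.array_equal(res.dp.L, base.dp.L), (
        f"{res.engine} L-matrix deviates from {base.engine}"
    )
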