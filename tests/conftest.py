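"""Shared fixtures: fitted scenario bundles are session-scoped because the
maximum-likelihood fits are the expensive step and many tests read them."""

from collections import namedtuple

import numpy as np
import pytest

import palaeocr as pc
from palaeocr.cr import FitOptions

Bundle = namedtuple("Bundle", "config truth matrix pradel popan")

_STUDY_OPTS = dict(n_restarts=2, seed=0)


def _bundle(name: str, with_popan: bool = False) -> Bundle:
    cfg = pc.scenario(name, seed=11)
    table, truth = pc.simulate_occurrences(cfg)
    mat = pc.bin_occurrences(table, cfg.scheme)
    pradel = pc.fit_pradel(mat, FitOptions(**_STUDY_OPTS))
    popan = pc.fit_popan(mat, FitOptions(**_STUDY_OPTS)) if with_popan else None
    return Bundle(cfg, truth, mat, pradel, popan)


@pytest.fixture(scope="session")
def stable_bundle() -> Bundle:
    return _bundle("stable", with_popan=True)


@pytest.fixture(scope="session")
def volatile_bundle() -> Bundle:
    return _bundle("volatile")


@pytest.fixture(scope="session")
def pulse_bundle() -> Bundle:
    return _bundle("extinction_pulse")


@pytest.fixture()
def small_matrices():
    """Seeded batch of small incidence matrices for oracle comparisons."""
    rng = np.random.default_rng(7)
    out = []
    for _ in range(40):
        k = int(rng.integers(2, 5))
        g = int(rng.integers(1, 7))
        cells = (rng.random((g, k)) < 0.5).astype(int)
        empty = cells.sum(axis=1) == 0
        cells[empty, rng.integers(0, k, size=empty.sum())] = 1
        scheme = pc.TimeBinScheme.uniform(k, 2.0)
        out.append(pc.IncidenceMatrix([f"g{i}" for i in range(g)], scheme, cells))
    return out
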