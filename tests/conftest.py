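"""Shared fixtures: reduced-scale protocols and simulated sessions.

Sessions here use the full protocol structure (three interleaved sequences,
five blocks, interblock rests, lead-in/out) at reduced block size and cell
count so the whole suite stays fast while every structural property of the
full design is preserved.
"""

import numpy as np
import pytest

from seqexpect.schedule import ProtocolConfig, build_protocol
from seqexpect.simulate import (GeneratorConfig, generate_population,
                                simulate_session)


@pytest.fixture(scope="session")
def small_protocol():
    return ProtocolConfig(block_size=20)   # 100 presentations per sequence


@pytest.fixture(scope="session")
def small_events(small_protocol):
    return build_protocol(small_protocol, "baseline")


@pytest.fixture(scope="session")
def small_generator():
    return GeneratorConfig(n_mice=2, cells_per_mouse=100, seed=11)


@pytest.fixture(scope="session")
def small_session(small_protocol, small_events, small_generator):
    """(cells, activity) for a reduced baseline session."""
    rng = np.random.default_rng(11)
    cells = generate_population(small_generator, "baseline", rng=rng)
    activity = simulate_session(cells, small_events, small_generator, rng=rng,
                                day="baseline")
    return cells, activity


def simulate_pe_session(day, rho, n_cells=120, block_size=10, seed=0,
                        noise=0.5, drift_eta=0.01):
    """Small ABBD-only session of pure B cells with a planted omission gain."""
    proto = ProtocolConfig(sequences=("ABBD",), block_size=block_size)
    events = build_protocol(proto, day if day != "test" else "test")
    cfg = GeneratorConfig(
        n_mice=1, cells_per_mouse=n_cells,
        class_fractions={"baseline": {"element_B": 1.0},
                         "test": {"element_B": 1.0}},
        omission_gain={"baseline": rho, "test": rho},
        noise_scale=noise, drift_eta=drift_eta, seed=seed)
    rng = np.random.default_rng(seed)
    cells = generate_population(cfg, day, rng=rng)
    activity = simulate_session(cells, events, cfg, rng=rng,
                                training_sequence="ABBD", day=day)
    return cells, events, activity
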