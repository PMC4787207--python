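"""Shared fixtures: desk-scale configurations sized for fast statistics.

The fast config uses a (40 µm)³ lattice and a 24 s mixed schedule — several
diffusion screening lengths across and long enough for stable epoch
statistics — so that full pipeline runs stay in the seconds range.
"""
import numpy as np
import pytest

import striatosim as ss


@pytest.fixture(scope="session")
def fast_cfg() -> ss.RunConfig:
    return ss.RunConfig(
        lattice=ss.Lattice(extent=(40.0, 40.0, 40.0)),
        experiment=ss.ExperimentConfig(duration=24.0, n_probes=4),
        transduction=ss.TransductionConfig(min_reference=8.0, burn_in=1.0),
    )


@pytest.fixture(scope="session")
def intact_map(fast_cfg) -> ss.TerminalMap:
    return ss.build_microscale(fast_cfg.lattice, 0.1, seed=7)


@pytest.fixture(scope="session")
def tonic_trace(fast_cfg, intact_map):
    """A 20 s tonic-firing dopamine trace on the fast lattice."""
    trains = ss.generate_tonic(100, 20.0, fast_cfg.firing, seed=7)
    return ss.simulate(trains, intact_map, fast_cfg.kinetics, dt=1e-3, seed=7)
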