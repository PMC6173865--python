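import numpy as np
import pytest

from cpgscape.genome import GenomeIndex
from cpgscape.simulate import (
    SimConfig,
    simulate_all,
    simulate_expression,
    simulate_genome,
    simulate_tracks,
    write_simulation,
)
from cpgscape.tracks import CoverageTrack, normalize_1x, subtract_input

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def sim_genome(sim_config):
    return simulate_genome(sim_config, DEFAULT_SEED)


@pytest.fixture(scope="session")
def ery_sim(sim_genome):
    return simulate_tracks(sim_genome, DEFAULT_SEED + 1000, "ery")


@pytest.fixture(scope="session")
def ery_tracks(ery_sim):
    """Normalised, input-subtracted tracks, as the pipeline would build them."""
    inp = normalize_1x(ery_sim.tracks["input"])
    return {
        n: subtract_input(normalize_1x(t), inp)
        for n, t in ery_sim.tracks.items()
        if n != "input"
    }


@pytest.fixture(scope="session")
def expr_sim(sim_genome):
    return simulate_expression(sim_genome, DEFAULT_SEED + 7)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, sim_config):
    """Full simulation written to disk once per session."""
    out = tmp_path_factory.mktemp("sim") / "data"
    sim, track_sims, expr = simulate_all(sim_config, DEFAULT_SEED)
    write_simulation(out, sim, track_sims, expr)
    return out


def toy_genome(lengths: dict[str, int]) -> GenomeIndex:
    return GenomeIndex.from_dict(lengths)


def toy_track(lengths: dict[str, int], bin_size: int = 50, fill=0.0) -> CoverageTrack:
    g = toy_genome(lengths)
    t = CoverageTrack.zeros(g, bin_size)
    for c in g.chroms:
        t.data[c][:] = fill
    return t
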