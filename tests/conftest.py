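import pytest

from spikequant import default_primer_pairs, default_spikes


@pytest.fixture(scope="session")
def primer_pairs():
    return default_primer_pairs()


@pytest.fixture(scope="session")
def spikes():
    return default_spikes(seed=7)


@pytest.fixture(scope="session")
def small_run():
    """A small error-free simulated run shared across read-processing tests."""
    from spikequant.simulate import simulate_run

    return simulate_run(n_samples=3, depth_per_family=3000, seed=42)
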