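import pytest

import spaceseq as ss


@pytest.fixture(scope="session")
def small_sim():
    """A small end-to-end fixture: 6 spots, 50 reads/spot, 30% duplicates."""
    cfg = ss.SimulationConfig(
        seed=11,
        n_spots=6,
        genome=(ss.ContigSpec("chr1", 200_000), ss.ContigSpec("chr2", 150_000)),
        reads_per_spot=50,
        duplicate_rate=0.3,
    )
    return ss.simulate(cfg)


@pytest.fixture(scope="session")
def dup_sim():
    """1,000-read fixture with duplicate_rate 0.5 and no UMI errors."""
    cfg = ss.SimulationConfig(
        seed=13,
        n_spots=10,
        genome=(ss.ContigSpec("chr1", 500_000),),
        reads_per_spot=100,
        duplicate_rate=0.5,
        umi_error_rate=0.0,
    )
    return ss.simulate(cfg)


@pytest.fixture
def toy_layout():
    return [
        ss.SpotBarcode("A" * 16, True, 0, 0, 0.0, 0.0),
        ss.SpotBarcode("C" * 16, True, 0, 1, 100.0, 0.0),
        ss.SpotBarcode("G" * 16, False, 1, 0, 0.0, 100.0),
    ]
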