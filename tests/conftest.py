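import pytest

from clinepool.io_formats import PoolProfile
from clinepool.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def pools():
    return [
        PoolProfile("F", 25.53, 78, n_flies=39),
        PoolProfile("P", 39.88, 204, n_flies=102),
        PoolProfile("M", 44.02, 172, n_flies=86),
    ]


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A small three-population study with clinal SNPs and an inversion,
    written to disk once per session."""
    outdir = tmp_path_factory.mktemp("study")
    cfg = SimConfig(
        seed=7,
        arms={"2L": 3000, "3R": 3000},
        clinal_fraction=0.01,
        inversion=dict_to_inversion(),
    )
    truth, sites, counts, paths = simulate_study(cfg, outdir=outdir)
    return cfg, truth, sites, counts, paths


def dict_to_inversion():
    from clinepool.synthetic_data import InversionSpec

    return InversionSpec(
        arm="3R", start=100_000, end=280_000,
        pool_frequencies=(0.5, 0.05, 0.05), linkage=0.8, n_markers=3,
    )
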