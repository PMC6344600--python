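import pytest

from eetscan.config import default_params
from eetscan.homology import load_references
from eetscan.pipeline import analyze_metagenome
from eetscan.synthetic_data import SynthConfig, generate_synthetic_metagenome

#: seed of the shared default synthetic metagenome
DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def refs():
    return load_references()


@pytest.fixture(scope="session")
def default_metagenome():
    """The default planted metagenome, generated once per session."""
    data, truth, _ = generate_synthetic_metagenome(SynthConfig(seed=DEFAULT_SEED))
    return data, truth


@pytest.fixture(scope="session")
def default_result(default_metagenome, refs):
    """Pipeline result on the shared default metagenome."""
    data, truth = default_metagenome
    return analyze_metagenome(data, default_params(), refs), truth


def small_config(seed: int, **overrides) -> SynthConfig:
    """A fast, few-plants configuration for unit-level tests."""
    base = dict(
        mhc_heme_counts=(5, 8, 11, 12),
        n_pcc_known=2,
        n_pcc_novel=2,
        novel_mhc_heme_counts=(8, 10),
        n_cyc2=2,
        n_outer_surface=2,
        n_cell_wall_mhc=1,
        n_decoy_near_mhc=2,
        n_decoy_lone_porin=2,
        n_decoy_mhc_no_signal=2,
        n_decoy_distant_pair=1,
        n_decoy_cys_rich=1,
        n_background=15,
        n_housekeeping=6,
        n_mags=3,
    )
    base.update(overrides)
    return SynthConfig(seed=seed, **base)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small metagenome written to disk, with its truth table."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = small_config(seed=3, metagenome_id="mini")
    data, truth, paths = generate_synthetic_metagenome(cfg, out)
    return data, truth, paths
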