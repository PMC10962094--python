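import numpy as np
import pytest

from m6aconserve.pipeline import prepare_dataset
from m6aconserve.synth import SynthConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small synthetic dataset with full planted signal."""
    config = SynthConfig(
        seed=11, n_sites=300, n_genes=60, n_chroms=2, chrom_length=250_000,
        effect_strength=1.0,
    )
    return generate_bundle(config, tmp_path_factory.mktemp("bundle_small"))


@pytest.fixture(scope="session")
def small_dataset(small_bundle):
    """Labeled + featurized version of the small bundle."""
    return prepare_dataset(
        small_bundle.genome_fa,
        small_bundle.gtf,
        small_bundle.sites_bed,
        small_bundle.profiles_tsv,
        tracks_config=small_bundle.tracks_config,
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
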