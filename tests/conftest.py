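import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from surfsig import SimConfig, load_bundle, write_fixture_bundle

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

#: fixed replication seed for every randomized check in the suite
SUITE_SEED = 20260927


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down study bundle: fast, but with every layer populated."""
    return SimConfig(
        n_genes=400,
        n_proteins=300,
        n_planted_surface=20,
        n_categories=60,
        category_size_range=(5, 15),
        n_shifted_categories=5,
        seed=SUITE_SEED,
    )


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory, small_cfg):
    outdir = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(small_cfg, outdir)
    return outdir


@pytest.fixture(scope="session")
def small_bundle(small_bundle_dir):
    return load_bundle(small_bundle_dir)


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)


def make_spectra(proteins, peptides_per_protein, spectra_per_peptide, ratios, weight=100.0):
    """Hand-built spectrum table: one true ratio per protein, no noise added."""
    rows = []
    for prot, ratio in zip(proteins, ratios):
        for j in range(peptides_per_protein):
            for k in range(spectra_per_peptide):
                rows.append(
                    {
                        "spectrum_id": f"{prot}.p{j}.s{k}",
                        "peptide_id": f"{prot}.p{j}",
                        "protein_id": prot,
                        "log2_ratio": ratio,
                        "weight": weight,
                        "comparison": "A_vs_B",
                    }
                )
    return pd.DataFrame(rows)
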