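import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from txprov.fixtures import make_toy_txome, simulate_quant
from txprov.quantio import SampleTable
from txprov.registry import FileCache, append_custom_record


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """One shared synthetic transcriptome: FASTA + GTF + GFF3 + record."""
    root = tmp_path_factory.mktemp("txome")
    return make_toy_txome(root, n_genes=6, tx_per_gene=3, seed=11)


@pytest.fixture(scope="session")
def toy_quants(toy_bundle, tmp_path_factory):
    """Two quantification directories for the shared transcriptome."""
    root = tmp_path_factory.mktemp("quants")
    return simulate_quant(toy_bundle["fasta"], root, n_samples=2, seed=5)


@pytest.fixture
def cache(tmp_path):
    return FileCache(tmp_path / "cache")


@pytest.fixture
def registered_cache(cache, toy_bundle):
    """A cache whose custom hash table already knows the toy transcriptome."""
    append_custom_record(cache.custom_registry_path, toy_bundle["record"])
    return cache


def make_sample_table(quant_dirs, names=None, **covariates):
    names = names or [p.name for p in quant_dirs]
    data = {"names": names, "files": [str(p / "quant.sf") for p in quant_dirs]}
    data.update(covariates)
    return SampleTable(pd.DataFrame(data))


@pytest.fixture
def sample_table(toy_quants):
    return make_sample_table(toy_quants, condition=["naive", "treated"])
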