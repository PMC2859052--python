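import pytest

from lncsieve.forge import Forge, ForgeConfig


@pytest.fixture(scope="session")
def default_forge():
    """The default forged dataset (study conditions), built once."""
    return Forge(ForgeConfig(seed=11)).build()


@pytest.fixture(scope="session")
def dataset_dir(default_forge, tmp_path_factory):
    out = tmp_path_factory.mktemp("data") / "ds"
    default_forge.emit(out)
    return out


@pytest.fixture(scope="session")
def small_forge():
    """A reduced forge for fast pipeline-level tests."""
    cfg = ForgeConfig(
        seed=4,
        n_genes=8,
        chrom_length=60_000,
        n_lnc_per_class={"utr_only": 1, "intron_only": 1, "mixed": 1, "near_gene": 1, "intergenic": 1},
        n_antisense=1,
        n_spliced_intergenic=1,
    )
    return Forge(cfg).build()


@pytest.fixture(scope="session")
def small_dataset_dir(small_forge, tmp_path_factory):
    out = tmp_path_factory.mktemp("smalldata") / "ds"
    small_forge.emit(out)
    return out
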