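import pytest

from erfkit.domains import architectures_from_hits, parse_interproscan_tsv
from erfkit.synthetic import TruthConfig, generate_proteomes

#: Small three-species dataset reused across module tests.  Tandem array
#: sizes are scaled with the gene count (the defaults suit 200 genes per
#: species).
SMALL_CONFIG = TruthConfig(
    n_species=3, genes_per_species=60, background_genes=20, seed=11,
    tandem_arrays=(("chr1", "B2", 4), ("chr4", "B3", 3)),
)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_proteomes(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_paths(small_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("inputs")
    return small_dataset.write(outdir)


@pytest.fixture(scope="session")
def small_architectures(small_paths):
    """Filtered architectures per species, from the emitted TSV files."""
    out = {}
    for sp, paths in small_paths.items():
        hits = parse_interproscan_tsv(paths["domains"])
        out[sp] = architectures_from_hits(hits)
    return out
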