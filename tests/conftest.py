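import warnings

import pytest

from cdpksurvey import core_io, synth

BUNDLE_SEED = 101


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One default-condition synthetic bundle shared across the suite."""
    outdir = tmp_path_factory.mktemp("bundle")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synth.generate_all(synth.GeneratorConfig(seed=BUNDLE_SEED), outdir)


@pytest.fixture(scope="session")
def target_proteins(bundle):
    return {p.seq_id: p for p in core_io.read_fasta(bundle.target_fasta)}


@pytest.fixture(scope="session")
def reference_proteins(bundle):
    return {p.seq_id: p for p in core_io.read_fasta(bundle.reference_fasta)}


@pytest.fixture(scope="session")
def gene_records(bundle):
    return {r.gene_id: r for r in core_io.read_gff3(bundle.gff_path)}


@pytest.fixture(scope="session")
def fixture_rows():
    return core_io.load_packaged_table1()
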