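import numpy as np
import pytest

from cpgscape.genome import GenomeSequence
from cpgscape.pipeline import PipelineInputs, run_pipeline
from cpgscape.synthetic import SyntheticConfig, generate


def make_genome(**seqs) -> GenomeSequence:
    """In-memory genome; test chromosomes must use conventional names (chr1...)."""
    return GenomeSequence(seqs)


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """The default demo bundle: 2 x 500 kb chromosomes, seed 7."""
    out = tmp_path_factory.mktemp("bundle")
    return generate(SyntheticConfig(seed=7), str(out))


@pytest.fixture(scope="session")
def demo_result(demo_bundle, tmp_path_factory):
    """Full pipeline run over the demo bundle."""
    out = tmp_path_factory.mktemp("pipeline_out")
    inputs = PipelineInputs(
        fasta=demo_bundle.paths["fasta"],
        genes=demo_bundle.paths["genes"],
        vcfs=[(demo_bundle.paths["wgs_vcf"], "wgs")],
        methylation=demo_bundle.paths["methylation"],
        coding_vcf=demo_bundle.paths["coding_vcf"],
    )
    return run_pipeline(inputs, str(out))


@pytest.fixture()
def rng():
    return np.random.default_rng(20200330)
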