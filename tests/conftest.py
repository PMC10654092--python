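import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from prophikit.config import PipelineConfig
from prophikit.pipeline import PipelineInputs, run_pipeline
from prophikit.simulate import CorpusConfig, generate_corpus

#: the study corpus every end-to-end check runs on
CORPUS_SEED = 42


@pytest.fixture(scope="session")
def default_corpus():
    """The default 20-assembly synthetic corpus with planted truth."""
    return generate_corpus(seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def default_inputs(default_corpus):
    c = default_corpus
    return PipelineInputs(
        assemblies=c.assemblies,
        genes=c.genes,
        phage_db=c.phage_db,
        profile_db=c.profile_db,
        rna_features=c.rna_features,
        reference=c.reference,
        reference_rna=c.reference_rna,
    )


@pytest.fixture(scope="session")
def default_bundle(default_inputs):
    """One full pipeline run over the default corpus."""
    return run_pipeline(default_inputs, PipelineConfig())


@pytest.fixture(scope="session")
def small_corpus():
    """A 4-assembly corpus for cheaper per-module checks."""
    return generate_corpus(CorpusConfig.scaled(4), seed=7)
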