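import pytest

from kolminer.pipeline import PipelineConfig, run_pipeline
from kolminer.synthetic_corpus import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default synthetic study conditions (seed 42)."""
    out = tmp_path_factory.mktemp("default_run")
    return run_pipeline(PipelineConfig(out_dir=str(out), seed=42))


@pytest.fixture(scope="session")
def synth_small():
    """A reduced synthetic corpus for fast unit tests."""
    return generate_corpus(
        GeneratorConfig(seed=11, n_articles=30, n_persons=24,
                        n_train_sentences=60)
    )
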