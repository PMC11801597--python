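import pathlib

import pytest

from pvsignal import PipelineConfig, SyntheticConfig, generate, generate_frames


@pytest.fixture(scope="session")
def planted_config() -> SyntheticConfig:
    """A desk-scale corpus with one strongly planted drug-event association."""
    return SyntheticConfig(n_reports=20_000, seed=7,
                           planted_effects={"drug_100": 10.0})


@pytest.fixture(scope="session")
def planted_data(planted_config):
    return generate_frames(planted_config)


@pytest.fixture(scope="session")
def planted_corpus_dir(planted_config, tmp_path_factory) -> pathlib.Path:
    """The same corpus written as FAERS-dialect files, with 10% duplicates."""
    outdir = tmp_path_factory.mktemp("faers")
    generate(planted_config, outdir, duplicate_rate=0.10)
    return outdir


@pytest.fixture(scope="session")
def planted_pipeline_config(planted_corpus_dir) -> PipelineConfig:
    return PipelineConfig(
        input_dir=planted_corpus_dir,
        target_pt="autoimmune hepatitis",
        dictionary=planted_corpus_dir / "drug_dictionary.tsv",
    )
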