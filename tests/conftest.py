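import pytest

from unibridge import expression, pipeline, synthetic_data


@pytest.fixture(scope="session")
def truth():
    """One deterministic noise-free synthetic transcriptome."""
    return synthetic_data.generate(seed=11)


@pytest.fixture(scope="session")
def matrix(truth):
    return expression.rpkm_matrix(truth.counts)


@pytest.fixture(scope="session")
def pipeline_result(truth, matrix):
    return pipeline.run_pipeline(
        truth.records, matrix, truth.alignments, truth.reference,
        pipeline.PipelineConfig(design_primers=False),
    )
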