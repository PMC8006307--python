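import numpy as np
import pytest

from coldmap import pipeline


@pytest.fixture(scope="session")
def planted_experiment():
    """One full-size synthetic experiment with a planted QTL (shared)."""
    config = pipeline.default_sim_config(seed=7, additive=15.0)
    return pipeline.simulate_experiment(config)


@pytest.fixture(scope="session")
def planted_result(planted_experiment):
    exp = planted_experiment
    return pipeline.run_qtlseq(
        exp.counts, exp.config.chrom_lengths, exp.config.bulk_size, seed=7
    )
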