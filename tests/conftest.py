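import numpy as np
import pytest

from socexp import (
    ExpressionMatrix,
    SyntheticConfig,
    build_barcodes,
    compute_rmsf,
    generate_annotation,
    generate_expression,
    partition_states,
)


@pytest.fixture
def small_matrix():
    """4 genes x 4 times, natural-log values, hand-checkable."""
    values = np.array(
        [
            [0.0, 0.1, 0.2, 0.3],
            [1.0, 1.0, 1.0, 1.0],
            [2.0, 1.9, 2.1, 2.0],
            [0.5, 0.7, 0.4, 0.6],
        ]
    )
    return ExpressionMatrix(["g1", "g2", "g3", "g4"], [0, 10, 15, 20], values, "natural_log")


class SynthBundle:
    """Shared study-condition data set (generated once per session)."""

    def __init__(self, seed=1, **overrides):
        self.config = SyntheticConfig(seed=seed, **overrides)
        self.matrix, self.truth = generate_expression(self.config)
        self.fluct = compute_rmsf(self.matrix)
        self.partition = partition_states(self.fluct)
        self.annotation = generate_annotation(self.config, self.truth)
        self.barcodes = build_barcodes(self.partition, self.annotation)


@pytest.fixture(scope="session")
def synth():
    """Default synthetic data set: 20000 genes, 18 time points."""
    return SynthBundle(seed=1)


@pytest.fixture(scope="session")
def synth_small():
    """Smaller synthetic data set for cheap structural checks."""
    return SynthBundle(seed=5, n_genes=4000)
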