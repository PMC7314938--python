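import numpy as np
import pandas as pd
import pytest

from mmibn import (
    Modality,
    ModalityMatrix,
    MultiOmicsDataset,
    OutcomeVector,
    assemble_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_modality(modality, genes, samples, values):
    return ModalityMatrix(
        Modality(modality),
        pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples),
    )


def make_dataset(
    n_genes=6, n_samples=40, seed=0, planted_m_shift=None, outcome_name="tumor_status"
) -> MultiOmicsDataset:
    """Small hand-rolled dataset; optionally shift gene 0's M component."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"p{i}" for i in range(n_samples)]
    y = np.tile([0, 1], n_samples // 2 + 1)[:n_samples]
    E = rng.standard_normal((n_genes, n_samples))
    M = rng.standard_normal((n_genes, n_samples))
    if planted_m_shift:
        M[0, y == 1] += planted_m_shift
    S = (rng.random((n_genes, n_samples)) < 0.15).astype(float)
    return assemble_dataset(
        make_modality("S", genes, samples, S),
        make_modality("E", genes, samples, E),
        make_modality("M", genes, samples, M),
        OutcomeVector(outcome_name, samples, y),
    )


@pytest.fixture
def small_dataset():
    return make_dataset()
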