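import numpy as np
import pytest

from translatekit.io_formats import ExpressionMatrix, GeneRecord, SampleMeta
from translatekit.synthetic_data import SimConfig, simulate_counts


def make_matrix(values, conditions=("CRPC", "ER"), fraction="total", biotypes=None):
    """Small ExpressionMatrix with one replicate column per condition entry."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    reps = {}
    samples = []
    for j, cond in enumerate(conditions):
        reps[cond] = reps.get(cond, 0) + 1
        samples.append(
            SampleMeta(
                sample_id=f"{cond}_{fraction}_{reps[cond]}",
                condition=cond,
                fraction=fraction,
                replicate=reps[cond],
            )
        )
    genes = [
        GeneRecord(f"g{i}", biotype=(biotypes or {}).get(f"g{i}", "protein_coding"))
        for i in range(n_genes)
    ]
    return ExpressionMatrix(genes, samples, values)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared across tests (study-like layout)."""
    config = SimConfig(n_genes=300, seed=42)
    transcriptome, translatome, truth = simulate_counts(config)
    return config, transcriptome, translatome, truth
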