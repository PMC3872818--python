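import numpy as np
import pandas as pd
import pytest

from heatnca import ExpressionMatrix, generate_connectivity, simulate_nca_instance


@pytest.fixture(scope="session")
def small_pattern():
    """Identifiable 60-gene x 5-TF pattern at density 0.2."""
    return generate_connectivity(60, 5, 0.2, seed=7)


@pytest.fixture(scope="session")
def noisefree_truth(small_pattern):
    return simulate_nca_instance(small_pattern, n_conditions=20,
                                 noise_sd=0.0, seed=11)


def make_expression(cells: dict, gene_ids=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from {(ecotype, treatment): genes x reps}."""
    sample_ids, design_rows, cols = [], [], []
    cells = {k: np.asarray(v, dtype=float) for k, v in cells.items()}
    n_genes = next(iter(cells.values())).shape[0]
    for (eco, trt), block in cells.items():
        block = np.asarray(block, dtype=float)
        for rep in range(block.shape[1]):
            sample_ids.append(f"{eco}_{trt}_{rep + 1}")
            design_rows.append((eco, trt, rep + 1))
            cols.append(block[:, rep])
    design = pd.DataFrame(design_rows, index=sample_ids,
                          columns=["ecotype", "treatment", "replicate"])
    if gene_ids is None:
        gene_ids = [f"AT1G{(i + 1) * 10:05d}" for i in range(n_genes)]
    return ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids,
                            values=np.column_stack(cols), design=design)
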