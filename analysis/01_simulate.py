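"""Simulate the study-style dataset: 10 ecotypes, triplicated control/heat
arrays, and a planted TF -> target regulatory layer.

The planted layer is a 300-target x 12-TF connectivity pattern with a mean
in-degree of ~1.5 regulators per target — the per-target edge density of
the study's 1947-edge, 1294-target network — scaled down so the whole
analysis sequence runs in seconds.  Writes the expression matrix, design, annotation
and ground truth under scratch/sim/ and a one-row summary under results/.
"""

from pathlib import Path

import numpy as np

from heatnca import generate_connectivity, simulate_regulated_experiment
from heatnca.io import (write_annotation, write_design, write_expression,
                        write_matrix, write_table)
import pandas as pd

ECOTYPES = ["Cvi", "Kas-1", "Kyo-2", "Sha", "Col-0",
            "Kond", "C24", "Ler", "An-1", "Eri"]
N_TARGETS, N_TFS, DENSITY = 300, 12, 1.5 / 12
SEED = 42

SIM_DIR = Path(__file__).resolve().parent.parent / "scratch" / "sim"
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    SIM_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    pattern = generate_connectivity(N_TARGETS, N_TFS, DENSITY, seed=SEED)
    expr, truth, annot = simulate_regulated_experiment(
        pattern, ECOTYPES, n_reps=3, noise_sd=0.05, replicate_sd=0.3,
        seed=SEED)

    write_expression(expr, SIM_DIR / "expression.tsv")
    write_design(expr.design, SIM_DIR / "design.tsv")
    write_annotation(annot, SIM_DIR / "annotation.tsv")
    tf_ids = expr.gene_ids[N_TARGETS:]
    write_matrix(truth.p_true, tf_ids, ECOTYPES, SIM_DIR / "p_true.tsv",
                 "planted TF activities (TF x ecotype)")
    write_matrix(truth.a_true, expr.gene_ids[:N_TARGETS], tf_ids,
                 SIM_DIR / "a_true.tsv", "planted control strengths")

    summary = pd.DataFrame([{
        "n_genes": len(expr.gene_ids), "n_tfs": N_TFS,
        "n_samples": len(expr.sample_ids), "n_ecotypes": len(ECOTYPES),
        "planted_edges": pattern.n_entries, "noise_sd": 0.05,
        "replicate_sd": 0.3, "seed": SEED,
    }])
    write_table(summary, RESULTS / "01_simulation.tsv",
                "synthetic study-design summary")
    print(f"simulated {len(expr.gene_ids)} genes "
          f"({N_TARGETS} targets + {N_TFS} TFs) x {len(expr.sample_ids)} arrays")
    print(f"planted {pattern.n_entries} regulatory edges "
          f"(mean {pattern.n_entries / N_TARGETS:.1f} regulators per target, "
          f"{pattern.n_entries / N_TFS:.1f} targets per TF)")
    print(f"wrote inputs to {SIM_DIR}")


if __name__ == "__main__":
    main()
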