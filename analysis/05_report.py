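"""Classify TF activity profiles and summarize the regulatory picture.

Per TF, the inferred activity row is robust-z standardized across ecotypes;
ecotypes at |z| >= 2 are the TF's responsive conditions, splitting TFs into
ecotype-specific (unique), multi-responsive and inactive.  The activity
matrix is clustered (1 - Pearson r, average linkage) with bootstrap support,
and the planted regulon of each TF is tested for over-representation among
the called DE genes as an enrichment sanity check.
"""

from pathlib import Path

import numpy as np

from heatnca import (bootstrap_support, classify_responsive, enrichment_test,
                     hierarchical_cluster, linkage_to_newick)
from heatnca.io import read_matrix, read_table, write_table

BASE = Path(__file__).resolve().parent.parent
SIM_DIR = BASE / "scratch" / "sim"
RESULTS = BASE / "results"


def main() -> None:
    tfa = read_matrix(RESULTS / "04_tfa.tsv")
    profile = classify_responsive(tfa.to_numpy(), list(tfa.index),
                                  list(tfa.columns), threshold_z=2.0)
    write_table(profile.to_frame(), RESULTS / "05_activity_calls.tsv",
                "ecotype-specific vs multi-responsive TF activity calls")
    for cat in ("unique", "multi", "none"):
        print(f"{cat}: {profile.category.count(cat)} TFs")

    clust = hierarchical_cluster(tfa.to_numpy())
    labels = [list(tfa.index)[i] for i in clust.kept]
    support = bootstrap_support(tfa.to_numpy()[clust.kept], n_boot=200, seed=1)
    (RESULTS / "05_tfa_tree.nwk").write_text(
        linkage_to_newick(clust.linkage, labels) + "\n")
    print(f"activity clustering: {len(labels)} TFs, "
          f"median bootstrap support {np.median(support):.2f}")

    # enrichment sanity check: is each TF's predicted target set
    # over-represented for its own planted regulon?
    import pandas as pd

    a_true = read_matrix(SIM_DIR / "a_true.tsv")
    edges = read_table(SIM_DIR / "network_edges.tsv")
    universe = set(a_true.index)
    regulons = {tf: set(a_true.index[a_true[tf] != 0])
                for tf in a_true.columns}
    rows = []
    for tf in sorted(set(edges["tf_id"]) & set(regulons)):
        predicted = set(edges.loc[edges["tf_id"] == tf, "target_id"]) & universe
        res = enrichment_test(predicted, universe, regulons)
        rows.append(res[res["set_id"] == tf].iloc[0])
    enr = pd.DataFrame(rows).reset_index(drop=True)
    write_table(enr, RESULTS / "05_regulon_enrichment.tsv",
                "hypergeometric over-representation of each TF's planted "
                "regulon among its predicted network targets (Bonferroni)")
    n_sig = int((enr["p_adjusted"] <= 0.05).sum())
    print(f"regulon recovery: predicted target sets of {n_sig}/{len(enr)} "
          f"TFs are enriched for their planted regulon (adjusted p <= 0.05)")


if __name__ == "__main__":
    main()
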