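"""Build the signed bipartite TF -> target network from fold-change profiles.

TF layer: significant TF-tagged genes.  Target layer: the remaining
significant genes.  Edges: |Pearson r| >= 0.8 between per-ecotype log2
fold-change profiles, signed as activation (+) or repression (-).  Writes
the edge list and the per-TF degree table.
"""

from pathlib import Path

from heatnca import (build_signed_network, correlation_profiles, degree_table,
                     hub_summary)
from heatnca.de import fold_change_matrix
from heatnca.io import (read_annotation, read_design, read_expression,
                        read_table, write_edge_list, write_table)

BASE = Path(__file__).resolve().parent.parent
SIM_DIR = BASE / "scratch" / "sim"
RESULTS = BASE / "results"
THRESHOLD = 0.8


def main() -> None:
    expr = read_expression(SIM_DIR / "expression.tsv",
                           read_design(SIM_DIR / "design.tsv"))
    annot = read_annotation(SIM_DIR / "annotation.tsv")
    records = read_table(SIM_DIR / "de_records.tsv")

    sig = set(records.loc[records["significant"], "gene_id"])
    tf_ids = sorted(g for g in sig if "TF" in annot.tags_for(g))
    targets = sorted(sig - set(tf_ids))
    fc = fold_change_matrix(expr)
    corr = correlation_profiles(fc.loc[tf_ids].to_numpy(),
                                fc.loc[targets].to_numpy())
    net = build_signed_network(corr, THRESHOLD, tf_ids, targets)

    write_edge_list(net, SIM_DIR / "network_edges.tsv")
    table = degree_table(net)
    write_table(table, RESULTS / "03_degree_table.tsv",
                f"per-TF connections at |r| >= {THRESHOLD}")

    n_act = sum(e.sign > 0 for e in net.edges)
    print(f"network: {len(net.tfs)} TFs -> {len(net.targets)} targets, "
          f"{net.n_edges} edges ({n_act} activations, "
          f"{net.n_edges - n_act} repressions)")
    hubs = hub_summary(net, k=3)
    print("top hubs:", ", ".join(f"{t} ({d})" for t, d in hubs["top"]))


if __name__ == "__main__":
    main()
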