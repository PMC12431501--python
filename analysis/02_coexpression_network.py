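#!/usr/bin/env python
"""Build the signed TF-SSP co-expression network and rank hub TFs.

Selects the most abundant transcripts from the simulated compendium,
partitions them into TF and SSP candidates, thresholds all pairwise Pearson
correlations at |r| >= 0.7, and reports hub degrees and the SSP targets
shared by the top hubs — the same procedure used to nominate candidate
regulators of seed storage proteins. Outputs land in results/network/.
"""

import argparse
from pathlib import Path

import pandas as pd

from seedreg.expression import (
    partition_candidates, read_expression_matrix, read_role_table,
    select_top_abundant,
)
from seedreg.network import (
    build_network, degree_table, export_network, shared_targets,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fixture", type=Path,
                        default=ROOT / "results" / "fixture")
    parser.add_argument("--outdir", type=Path,
                        default=ROOT / "results" / "network")
    parser.add_argument("--top-n", type=int, default=40)
    parser.add_argument("--cutoff", type=float, default=0.7)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    matrix = read_expression_matrix(args.fixture / "expression.tsv")
    roles = read_role_table(args.fixture / "roles.tsv")
    top = select_top_abundant(matrix, min(args.top_n, matrix.shape[0]))
    tf_ids, ssp_ids = partition_candidates(top, roles)
    print(f"selected top {len(top)} transcripts: "
          f"{len(tf_ids)} TF, {len(ssp_ids)} SSP candidates")

    net = build_network(matrix, tf_ids, ssp_ids, cutoff=args.cutoff,
                        roles=roles)
    for fmt, name in [("edge-tsv", "edges.tsv"), ("sif", "edges.sif"),
                      ("graphml", "edges.graphml")]:
        export_network(net, fmt, args.outdir / name)
    degrees = degree_table(net)
    degrees.to_csv(args.outdir / "degree_table.tsv", sep="\t", index=False)

    n_pos = sum(e.sign == "positive" for e in net.edges)
    print(f"network at |r| >= {args.cutoff}: {len(net.edges)} edges "
          f"({n_pos} positive, {len(net.edges) - n_pos} negative)")
    hubs = list(degrees.loc[degrees["degree"] > 0, "tf_id"].head(3))
    shared = shared_targets(net, hubs)
    print(f"top hub TFs by degree: "
          f"{[(t, int(degrees.set_index('tf_id').degree[t])) for t in hubs]}")
    print(f"SSP targets shared by all top hubs: {sorted(shared) or 'none'}")
    with open(args.outdir / "hubs.tsv", "w") as fh:
        fh.write("hub_tfs\tshared_ssp_targets\n")
        fh.write(",".join(hubs) + "\t" + ",".join(sorted(shared)) + "\n")


if __name__ == "__main__":
    main()
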