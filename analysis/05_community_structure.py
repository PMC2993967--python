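#!/usr/bin/env python
"""Stage 5: multivariate community structure.

Square-root transform, Bray-Curtis similarity, UPGMA dendrogram with SIMPROF
structure tests, ANOSIM on season labels, SIMPER between day and night, and a
2-D NMDS ordination — on the stage-1 count table.

Writes all tables under results/structure/.
"""

import argparse
from pathlib import Path

import pandas as pd

from omicdiv import (
    anosim,
    bray_curtis,
    nmds,
    simper,
    simprof,
    transform_counts,
)
from omicdiv.compare import simprof_annotation_table
from omicdiv.records import read_count_matrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--counts", type=Path, default=Path("results/data/counts.tsv"))
    ap.add_argument("--metadata", type=Path, default=Path("results/data/metadata.tsv"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/structure"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    counts = read_count_matrix(args.counts)
    meta = pd.read_csv(args.metadata, sep="\t", index_col=0)

    transformed = transform_counts(counts, "sqrt")
    sim = bray_curtis(transformed, transform="sqrt")
    sim.data.round(6).to_csv(args.outdir / "bray_curtis.tsv", sep="\t")

    tree = simprof(transformed, seed=args.seed)
    (args.outdir / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
    nodes = simprof_annotation_table(tree)
    nodes.to_csv(args.outdir / "simprof_nodes.tsv", sep="\t", index=False)
    sig = nodes[nodes["significant"]]
    print(f"SIMPROF: {len(sig)}/{len(nodes)} internal nodes significant")

    seasons = meta["season"].to_dict()
    ano = anosim(sim, seasons, n_perms=999, seed=args.seed)
    print(f"ANOSIM (season): R = {ano.r:.3f}, p = {ano.p_value:.4f} "
          f"({ano.n_permutations} permutations)")

    phases = meta["phase"].to_dict()
    for (g1, g2), res in simper(transformed, phases).items():
        res.table.round(6).to_csv(args.outdir / f"simper_{g1}_vs_{g2}.tsv",
                                  sep="\t", index=False)
        top = res.table.iloc[0]
        print(f"SIMPER {g1} vs {g2}: overall dissimilarity "
              f"{res.overall_dissimilarity:.2f}%, top feature {top['feature']} "
              f"({top['contrib_pct']:.1f}%)")

    nm = nmds(sim, k=2, restarts=20, seed=args.seed)
    nm.coords.round(6).to_csv(args.outdir / "nmds_coords.tsv", sep="\t")
    print(f"NMDS: stress-1 = {nm.stress:.4f} (best restart {nm.best_restart})")


if __name__ == "__main__":
    main()
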