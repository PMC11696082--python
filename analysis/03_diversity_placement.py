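#!/usr/bin/env python
"""Stage 3: distance-based placement of the assembled consensus genomes.

Takes the N-masked consensus sequences from results/pipeline/consensus.fasta,
computes pairwise p-distances (pairwise deletion of masked sites, in both
all-substitutions and transversions-only modes) against the true reference
panel, ranks each consensus against the panel (nearest-reference), and builds
a neighbor-joining tree over panel + consensus sequences. Each consensus
should place next to its own species' reference. Writes the distance matrix
and Newick tree under results/phylo/.
"""

import argparse
from pathlib import Path

from sedascope import (
    AlignedPanel,
    neighbor_joining,
    nearest_reference,
    pairwise_distance,
)
from sedascope.io import read_fasta, write_tsv


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scene", type=Path, default=Path("results/scene"))
    parser.add_argument("--pipeline", type=Path, default=Path("results/pipeline"))
    parser.add_argument("--outdir", type=Path, default=Path("results/phylo"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    panel = read_fasta(args.scene / "panel.fasta")
    consensus = read_fasta(args.pipeline / "consensus.fasta")
    references = AlignedPanel(labels=list(panel), sequences=list(panel.values()))

    print("nearest reference per consensus genome (all-substitution p-distance):")
    correct = 0
    for taxon, seq in consensus.items():
        ranked = nearest_reference(seq, references)
        top, dist, n_comp = ranked[0]
        hit = "OK" if top == taxon else "MISPLACED"
        if top == taxon:
            correct += 1
        print(f"  {taxon}: nearest={top} d={dist:.4f} over {n_comp} sites [{hit}]")
    print(f"{correct}/{len(consensus)} consensus genomes placed with their own species")

    labels = list(panel) + [f"{t}_consensus" for t in consensus]
    seqs = list(panel.values()) + list(consensus.values())
    joint = AlignedPanel(labels=labels, sequences=seqs)
    for mode, tag in (("all", "all"), ("transversions_only", "tv")):
        dm = pairwise_distance(joint, mode=mode)
        write_tsv(
            dm.to_frame().reset_index(names="taxon"),
            args.outdir / f"distances_{tag}.tsv",
        )
    tree = neighbor_joining(pairwise_distance(joint))
    (args.outdir / "nj_tree.nwk").write_text(tree.newick + "\n")
    print(f"NJ tree over {len(labels)} sequences written to {args.outdir / 'nj_tree.nwk'}")


if __name__ == "__main__":
    main()
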