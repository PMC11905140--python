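#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/data/: the focused-screen library and truth tables,
the tiling library and its fabricated CDS, an 8-species protein alignment,
and promoter occupancy / DE tables with planted target classes.  The bulky
FASTQ set (reduced 25x coverage; the scoring analyses re-simulate counts at
the full 1000x design coverage) goes under scratch/panel_fastq/.
"""

from pathlib import Path

import pandas as pd

from tilescreen.library import write_library
from tilescreen.simulate import (
    make_panel_library,
    make_planted_genes,
    make_screen_truth,
    make_tiling_library,
    simulate_alignment,
    simulate_occupancy_and_de,
    simulate_screen,
    write_narrowpeak,
)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "data"
SCRATCH = ROOT / "scratch"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    panel = make_panel_library(seed=SEED)
    write_library(panel, OUT / "panel_library.tsv")
    truth = make_screen_truth(panel, {"GENE01": -0.5}, seed=SEED, coverage=25)
    _, _, paths = simulate_screen(panel, truth, SCRATCH / "panel_fastq")
    truth.effects.rename_axis("guide_id").to_csv(OUT / "panel_truth_effects.tsv", sep="\t")
    print(f"focused screen: {len(panel)} guides, {len(paths)} FASTQ samples at 25x coverage")

    tiling, cds = make_tiling_library(seed=SEED)
    write_library(tiling, OUT / "tiling_library.tsv")
    (OUT / "tiling_cds.fasta").write_text(f">synthetic_cds\n{cds}\n")
    print(f"tiling library: {len(tiling)} guides over a {len(cds)}-nt CDS")

    aln, invariant = simulate_alignment(seed=SEED, length=500)
    with open(OUT / "alignment.fasta", "w") as fh:
        for name, seq in zip(aln.names, aln.sequences):
            fh.write(f">{name}\n{seq}\n")
    pd.DataFrame({"invariant": invariant}).rename_axis("column").to_csv(
        OUT / "alignment_truth.tsv", sep="\t"
    )
    print(f"alignment: {len(aln.names)} species x {aln.length} columns, "
          f"{invariant.sum()} invariant")

    genes, planted = make_planted_genes(n_genes=300, seed=SEED)
    peaks, de = simulate_occupancy_and_de(genes, planted)
    for (factor, cond), df in peaks.items():
        write_narrowpeak(df, OUT / f"{factor}_{cond}.narrowPeak")
    de.to_csv(OUT / "de_table.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g.gene_id, g.chromosome, g.tss, g.strand) for g in genes],
        columns=["gene_id", "chrom", "tss", "strand"],
    ).to_csv(OUT / "genes.tsv", sep="\t", index=False)
    planted.table.to_csv(OUT / "occupancy_truth.tsv", sep="\t")
    print(f"occupancy: {len(genes)} genes, "
          f"{(planted.table['true_class'] != 'unbound').sum()} planted bound targets")


if __name__ == "__main__":
    main()
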