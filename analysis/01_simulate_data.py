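#!/usr/bin/env python
"""Generate the synthetic study inputs every later stage consumes.

Emulated conditions: 20 genes whose annotations are off by up to +-20 nt
from the true start sites; short capped RNAs pausing 33-35 nt downstream
of the TSS with 20% divergent (antisense) transcription centered 150 nt
upstream; paired-end ChIP fragments whose centers mix around the TSS and
+110 nt; permanganate lanes with a +31..+51 bubble; and a 10-minute
triptolide decay series.  Everything is written under scratch/sim/.
"""

from pathlib import Path

import pausekit as pk
from pausekit import io as pio

SEED = 20240517
OUT = Path("scratch/sim")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    shift = {k: 1 / 9 for k in range(-20, 21, 5)}
    genes = pk.make_gene_panel(20, tss_shift_dist=shift, seed=SEED)
    pio.write_genes_bed(genes, OUT / "genes.bed")

    params = pk.KineticParams(seed=SEED + 1)
    reads = pk.generate_scrna_reads(genes, params, 3000, antisense_fraction=0.2)
    pio.write_scrna_bedpe(reads, OUT / "scrna.bedpe")
    print(f"scRNA: {len(reads)} paired-end reads for {len(genes)} genes")

    shear = pk.ShearBiasParams(seed=SEED + 2)  # empirical twin-peak mode
    frags = pk.generate_chip_fragments(genes, shear, 5000)
    pio.write_fragments_bed(frags, OUT / "chip_fragments.bed")
    print(f"ChIP: {len(frags)} fragments (centers mixed at 0 and +110 nt)")

    seq = ("TTAGCTTACGTTAGGCTTAACTGTTACGTATT" * 5)[:150]
    for label, fraction in [("uninduced", 0.4), ("induced", 0.935)]:
        lane = pk.generate_lane_profile(
            -30, 120, seq, (31, 51), fraction, noise_sd=0.2, seed=SEED + 3
        )
        pio.write_lane_tsv(lane, OUT / f"lane_{label}.tsv")
    print("lanes: +31..+51 bubble at occupancies 0.40 (uninduced), 0.935 (induced)")

    series = pk.generate_decay_series(
        10.0, [0, 5, 10, 20, 30], n_replicates=3, noise_sd=0.05, seed=SEED + 4
    )
    pio.write_decay_tsv(series, OUT / "decay.tsv")
    print("decay: t_half 10 min, 3 replicates, 5% noise")

    table = pk.generate_gene_table(1000, seed=SEED + 5)
    table.to_csv(OUT / "gene_scores.tsv", sep="\t", index=False)
    print(f"gene table: {len(table)} promoter enrichment scores")


if __name__ == "__main__":
    main()
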