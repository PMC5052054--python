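#!/usr/bin/env python
"""Generate the synthetic study: embryo series, junctions, annotated genome.

Writes expression matrices (TSV), ground-truth compositions and stage
programs, a junction count table, and the genome bundle (GFF3 +
bedGraph coverage + SL counts + chromatin + histone FASTA) under
``<outdir>/simulation/``.
"""

import argparse
import json
from pathlib import Path

from wormcycle import io
from wormcycle.synthetic_data import (
    GenomeConfig,
    SimulationConfig,
    simulate_genome,
    simulate_junctions,
    simulate_series,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.outdir / "simulation"
    out.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(n_genes=200, n_stages=20, seed=args.seed, lognormal_sd=0.2)
    series, truth = simulate_series(cfg)
    for sid, df in series.items():
        io.write_expression_tsv(df, out / f"{sid}.tsv")
        io.write_expression_tsv(truth.per_sample_composition[sid],
                                out / f"{sid}_composition_truth.tsv")
    io.write_expression_tsv(truth.stage_expression, out / "stage_expression_truth.tsv")
    (out / "sample_times.json").write_text(json.dumps(
        {sid: df.attrs["sample_times"] for sid, df in series.items()}, indent=2))

    table, jtruth = simulate_junctions(n_pairs=60, n_constitutive=40, n_samples=24,
                                       seed=args.seed)
    table.to_csv(out / "junctions.tsv", sep="\t", index=False)
    jtruth.to_csv(out / "junction_truth.tsv", sep="\t", index=False)

    g = simulate_genome(GenomeConfig(seed=args.seed))
    io.write_gff3(g["annotation"], out / "annotation.gff3")
    g["genes"].to_csv(out / "genes.tsv", sep="\t", index=False)
    for sample in g["samples"][:3]:  # a few coverage tracks are enough downstream
        io.write_bedgraph(g["coverage"][sample], out / f"coverage_{sample}.bedgraph")
    io.write_bedgraph(g["chromatin"], out / "chromatin.bedgraph")
    io.write_expression_tsv(g["expression"], out / "gene_expression.tsv")
    io.write_expression_tsv(g["sl1"], out / "sl1.tsv")
    io.write_expression_tsv(g["sl2"], out / "sl2.tsv")
    g["operon_truth"].to_csv(out / "operon_truth.tsv", sep="\t", index=False)
    for fam, members in g["histone_families"].items():
        io.write_fasta(members, out / f"histones_{fam}.fa")
    (out / "chrom_sizes.json").write_text(json.dumps(g["chrom_sizes"], indent=2))

    n_internal = int(g["operon_truth"].internal_promoter.sum())
    print(f"simulated {cfg.n_genes} genes x {cfg.n_stages} stages across "
          f"{len(series)} series; {len(table)} junctions; "
          f"{len(g['operon_truth'])} operons ({n_internal} with internal promoters); "
          f"{len(g['histone_families'])} histone clusters -> {out}")


if __name__ == "__main__":
    main()
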