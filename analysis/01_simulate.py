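#!/usr/bin/env python
"""Generate the synthetic study system used by all downstream analyses.

Builds a three-genome chromosome (two ingroups + outgroup) with 50 planted
structural events of known mechanism plus outgroup-private and minimum-length
decoys, synthetic gene models, a 101-variety breeding cohort (1905-2013) and
per-sample read evidence over the SV loci.  Everything is written under
results/sim/ and is reproducible from the fixed seed.
"""

import sys
from pathlib import Path

import numpy as np

from svlegacy import io
from svlegacy.alignment import write_alignment
from svlegacy.experiments import default_event_spec
from svlegacy.synthdata import (
    EventSpec,
    SimConfig,
    gen_ancestor,
    gen_gene_models,
    plant_events,
    simulate_read_evidence,
    simulate_trios,
)
from svlegacy.synthdata.cohort import build_loci_table, simulate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
OUT = Path("results/sim")
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    rng = np.random.default_rng(SEED)
    cfg = SimConfig(genome_length=400_000, seed=SEED, n_varieties=101, snp_count=120)

    anc = gen_ancestor(cfg.genome_length, cfg.gc_content, rng)
    spec = default_event_spec(rng, n_events=50)
    spec += [
        EventSpec("B", "te_ins", 1_000),
        EventSpec("B", "te_ins", 2_500),
        EventSpec("A", "te_ins", 1_000),
        EventSpec("A", "deletion", 50),  # exactly the minimum gap: a decoy
    ]
    seq_a, seq_b, seq_o, aln, truth = plant_events(anc, spec, rng)
    genes = gen_gene_models(cfg.genome_length, n_genes=60, seed=rng)

    io.write_fasta(
        {"ingroupA": seq_a, "ingroupB": seq_b, "outgroup": seq_o}, OUT / "genomes.fa"
    )
    write_alignment(aln, OUT / "chr1.aln.fa")
    io.write_gff3(genes, OUT / "genes.gff3")
    io.write_truth_table(truth, OUT / "truth.tsv")

    loci = build_loci_table(truth, cfg, rng, gene_models=genes)
    cohort = simulate_cohort(loci, cfg, rng)
    cohort.metadata.to_csv(OUT / "cohort.tsv", sep="\t", index=False)
    cohort.genotypes.T.to_csv(OUT / "genotypes_truth.tsv", sep="\t")
    cohort.loci.to_csv(OUT / "loci.tsv", sep="\t", index=False)

    # read evidence over SV loci for a 12-variety subsample (reference = A)
    sv = cohort.loci[cohort.loci.kind == "SV"].copy()
    ingroup = [e for e in truth.ingroup_events]
    sv_loci = sv.assign(
        chrom=truth.chrom,
        start=[ingroup[int(i.replace("sv", ""))].intervals["A"][0] for i in sv.locus_id],
        end=[ingroup[int(i.replace("sv", ""))].intervals["A"][1] for i in sv.locus_id],
    )[["locus_id", "chrom", "start", "end"]]
    sv_loci.to_csv(OUT / "sv_loci.tsv", sep="\t", index=False)
    subsample = cohort.genotypes.iloc[:12][sv_loci.locus_id]
    evidence = simulate_read_evidence(subsample, sv_loci, cfg, rng)
    io.write_read_evidence(evidence, OUT / "read_evidence.tsv")

    trios = simulate_trios(cohort, 25, miscall_rate=0.02, seed=rng)
    rows = []
    for t in trios:
        rows.append(
            {
                "progeny": t.progeny_id,
                "parent1": t.parent1_id,
                "parent2": t.parent2_id,
                "progeny_genotypes": ",".join(map(str, t.progeny)),
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(OUT / "trios.tsv", sep="\t", index=False)

    n_ingroup = len(truth.ingroup_events)
    print(f"simulated chr1: {aln.ncols:,} alignment columns")
    print(f"planted events: {len(truth.events)} ({n_ingroup} ingroup, "
          f"{len(truth.events) - n_ingroup} outgroup-private)")
    print(f"cohort: {cfg.n_varieties} varieties, {len(loci)} loci; "
          f"read evidence for {len(subsample)} samples; {len(trios)} trios")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    main()
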