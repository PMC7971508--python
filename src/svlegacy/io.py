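"""File-boundary helpers.

Internal coordinates are 0-based, half-open everywhere; GFF3 conversion to
1-based inclusive happens here and only here.
"""

from __future__ import annotations

import pandas as pd


def write_fasta(records: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write the tidy gene-model table (0-based half-open) as GFF3 (1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in genes.iterrows():
            attr = (
                f"ID={r.gene_id}" if r.feature == "gene" else f"Parent={r.gene_id}"
            )
            fh.write(
                f"{r.chrom}\tsvlegacy\t{r.feature}\t{int(r.start) + 1}\t{int(r.end)}\t"
                f".\t{r.strand}\t.\t{attr}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read GFF3/BED-like gene models into the tidy 0-based table.

    Keeps gene and exon features; BED input (detected by extension) is read as
    0-based half-open already.
    """
    path = str(path)
    if path.endswith(".bed"):
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = bed.iloc[:, :3].copy()
        df.columns = ["chrom", "start", "end"]
        df["feature"] = "exon"
        df["strand"] = "+"
        df["gene_id"] = [f"bed{i}" for i in range(len(df))]
        return df[["chrom", "feature", "start", "end", "strand", "gene_id"]]
    gff = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attr"],
    )
    gff = gff[gff.feature.isin(["gene", "exon"])].copy()
    gff["start"] = gff["start"].astype(int) - 1
    gff["end"] = gff["end"].astype(int)

    def _gid(a: str) -> str:
        for key in ("ID=", "Parent="):
            for part in a.split(";"):
                if part.startswith(key):
                    return part[len(key):]
        return a

    gff["gene_id"] = gff["attr"].map(_gid)
    return gff[["chrom", "feature", "start", "end", "strand", "gene_id"]].reset_index(drop=True)


def write_read_evidence(evidence: dict, path) -> None:
    """Long-format TSV: sample, chrom, start, end, is_split, is_softclipped."""
    frames = []
    for sample, ev in evidence.items():
        df = ev.reads.copy()
        df.insert(0, "sample", sample)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_read_evidence(path, depth: float = float("nan")) -> dict:
    from .synthdata.reads import ReadEvidence

    df = pd.read_csv(path, sep="\t")
    out = {}
    for sample, grp in df.groupby("sample", sort=False):
        out[str(sample)] = ReadEvidence(
            sample_id=str(sample),
            reads=grp.drop(columns=["sample"]).reset_index(drop=True),
            mean_depth=depth,
        )
    return out


def write_truth_table(truth, path) -> None:
    rows = []
    for ev in truth.events:
        rows.append(
            {
                "chrom": truth.chrom,
                "lineage": ev.lineage,
                "mechanism": ev.mechanism,
                "length": ev.length,
                "anc_start": ev.anc_interval[0],
                "anc_end": ev.anc_interval[1],
                "derived_start": ev.derived_interval[0],
                "derived_end": ev.derived_interval[1],
                "col_start": ev.col_interval[0],
                "col_end": ev.col_interval[1],
                "g_true": ev.g_true,
                "ambiguous": ev.ambiguous,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path) -> pd.DataFrame:
    """Loci x samples TSV with NA for missing, as written by the genotyper."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_vcf_haploid(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read biallelic sites from a VCF into the inbred haploid coding.

    Homozygous genotypes become 0/1 dosages, heterozygous calls 0.5 (they are
    filtered or masked downstream — all varieties are inbred), missing
    genotypes NaN.  Returns (varieties x sites matrix, per-site bp positions);
    site ids are "chrom:pos".
    """
    import numpy as np
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, list[float]] = {}
    positions: dict[str, int] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        site = f"{var.CHROM}:{var.POS}"
        gts = var.genotype.array()
        vals = []
        for row in gts:
            alleles = [a for a in row[:-1] if a >= 0]
            if not alleles:
                vals.append(np.nan)
            else:
                vals.append(float(sum(alleles)) / len(alleles))
        cols[site] = vals
        positions[site] = var.POS - 1  # back to 0-based
    matrix = pd.DataFrame(cols, index=samples)
    return matrix, pd.Series(positions, dtype=float)
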