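"""File interchange: FASTA, minimal phased VCF, and TSV tables.

Haplotype matrices travel either as a minimal VCF (phased GT, biallelic
SNVs; anything else is skipped and counted) or as a plain TSV with a
``position`` column followed by one column per haplotype.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .popgen import MISSING, HaplotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_haplotype_tsv",
    "write_haplotype_tsv",
    "read_vcf",
    "write_vcf",
    "read_labels_tsv",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_haplotype_tsv(matrix: HaplotypeMatrix, path) -> None:
    df = pd.DataFrame(
        matrix.alleles.T, index=matrix.site_positions, columns=matrix.sample_ids
    )
    df.index.name = "position"
    with open(path, "w") as fh:
        fh.write(f"#sequence_name={matrix.sequence_name}\n")
        df.replace(MISSING, ".").to_csv(fh, sep="\t")


def read_haplotype_tsv(path) -> HaplotypeMatrix:
    seq_name = "unknown"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#sequence_name="):
            seq_name = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
    alleles = df.replace(".", str(MISSING)).astype(np.int8).to_numpy().T
    return HaplotypeMatrix(
        seq_name, df.index.to_numpy(dtype=np.int64), alleles, list(df.columns)
    )


def read_vcf(path) -> HaplotypeMatrix:
    """Read phased biallelic SNVs from a minimal VCF into a matrix.

    Multi-allelic, non-SNV or unphased records are skipped with a logged
    count.  Sample columns expand to two haplotypes each (``<sample>_1/2``);
    positions convert from VCF 1-based to 0-based.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions, columns = [], []
    chrom = None
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        gts = var.genotypes  # [allele_a, allele_b, phased]
        if not all(g[2] for g in gts):
            skipped += 1
            continue
        col = np.empty(2 * len(samples), dtype=np.int8)
        for k, g in enumerate(gts):
            col[2 * k] = MISSING if g[0] < 0 else g[0]
            col[2 * k + 1] = MISSING if g[1] < 0 else g[1]
        chrom = var.CHROM
        positions.append(var.POS - 1)
        columns.append(col)
    if skipped:
        logger.warning("read_vcf: skipped %d non-biallelic/non-SNV/unphased records", skipped)
    if not positions:
        raise ValueError(f"no usable phased biallelic SNVs in {path}")
    sample_ids = [f"{s}_{i}" for s in samples for i in (1, 2)]
    return HaplotypeMatrix(chrom, np.asarray(positions), np.column_stack(columns), sample_ids)


def write_vcf(matrix: HaplotypeMatrix, path, ref: str = "A", alt: str = "T") -> None:
    """Write the matrix as a minimal phased VCF (synthetic REF/ALT bases)."""
    if matrix.n_haplotypes % 2:
        raise ValueError("odd haplotype count cannot be written as diploid VCF")
    samples = [matrix.sample_ids[i].rsplit("_", 1)[0] for i in range(0, matrix.n_haplotypes, 2)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={matrix.sequence_name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for s in range(matrix.n_sites):
            col = matrix.alleles[:, s]
            gts = []
            for k in range(0, matrix.n_haplotypes, 2):
                a = "." if col[k] == MISSING else str(int(col[k]))
                b = "." if col[k + 1] == MISSING else str(int(col[k + 1]))
                gts.append(f"{a}|{b}")
            fh.write(
                f"{matrix.sequence_name}\t{int(matrix.site_positions[s]) + 1}\t.\t"
                f"{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_labels_tsv(path) -> dict[str, str]:
    """Two-column TSV: haplotype_id, label (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("labels TSV needs two columns")
    if df.columns[0].lower() not in ("haplotype", "haplotype_id", "hap", "id"):
        # no header: first row is data
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
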