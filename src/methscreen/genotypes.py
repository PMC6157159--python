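"""Genotype dosage matrices: VCF/TSV input, MAF filtering, cis windows."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "read_genotypes_vcf",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "maf_filter",
    "cis_window",
]


@dataclass
class GenotypeMatrix:
    """Biallelic dosages (0/1/2 copies of the alternate allele, NaN missing).

    ``dosages``: (n_samples, n_snps) float array; ``snps``: DataFrame
    indexed by snp_id with columns ``chrom`` and ``pos`` (1-based bp).
    """

    sample_ids: list[str]
    snps: pd.DataFrame = field(repr=False)
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError("dosage matrix shape does not match sample/snp lists")
        v = self.dosages
        ok = np.isnan(v) | np.isin(v, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids, self.snps.loc[mask], self.dosages[:, mask])

    def restrict_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return GenotypeMatrix(list(sample_ids), self.snps, self.dosages[idx])


def maf_filter(g: GenotypeMatrix, min_maf: float = 0.01) -> GenotypeMatrix:
    """Keep SNPs with minor allele frequency strictly greater than ``min_maf``."""
    maf = g.maf()
    keep = np.nan_to_num(maf, nan=0.0) > min_maf
    return g.subset_snps(keep)


def cis_window(
    cpg_chrom: str, cpg_pos: int, g: GenotypeMatrix, half_width_bp: int = 1_000_000
) -> GenotypeMatrix:
    """SNPs on the CpG's chromosome within +/- half_width_bp (closed interval)."""
    chrom = g.snps["chrom"].astype(str).to_numpy()
    pos = g.snps["pos"].to_numpy()
    keep = (chrom == str(cpg_chrom)) & (np.abs(pos - int(cpg_pos)) <= half_width_bp)
    return g.subset_snps(keep)


# ---------------------------------------------------------------------------
# I/O


def read_genotypes_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic GT records from a VCF into a dosage matrix."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    snp_rows, columns = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic only
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        snp_rows.append({"snp_id": snp_id, "chrom": str(var.CHROM), "pos": int(var.POS)})
        gts = var.genotypes  # [allele1, allele2, phased]
        col = np.array(
            [np.nan if gt[0] < 0 or gt[1] < 0 else float(gt[0] + gt[1]) for gt in gts]
        )
        columns.append(col)
    snps = pd.DataFrame(snp_rows).set_index("snp_id") if snp_rows else pd.DataFrame(
        columns=["chrom", "pos"]
    )
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples, snps, dosages)


def write_genotypes_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write dosages as an unphased minimal VCF (REF=A, ALT=G placeholders)."""
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    order = np.lexsort((g.snps["pos"].to_numpy(), g.snps["chrom"].astype(str).to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(set(g.snps["chrom"].astype(str))):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j in order:
            row = g.snps.iloc[j]
            gts = [
                "./." if np.isnan(d) else gt_of[d] for d in g.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{g.snps.index[j]}\tA\tG\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_genotypes_tsv(g: GenotypeMatrix, dosage_path: str, snp_path: str) -> None:
    df = pd.DataFrame(g.dosages, index=g.sample_ids, columns=g.snp_ids)
    df.to_csv(dosage_path, sep="\t", index_label="sample_id", float_format="%g")
    g.snps.to_csv(snp_path, sep="\t", index_label="snp_id")


def read_genotypes_tsv(dosage_path: str, snp_path: str) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    snps = pd.read_csv(snp_path, sep="\t", index_col=0)
    snps.index = snps.index.astype(str)
    snps = snps.loc[df.columns]
    return GenotypeMatrix(list(df.index), snps, df.to_numpy(dtype=float))
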