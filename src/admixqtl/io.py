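"""Reading and writing the cohort's standard file formats.

Genotypes are exchanged as VCF v4.2 (biallelic SNPs, phased GT, PASS
filter, 1-based positions), expression as a BED-like tab-separated table
(chrom, start, end, gene_id, one column per sample; 0-based half-open
interval containing the TSS), and covariates / global ancestry / local
ancestry / simulation truth as TSVs with a header. VCF reading goes
through :mod:`cyvcf2`.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simulate import AdmixedCohort, ExpressionDataset

__all__ = [
    "write_vcf",
    "read_vcf_dosage",
    "write_expression_bed",
    "read_expression_bed",
    "write_cohort",
]


def write_vcf(cohort: AdmixedCohort, path: str | os.PathLike) -> None:
    """Write phased biallelic genotypes as VCF v4.2, sorted by position."""
    panel = cohort.panel
    n = cohort.n_individuals
    samples = [f"sample{i}" for i in range(n)]
    hap = cohort.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(panel.n_variants):
            gts = "\t".join(f"{hap[i, 0, j]}|{hap[i, 1, j]}" for i in range(n))
            fh.write(
                f"{panel.chrom}\t{panel.positions[j]}\t{panel.variant_ids[j]}\t"
                f"{panel.ref[j]}\t{panel.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf_dosage(path: str | os.PathLike) -> tuple[np.ndarray, list[str], np.ndarray, list[str]]:
    """Read a VCF into (dosage matrix, variant ids, positions, samples)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, pos, rows = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        ids.append(rec.ID)
        pos.append(rec.POS)
        gt = np.asarray(rec.genotype.array())[:, :2]
        rows.append(gt.sum(axis=1).astype(float))
    vcf.close()
    dosage = np.vstack(rows).T if rows else np.zeros((len(samples), 0))
    return dosage, ids, np.asarray(pos, dtype=np.int64), samples


def write_expression_bed(ds: ExpressionDataset, tss: np.ndarray, chrom: str, path: str | os.PathLike) -> None:
    samples = [f"sample{i}" for i in range(ds.expr.shape[1])]
    with open(path, "w") as fh:
        fh.write("#chr\tstart\tend\tgene_id\t" + "\t".join(samples) + "\n")
        for g, gid in enumerate(ds.gene_ids):
            vals = "\t".join(format(v, ".17g") for v in ds.expr[g])
            fh.write(f"{chrom}\t{tss[g] - 1}\t{tss[g]}\t{gid}\t{vals}\n")


def read_expression_bed(path: str | os.PathLike) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Read a BED-like expression table into (matrix, gene ids, tss)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    gene_ids = df["gene_id"].tolist()
    tss = df["end"].to_numpy(dtype=np.int64)
    expr = df.iloc[:, 4:].to_numpy(dtype=float)
    return expr, gene_ids, tss


def write_cohort(cohort: AdmixedCohort, expression: ExpressionDataset | None, outdir: str | os.PathLike) -> dict:
    """Write a cohort (and optional expression) to a directory of text files.

    Emits ``genotypes.vcf``, ``expression.bed`` (if given), ``covariates.tsv``
    (covariates plus global ancestry proportions), ``local_ancestry.tsv``
    (long format: gene x sample ancestral allele counts) and ``truth.tsv``.
    A read-back round trip reproduces dosages and expression exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": outdir / "genotypes.vcf", "covariates": outdir / "covariates.tsv",
             "local_ancestry": outdir / "local_ancestry.tsv"}
    write_vcf(cohort, paths["vcf"])

    panel = cohort.panel
    samples = [f"sample{i}" for i in range(cohort.n_individuals)]
    cov = cohort.covariates.copy()
    cov.insert(0, "sample", samples)
    for k, lab in enumerate(panel.pop_labels):
        cov[f"theta_{lab}"] = cohort.theta[:, k]
    cov.to_csv(paths["covariates"], sep="\t", index=False)

    la = cohort.local_anc
    recs = []
    for g, gid in enumerate(panel.gene_ids):
        for i, s in enumerate(samples):
            recs.append([gid, s] + la[g, i].tolist())
    pd.DataFrame(recs, columns=["gene_id", "sample"] + [f"n_{lab}" for lab in panel.pop_labels]).to_csv(
        paths["local_ancestry"], sep="\t", index=False
    )

    if expression is not None:
        paths["expression"] = outdir / "expression.bed"
        paths["truth"] = outdir / "truth.tsv"
        write_expression_bed(expression, panel.tss, panel.chrom, paths["expression"])
        expression.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
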