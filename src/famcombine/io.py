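"""Readers for genotypes (VCF or dosage matrix), gene maps and phenotypes."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .lmm import PhenotypeData
from .stats import GeneGenotypes, GeneSkippedError

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf_genes",
    "read_dosage_matrix",
    "read_gene_bed",
    "read_variant_gene_map",
    "read_phenotype_table",
]


def read_gene_bed(path) -> pd.DataFrame:
    """4-column BED-like gene map: chrom, start, end, gene_id (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError("gene intervals must satisfy start < end")
    return df


def read_variant_gene_map(path) -> dict[str, str]:
    """Two-column variant_id -> gene_id map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["variant_id", "gene_id"], dtype=str)
    return dict(zip(df["variant_id"], df["gene_id"]))


def read_vcf_genes(
    path,
    gene_bed: pd.DataFrame | None = None,
    variant_map: dict[str, str] | None = None,
    max_maf: float | None = None,
) -> tuple[list[GeneGenotypes], list[str]]:
    """Read GT dosages from a VCF and group variants into genes.

    Gene membership comes from the BED-like table (interval overlap of the
    variant position) or an explicit variant -> gene map; with neither, all
    variants form one gene named after the file. Missing calls are
    mean-imputed per variant; dosages are oriented to the minor allele.
    Returns the testable genes plus the VCF sample order.
    """
    from cyvcf2 import VCF

    if gene_bed is not None and variant_map is not None:
        raise ValueError("give either a gene BED or a variant map, not both")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    by_gene: dict[str, list[tuple[str, np.ndarray]]] = {}
    for var in vcf:
        gts = var.genotypes  # [allele0, allele1, phased]
        dosage = np.array(
            [a0 + a1 if (a0 >= 0 and a1 >= 0) else np.nan for a0, a1, *_ in gts],
            dtype=float,
        )
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if variant_map is not None:
            gene_ids = [variant_map[vid]] if vid in variant_map else []
        elif gene_bed is not None:
            hit = gene_bed[
                (gene_bed["chrom"] == str(var.CHROM))
                & (gene_bed["start"] <= var.POS - 1)
                & (var.POS - 1 < gene_bed["end"])
            ]
            gene_ids = list(hit["gene_id"])
        else:
            gene_ids = ["all_variants"]
        for gid in gene_ids:
            by_gene.setdefault(gid, []).append((vid, dosage))
    genes = []
    for gid, pairs in by_gene.items():
        ids = [v for v, _ in pairs]
        G = np.vstack([d for _, d in pairs])
        G = np.where(np.isnan(G), -1.0, G)  # from_dosages mean-imputes negatives
        try:
            genes.append(GeneGenotypes.from_dosages(gid, G, ids, max_maf=max_maf))
        except GeneSkippedError as exc:
            logger.warning("%s", exc)
    return genes, samples


def read_dosage_matrix(
    path, gene_id: str | None = None, max_maf: float | None = None
) -> tuple[GeneGenotypes, list[str]]:
    """Tab-delimited variant x sample dosage matrix (first column variant IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    gene = GeneGenotypes.from_dosages(
        gene_id or "all_variants",
        df.to_numpy(dtype=float),
        [str(v) for v in df.index],
        max_maf=max_maf,
    )
    return gene, [str(c) for c in df.columns]


def read_phenotype_table(
    path, trait: str, covariates: list[str] | None = None, id_col: str = "ID"
) -> PhenotypeData:
    """Tab-delimited phenotype/covariate table with a header row."""
    df = pd.read_csv(path, sep="\t")
    if id_col not in df.columns or trait not in df.columns:
        raise ValueError(f"phenotype table must contain columns {id_col!r} and {trait!r}")
    return PhenotypeData.from_dataframe(df, trait, covariates, id_col=id_col)
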