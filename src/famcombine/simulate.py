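"""Synthetic pedigrees, gene-dropped genotypes and polygenic traits.

The generator emulates the structure of a large family study of a
quantitative blood-pressure-like trait: ~20 extended pedigrees totalling
~840 individuals, genes carrying a handful to a couple of hundred variants
with mostly rare minor alleles, and a trait with kinship-proportional
polygenic covariance. Two trait regimes are produced: a genotype-linked
trait (for power experiments) and a heritable but genotype-independent
trait (for type-I-error experiments).

Genotypes are generated by gene dropping: founder alleles are drawn
per-variant from Bernoulli(maf) and transmitted through the pedigree by
Mendelian sampling (one random allele per parent), so genotypes are
Mendelian-consistent by construction. Variants are independent (no LD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import PhenotypeData
from .pedigree import KinshipMatrix, Pedigree, kinship_matrix
from .stats import GeneGenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "simulate_pedigrees",
    "gene_drop",
    "simulate_trait",
    "simulate_study",
    "estimate_kinship_gene_drop",
    "mean_arterial_pressure",
    "write_ped",
    "write_vcf",
    "write_phenotypes",
]


@dataclass
class SimConfig:
    """Study-generation parameters.

    Defaults mirror the evaluation conditions: 20 three-generation
    pedigrees of 42 members (840 individuals), 30-variant genes with
    mostly rare minor alleles (uniform maf in [0.001, 0.05], with an
    optional common-variant fraction), polygenic heritability 0.3, and a
    unit-variance trait. Effect sizes for causal variants follow
    beta_v = c * |log10(maf_v)| with c scaled so the genic part explains
    ``genic_variance`` of the (non-genic) trait variance.
    """

    n_families: int = 20
    family_template: str = "three_generation"
    children_per_couple: int = 5
    grandchildren_per_couple: int = 6
    n_variants: int = 30
    maf_range: tuple[float, float] = (0.001, 0.05)
    common_fraction: float = 0.0
    common_maf_range: tuple[float, float] = (0.05, 0.3)
    h2: float = 0.3
    causal_fraction: float = 0.3
    causal_maf_range: tuple[float, float] | None = None
    effect_model: str = "same_direction"
    genic_variance: float = 0.05
    effect_size_scale: float | None = None
    trait_sd: float = 1.0
    covariate_effect: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("common_fraction", "causal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must be in [0, 1)")
        if min(self.n_families, self.n_variants) < 1:
            raise ValueError("counts must be >= 1")
        if self.family_template not in ("three_generation", "nuclear", "founders"):
            raise ValueError(f"unknown family template {self.family_template!r}")


@dataclass
class SimulatedStudy:
    """One generated data set plus the ground truth of its architecture."""

    pedigree: Pedigree
    genotypes: list[GeneGenotypes]
    trait: PhenotypeData
    truth: dict
    kinship: KinshipMatrix = field(repr=False, default=None)


def _family(cfg: SimConfig, fam: str, rng) -> tuple[list, dict, dict, dict]:
    """Rows for one family; IDs are globally unique strings."""
    counter = iter(range(1, 10_000))

    def new(sex):
        return f"{fam}-I{next(counter):03d}", sex

    rows, parent, famid, sex = [], {}, {}, {}

    def add(iid, sx, fa=None, mo=None):
        rows.append(iid)
        parent[iid] = (fa, mo)
        famid[iid] = fam
        sex[iid] = sx

    pa, _ = new("male")
    ma, _ = new("female")
    add(pa, "male")
    add(ma, "female")
    if cfg.family_template == "founders":
        return rows, parent, famid, sex
    n_child = cfg.children_per_couple
    for c in range(n_child):
        child_sex = "male" if c % 2 == 0 else "female"
        child, _ = new(child_sex)
        add(child, child_sex, pa, ma)
        if cfg.family_template == "three_generation":
            sp_sex = "female" if child_sex == "male" else "male"
            spouse, _ = new(sp_sex)
            add(spouse, sp_sex)
            fa, mo = (child, spouse) if child_sex == "male" else (spouse, child)
            for g in range(cfg.grandchildren_per_couple):
                gsex = "male" if g % 2 == 0 else "female"
                gc, _ = new(gsex)
                add(gc, gsex, fa, mo)
    return rows, parent, famid, sex


def simulate_pedigrees(cfg: SimConfig, rng=None) -> Pedigree:
    """``n_families`` disjoint pedigrees from the chosen template.

    The default template (a founder couple, 5 married children, 6
    grandchildren per couple) has 42 members, so 20 families give 840
    individuals — the scale of a large extended-pedigree study.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    individuals, parent_map, family_ids, sex = [], {}, {}, {}
    for f in range(cfg.n_families):
        rows, parent, famid, sx = _family(cfg, f"F{f + 1:02d}", rng)
        individuals.extend(rows)
        parent_map.update(parent)
        family_ids.update(famid)
        sex.update(sx)
    ped = Pedigree(individuals, parent_map, family_ids, sex)
    logger.info(
        "simulated %d individuals in %d families (%d founders)",
        ped.n, cfg.n_families, len(ped.founders()),
    )
    return ped


def _draw_mafs(cfg: SimConfig, rng) -> np.ndarray:
    maf = rng.uniform(*cfg.maf_range, size=cfg.n_variants)
    n_common = int(round(cfg.common_fraction * cfg.n_variants))
    if n_common:
        maf[:n_common] = rng.uniform(*cfg.common_maf_range, size=n_common)
        rng.shuffle(maf)
    return maf


def _drop_alleles(ped: Pedigree, founder_draw, rng) -> np.ndarray:
    """Transmit founder alleles through the pedigree; (n, p, 2) array.

    ``founder_draw(iid)`` returns the (p, 2) allele array for a founder.
    """
    order = ped.topological_order()
    pos = {iid: k for k, iid in enumerate(order)}
    first = founder_draw(order[0])
    p = first.shape[0]
    alleles = np.zeros((len(order), p, 2), dtype=first.dtype)
    for iid in order:
        k = pos[iid]
        fa, mo = ped.parent_map.get(iid, (None, None))
        if fa is None and mo is None:
            alleles[k] = founder_draw(iid)
            continue
        for slot, par in enumerate((fa, mo)):
            if par is None:  # unique unrelated founder allele
                alleles[k, :, slot] = founder_draw(iid)[:, slot]
            else:
                pick = rng.integers(0, 2, size=p)
                alleles[k, :, slot] = alleles[pos[par], np.arange(p), pick]
    keep = np.array([pos[i] for i in ped.individuals])
    return alleles[keep]


def gene_drop(
    ped: Pedigree, cfg: SimConfig, rng=None, maf: np.ndarray | None = None, gene_id: str = "GENE1"
) -> GeneGenotypes:
    """Gene-drop genotypes for one gene (independent variants, no LD)."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    maf = _draw_mafs(cfg, rng) if maf is None else np.asarray(maf, dtype=float)
    p = maf.size

    def founder_draw(_iid):
        return (rng.random((p, 2)) < maf[:, None]).astype(np.int8)

    alleles = _drop_alleles(ped, founder_draw, rng)
    dosage = alleles.sum(axis=2).T.astype(float)  # variants x samples
    ids = [f"{gene_id}_v{j + 1}" for j in range(p)]
    # minor-allele orientation + drop of realised-monomorphic variants
    return GeneGenotypes.from_dosages(gene_id, dosage, ids)


def estimate_kinship_gene_drop(ped: Pedigree, n_drops: int, seed: int = 0):
    """Monte-Carlo kinship from gene dropping of uniquely labelled alleles.

    Independent of the recursive computation: every founder allele gets a
    unique label, labels are transmitted Mendelianly ``n_drops`` times, and
    phi(i, j) is estimated as the average probability that randomly chosen
    alleles of i and j are identical by descent. Returns ``(phi_hat, se)``
    aligned with ``ped.individuals``.
    """
    rng = np.random.default_rng(seed)
    label = iter(range(1, 10**9))

    def founder_draw(iid):
        # same labels every drop (drops dimension = n_drops)
        pair = founder_labels.setdefault(iid, (next(label), next(label)))
        out = np.empty((n_drops, 2), dtype=np.int64)
        out[:, 0], out[:, 1] = pair
        return out

    founder_labels: dict[str, tuple[int, int]] = {}
    alleles = _drop_alleles(ped, founder_draw, rng)  # (n, n_drops, 2)
    n = alleles.shape[0]
    phi_hat = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        ai = alleles[i]
        for j in range(i, n):
            aj = alleles[j]
            match = np.zeros(n_drops)
            for a in range(2):
                for b in range(2):
                    match += ai[:, a] == aj[:, b]
            per_drop = match / 4.0
            phi_hat[i, j] = phi_hat[j, i] = per_drop.mean()
            se[i, j] = se[j, i] = per_drop.std(ddof=1) / np.sqrt(n_drops)
    return phi_hat, se


def simulate_trait(
    ped: Pedigree,
    genotypes: GeneGenotypes | None,
    cfg: SimConfig,
    rng=None,
    kinship: KinshipMatrix | None = None,
    chol: np.ndarray | None = None,
) -> tuple[PhenotypeData, dict]:
    """Polygenic quantitative trait, optionally with genic effects.

    y = X beta + sum_causal beta_v g_v + a + e with a ~ N(0, sigma_g^2 2Phi)
    and e ~ N(0, sigma_e^2 I); sigma_g^2 = h2 * trait_sd^2 and sigma_e^2 =
    (1 - h2) * trait_sd^2, so h2 is the heritability of the non-genic
    variance. ``genotypes=None`` yields the heritable, genotype-independent
    null trait used for type-I-error experiments. Covariates are an
    intercept plus one standard-normal covariate.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    n = ped.n
    if chol is None:
        kin = kinship if kinship is not None else kinship_matrix(ped)
        A = kin.subset(ped.individuals).relationship()
        chol = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    L = chol
    sigma_g = np.sqrt(cfg.h2) * cfg.trait_sd
    sigma_e = np.sqrt(1.0 - cfg.h2) * cfg.trait_sd
    a = sigma_g * (L @ rng.standard_normal(n))
    e = sigma_e * rng.standard_normal(n)
    covar = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), covar])
    beta = np.array([0.0, cfg.covariate_effect])
    y = X @ beta + a + e

    betas = np.zeros(0)
    causal = np.zeros(0, dtype=bool)
    scale = 0.0
    if genotypes is not None:
        p = genotypes.n_variants
        causal = np.zeros(p, dtype=bool)
        lo, hi = cfg.causal_maf_range or (0.0, 0.5)
        eligible = np.where((genotypes.maf >= lo) & (genotypes.maf <= hi))[0]
        n_causal = int(round(cfg.causal_fraction * eligible.size))
        if n_causal:
            causal[rng.choice(eligible, size=n_causal, replace=False)] = True
        betas = np.zeros(p)
        betas[causal] = np.abs(np.log10(genotypes.maf[causal]))
        if cfg.effect_model == "mixed_direction":
            betas[causal] *= rng.choice([-1.0, 1.0], size=n_causal)
        elif cfg.effect_model != "same_direction":
            raise ValueError(f"unknown effect model {cfg.effect_model!r}")
        genic = betas @ genotypes.G
        v = genic.var()
        if v > 0:
            if cfg.effect_size_scale is not None:
                scale = cfg.effect_size_scale
            else:
                scale = np.sqrt(cfg.genic_variance * cfg.trait_sd**2 / v)
            betas *= scale
            y = y + scale * genic
    data = PhenotypeData(y, X, list(ped.individuals), ["intercept", "covar1"])
    truth = {
        "beta_covariates": beta,
        "variant_betas": betas,
        "causal": causal,
        "effect_scale": scale,
        "sigma_g2": sigma_g**2,
        "sigma_e2": sigma_e**2,
    }
    return data, truth


def simulate_study(cfg: SimConfig, n_genes: int = 1, null_trait: bool = False) -> SimulatedStudy:
    """Pedigree + genotypes + trait in one call, fully determined by cfg.seed."""
    root = np.random.SeedSequence(cfg.seed)
    s_ped, s_geno, s_trait = root.spawn(3)
    ped = simulate_pedigrees(cfg, np.random.default_rng(s_ped))
    rng_g = np.random.default_rng(s_geno)
    genes = [gene_drop(ped, cfg, rng_g, gene_id=f"GENE{k + 1}") for k in range(n_genes)]
    kin = kinship_matrix(ped)
    trait, truth = simulate_trait(
        ped, None if null_trait else genes[0], cfg, np.random.default_rng(s_trait), kinship=kin
    )
    return SimulatedStudy(ped, genes, trait, truth, kin)


def mean_arterial_pressure(dbp, sbp):
    """MAP = (2/3) * diastolic + (1/3) * systolic (mmHg)."""
    return (2.0 / 3.0) * np.asarray(dbp, float) + (1.0 / 3.0) * np.asarray(sbp, float)


# -- plain-text writers matching the dialects the readers accept -------------

_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


def write_ped(ped: Pedigree, path, phenotype: np.ndarray | None = None) -> None:
    with open(path, "w") as fh:
        for k, iid in enumerate(ped.individuals):
            fa, mo = ped.parent_map.get(iid, (None, None))
            pheno = "-9" if phenotype is None else f"{phenotype[k]:.6g}"
            fh.write(
                "\t".join(
                    [
                        ped.family_ids[iid],
                        iid,
                        fa or "0",
                        mo or "0",
                        _SEX_OUT.get(ped.sex.get(iid, "unknown"), "0"),
                        pheno,
                    ]
                )
                + "\n"
            )


def write_vcf(genes: list[GeneGenotypes], sample_ids: list[str], path, chrom: str = "3") -> None:
    """Minimal VCF v4.2 with GT only; ALT is the minor allele by construction."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=%s>\n" % chrom)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        pos = 0
        for gene in genes:
            pos += 10_000
            for i, vid in enumerate(gene.variant_ids):
                pos += 10
                calls = "\t".join(gt[int(round(d))] for d in gene.G[i])
                fh.write(f"{chrom}\t{pos}\t{vid}\tA\tC\t.\t.\tGENE={gene.gene_id}\tGT\t{calls}\n")


def write_phenotypes(trait: PhenotypeData, path) -> None:
    cols = {"ID": trait.sample_order, "trait": trait.y}
    names = trait.covariate_names or [f"x{j}" for j in range(trait.X.shape[1])]
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        cols[name] = trait.X[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
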