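"""Replicate-level type-I-error, power and test-correlation experiments.

Design follows the standard evaluation protocol for family-based gene
tests: genotypes (and the pedigree) are generated once per experiment and
held fixed, a fresh phenotype is simulated for every replicate, the full
null-model + permutation-combination pipeline runs on each, and the
rejection proportion at a nominal level is reported per individual test
and for the combined min-p test, with exact binomial confidence intervals.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .combine import GeneTestSpec, run_gene
from .lmm import FamilialLMM
from .simulate import SimConfig, gene_drop, simulate_pedigrees, simulate_trait
from .pedigree import kinship_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentReport",
    "run_level_experiment",
    "run_power_experiment",
    "pvalue_correlations",
]


@dataclass
class ExperimentReport:
    """Rejection rates with exact binomial CIs plus per-replicate p-values."""

    kind: str
    alpha: float
    m: int
    replicates: int
    seed: int
    n_individuals: int
    n_variants: int
    rejection_rates: dict[str, float]
    ci99: dict[str, tuple[float, float]]
    pvalues: pd.DataFrame = field(repr=False)
    runtime_s: float = 0.0

    def __post_init__(self) -> None:
        for name, rate in self.rejection_rates.items():
            lo, hi = self.ci99[name]
            if not (0.0 <= lo <= hi <= 1.0 and 0.0 <= rate <= 1.0):
                raise ValueError(f"malformed rate/CI for {name}")

    def summary(self) -> str:
        rows = pd.DataFrame(
            {
                "rejection_rate": self.rejection_rates,
                "ci99_low": {k: v[0] for k, v in self.ci99.items()},
                "ci99_high": {k: v[1] for k, v in self.ci99.items()},
            }
        )
        return (
            f"{self.kind} experiment: {self.replicates} replicates, "
            f"alpha = {self.alpha}, m = {self.m}, n = {self.n_individuals}, "
            f"variants = {self.n_variants}, seed = {self.seed}\n\n"
            + rows.to_string(float_format=lambda v: f"{v:.4f}")
        )

    def to_json(self, path) -> None:
        payload = {
            "kind": self.kind,
            "alpha": self.alpha,
            "m": self.m,
            "replicates": self.replicates,
            "seed": self.seed,
            "n_individuals": self.n_individuals,
            "n_variants": self.n_variants,
            "rejection_rates": self.rejection_rates,
            "ci99": {k: list(v) for k, v in self.ci99.items()},
            "runtime_s": self.runtime_s,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_tsv(self, path) -> None:
        self.pvalues.to_csv(path, sep="\t", index=False)


def _experiment(
    cfg: SimConfig,
    replicates: int,
    alpha: float,
    m: int,
    seed: int,
    null_trait: bool,
    spec: GeneTestSpec | None,
    method: str = "ML",
) -> ExperimentReport:
    if replicates < 50:
        raise ValueError("need at least 50 replicates for a stable rate estimate")
    t0 = time.perf_counter()
    spec = spec or GeneTestSpec()
    root = np.random.SeedSequence(seed)
    s_ped, s_geno, s_traits = root.spawn(3)
    ped = simulate_pedigrees(cfg, np.random.default_rng(s_ped))
    gene = gene_drop(ped, cfg, np.random.default_rng(s_geno))
    kin = kinship_matrix(ped)
    A = kin.relationship()
    d, V = np.linalg.eigh(A)
    d = np.clip(d, 0.0, None)
    chol = np.linalg.cholesky(A + 1e-10 * np.eye(ped.n))

    rows = []
    trait_seeds = s_traits.spawn(replicates)
    for r in range(replicates):
        ss = trait_seeds[r]
        rng = np.random.default_rng(ss)
        trait, _ = simulate_trait(
            ped, None if null_trait else gene, cfg, rng, chol=chol
        )
        fit = FamilialLMM(trait.y, trait.X, A, eig=(d, V)).fit(method=method)
        gene_master = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
        res = run_gene(gene, fit, spec, m=m, seed=gene_master)
        row = dict(res.per_test_p)
        row["combined"] = res.combined_p
        rows.append(row)
    pvals = pd.DataFrame(rows)
    rates, ci = {}, {}
    for col in pvals.columns:
        k = int((pvals[col] <= alpha).sum())
        rates[col] = k / replicates
        interval = binomtest(k, replicates).proportion_ci(confidence_level=0.99, method="exact")
        ci[col] = (float(interval.low), float(interval.high))
    return ExperimentReport(
        kind="level" if null_trait else "power",
        alpha=alpha,
        m=m,
        replicates=replicates,
        seed=seed,
        n_individuals=ped.n,
        n_variants=gene.n_variants,
        rejection_rates=rates,
        ci99=ci,
        pvalues=pvals,
        runtime_s=time.perf_counter() - t0,
    )


def run_level_experiment(
    cfg: SimConfig,
    replicates: int = 200,
    alpha: float = 0.05,
    m: int = 1000,
    seed: int = 0,
    spec: GeneTestSpec | None = None,
) -> ExperimentReport:
    """Type-I-error experiment on a heritable, genotype-independent trait."""
    return _experiment(cfg, replicates, alpha, m, seed, null_trait=True, spec=spec)


def run_power_experiment(
    cfg: SimConfig,
    replicates: int = 200,
    alpha: float = 0.05,
    m: int = 1000,
    seed: int = 0,
    spec: GeneTestSpec | None = None,
) -> ExperimentReport:
    """Power experiment: trait carries genic effects per the architecture."""
    return _experiment(cfg, replicates, alpha, m, seed, null_trait=False, spec=spec)


def pvalue_correlations(pvalues: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of per-test p-values across replicates.

    Constant columns yield undefined (NaN) entries and a logged warning
    rather than a silent zero.
    """
    if len(pvalues) < 30:
        raise ValueError("need at least 30 replicates for correlation estimates")
    constant = [c for c in pvalues.columns if pvalues[c].nunique() <= 1]
    if constant:
        logger.warning("constant p-value columns (correlation undefined): %s", constant)
    corr = pvalues.corr()
    np.fill_diagonal(corr.values, 1.0)
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = 1.0
    return corr
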