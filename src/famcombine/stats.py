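"""Per-variant score statistics, variant weights and the 8 gene-level tests.

For variant i with genotype vector g_i (minor-allele dosage), the score
statistic under the fitted familial null model is

    U_i = (y - X B-hat)' Sigma^-1 g_i .

Two weighting schemes are supported: the SKAT-style Beta-density weights
w_i = Beta(maf_i; a1, a2) (default a1=1, a2=25, sharply down-weighting
common variants) and the milder allele-frequency standardisation
w*_i = 1 / sqrt(p_i (1 - p_i)).

Eight gene-level statistics combine the weighted scores, four burden-type
(odd powers, signal with a shared direction) and four variance-component-
type (even powers, robust to mixed directions):

    Q1 = |sum w_i U_i|        Q2 = sum w_i^2 U_i^2
    Q3 = |sum w_i^3 U_i^3|    Q4 = sum w_i^4 U_i^4

with starred versions using w* in place of w. Q2 corresponds to the
famSKAT statistic; Q1 to a classical weighted burden test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "TEST_NAMES",
    "GeneGenotypes",
    "WeightScheme",
    "GeneSkippedError",
    "score_vector",
    "variant_weights",
    "gene_statistics",
    "gene_statistics_table",
]

#: canonical test order: variance-component / burden pairs by power
TEST_NAMES = ("Q2", "Q2*", "Q1", "Q1*", "Q4", "Q4*", "Q3", "Q3*")

_POWER = {"Q1": 1, "Q2": 2, "Q3": 3, "Q4": 4}


class GeneSkippedError(ValueError):
    """Gene cannot be tested (e.g. no polymorphic variants left)."""


@dataclass
class GeneGenotypes:
    """Dosage matrix for one gene: variants x samples, entries in {0,1,2}."""

    gene_id: str
    G: np.ndarray
    variant_ids: list[str]
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.maf = np.asarray(self.maf, dtype=float).ravel()
        if self.G.shape[0] != len(self.variant_ids) or self.G.shape[0] != self.maf.size:
            raise ValueError("variant dimension mismatch in GeneGenotypes")
        freq = self.G.mean(axis=1) / 2.0
        if not np.allclose(np.minimum(freq, 1 - freq), self.maf, atol=1e-12):
            raise ValueError("stored maf does not match genotype matrix")

    @property
    def n_variants(self) -> int:
        return self.G.shape[0]

    @property
    def n_samples(self) -> int:
        return self.G.shape[1]

    @classmethod
    def from_dosages(
        cls,
        gene_id: str,
        dosages: np.ndarray,
        variant_ids: list[str],
        max_maf: float | None = None,
    ) -> "GeneGenotypes":
        """Orient dosages to the minor allele, drop monomorphic variants.

        Missing entries (negative or NaN) are mean-imputed per variant
        before orientation; drops are logged. Raises
        :class:`GeneSkippedError` if nothing polymorphic remains.
        """
        G = np.atleast_2d(np.asarray(dosages, dtype=float)).copy()
        bad = ~np.isfinite(G) | (G < 0)
        if bad.any():
            logger.info("%s: mean-imputing %d missing genotype entries", gene_id, int(bad.sum()))
            for i in np.where(bad.any(axis=1))[0]:
                row = G[i]
                ok = ~bad[i]
                row[~ok] = row[ok].mean() if ok.any() else 0.0
        freq = G.mean(axis=1) / 2.0
        flip = freq > 0.5
        G[flip] = 2.0 - G[flip]
        maf = np.where(flip, 1.0 - freq, freq)
        keep = maf > 0.0
        if max_maf is not None:
            keep &= maf <= max_maf
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("%s: dropping %d monomorphic/filtered variants", gene_id, n_drop)
        if not keep.any():
            raise GeneSkippedError(f"gene {gene_id!r} has no usable polymorphic variants")
        ids = [v for v, k in zip(variant_ids, keep) if k]
        return cls(gene_id, G[keep], ids, maf[keep])


@dataclass
class WeightScheme:
    """Variant weighting: ``wu_beta`` (Beta density) or ``price`` (1/sqrt(pq))."""

    kind: str = "wu_beta"
    a1: float = 1.0
    a2: float = 25.0

    def __post_init__(self) -> None:
        if self.kind not in ("wu_beta", "price"):
            raise ValueError(f"unknown weight scheme {self.kind!r}")
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("Beta shape parameters must be positive")


def score_vector(residual: np.ndarray, Sigma_inv: np.ndarray, G) -> np.ndarray:
    """U_i = residual' Sigma^-1 g_i for every variant of the gene.

    ``residual`` is (y - X B-hat) for the observed statistics, or a permuted
    residual vector standing in for it.
    """
    Gm = G.G if isinstance(G, GeneGenotypes) else np.atleast_2d(np.asarray(G, float))
    r = np.asarray(residual, dtype=float).ravel()
    Sigma_inv = np.asarray(Sigma_inv, dtype=float)
    if Sigma_inv.shape != (r.size, r.size) or Gm.shape[1] != r.size:
        raise ValueError("dimension mismatch between residual, Sigma_inv and genotypes")
    return Gm @ (Sigma_inv @ r)


def variant_weights(maf: np.ndarray, scheme: WeightScheme) -> np.ndarray:
    """Per-variant weights under the given scheme.

    Under ``price``, variants with maf exactly 0 or 1 get weight 0 (they
    carry no score signal; logged) rather than an infinite weight.
    """
    maf = np.asarray(maf, dtype=float).ravel()
    if ((maf < 0) | (maf > 1)).any():
        raise ValueError("maf outside [0, 1]")
    if scheme.kind == "wu_beta":
        return sps.beta.pdf(maf, scheme.a1, scheme.a2)
    fixed = (maf == 0.0) | (maf == 1.0)
    if fixed.any():
        logger.info("excluding %d fixed variants from price weighting", int(fixed.sum()))
    w = np.zeros_like(maf)
    pq = maf[~fixed] * (1.0 - maf[~fixed])
    w[~fixed] = 1.0 / np.sqrt(pq)
    return w


def gene_statistics_table(
    U: np.ndarray,
    w: np.ndarray,
    w_star: np.ndarray,
    tests: tuple[str, ...] = TEST_NAMES,
) -> np.ndarray:
    """Vectorised statistics for a block of score vectors.

    ``U`` has shape (rows, n_variants) — one row per permutation — and the
    result has shape (rows, len(tests)).
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if U.shape[1] == 0:
        raise GeneSkippedError("empty variant set")
    out = np.empty((U.shape[0], len(tests)))
    cache: dict[str, np.ndarray] = {}
    for j, name in enumerate(tests):
        base = name.rstrip("*")
        if base not in _POWER:
            raise ValueError(f"unknown test statistic {name!r}")
        d = _POWER[base]
        key = "star" if name.endswith("*") else "plain"
        if key not in cache:
            cache[key] = U * (w_star if key == "star" else w)[None, :]
        wu = cache[key]
        s = (wu**d).sum(axis=1)
        out[:, j] = np.abs(s) if d % 2 else s
    return out


def gene_statistics(
    U: np.ndarray,
    w: np.ndarray,
    w_star: np.ndarray,
    tests: tuple[str, ...] = TEST_NAMES,
) -> dict[str, float]:
    """The requested gene-level statistics for a single score vector."""
    row = gene_statistics_table(np.atleast_2d(U), w, w_star, tests)[0]
    return {name: float(v) for name, v in zip(tests, row)}
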