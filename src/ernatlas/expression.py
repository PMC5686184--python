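"""FPKM computation and eRNA-to-gene expression association.

An eRNA region is associated with the gene whose TSS is closest to the
region midpoint (ties broken towards the leftmost TSS), and the
association is quantified by the Spearman rank correlation of the two
FPKM profiles across cell types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import Annotation, GenomicInterval

__all__ = [
    "ExpressionRecord",
    "compute_fpkm",
    "associate_nearest_gene",
    "spearman_correlation",
    "NoAssociationError",
    "ConstantInputError",
]


@dataclass
class ExpressionRecord:
    feature_id: str
    length_bp: int
    count: float
    fpkm: float


def compute_fpkm(count: float, length_bp: int, total_fragments: float) -> float:
    """Fragments per kilobase of model per million mapped fragments."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    return count / ((length_bp / 1_000.0) * (total_fragments / 1e6))


class NoAssociationError(ValueError):
    """No gene available on the region's chromosome."""


def associate_nearest_gene(region: GenomicInterval, ann: Annotation) -> str:
    """Gene whose TSS is nearest to the region midpoint (ties: leftmost TSS)."""
    mid = region.midpoint
    candidates = [(abs(t.pos - mid), t.pos, t.gene_id)
                  for t in ann.tss_list if t.chrom == region.chrom]
    if not candidates:
        raise NoAssociationError(f"no gene on {region.chrom}")
    candidates.sort(key=lambda c: (c[0], c[1]))
    return candidates[0][2]


class ConstantInputError(ValueError):
    """Spearman correlation undefined for a constant vector."""


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("constant vector has no rank ordering")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def correlated_expression_pairs(n_pairs: int, n_cells: int, target_rho: float,
                                rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic eRNA/gene FPKM profile pairs with a target Spearman rho.

    Uses a Gaussian copula: the Pearson correlation of the latent
    normals is set to 2·sin(pi·rho_s/6) so the population Spearman
    correlation equals ``target_rho``; profiles are mapped through
    exp() to positive, FPKM-like values (a monotone transform, which
    leaves Spearman correlation unchanged).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    r = 2.0 * np.sin(np.pi * target_rho / 6.0)
    cov = np.array([[1.0, r], [1.0 * r, 1.0]])
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_pairs, n_cells, 2)) @ L.T
    e = np.exp(z)
    return e[:, :, 0], e[:, :, 1]
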