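"""Motif-enrichment statistics, LD expansion and permutation enrichment.

Motif enrichment is scored two ways, as in the discovery workflow: an
upper-tail binomial test of motif occurrences in transcribed-enhancer
regions against the genome-background rate, and Fisher's exact test of
transcribed versus weakly-transcribed regions; p-values are mapped to
z-scores through the standard normal quantile (capped at ±8).

SNP-set enrichment in genomic loci uses a permutation null: the loci
are relocated uniformly at random (length-matched, non-overlapping)
within the domain and the in-locus SNP count is re-tallied, giving the
add-one empirical p-value (1 + #{null >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import GenomicInterval

__all__ = [
    "LDPair",
    "EnrichmentResult",
    "MotifEnrichment",
    "motif_enrichment_stats",
    "ld_expand",
    "permutation_enrichment",
    "PlacementError",
]

_Z_CAP = 8.0


@dataclass(frozen=True)
class LDPair:
    """An unordered SNP pair with its squared allelic correlation."""

    snp_a: str
    snp_b: str
    r2: float

    def __post_init__(self):
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 must lie in [0, 1]")


@dataclass
class MotifEnrichment:
    binomial_p: float   # upper tail vs genome background
    fisher_p: float     # two-sided, transcribed vs weak
    z_binomial: float
    z_fisher: float


def _p_to_z(p: float) -> float:
    z = stats.norm.ppf(1.0 - p)
    return float(np.clip(z, -_Z_CAP, _Z_CAP))


def motif_enrichment_stats(k_erna: int, n_erna: int, k_weak: int, n_weak: int,
                           p_background: float) -> MotifEnrichment:
    """Binomial and Fisher enrichment of a motif with z-transforms.

    ``k_erna``/``n_erna`` are motif-bearing and total transcribed
    regions; ``k_weak``/``n_weak`` the same for weakly-transcribed
    regions; ``p_background`` the genome-wide motif rate.
    """
    if not (0 <= k_erna <= n_erna and 0 <= k_weak <= n_weak):
        raise ValueError("need 0 <= k <= n for both groups")
    if not (0.0 < p_background < 1.0):
        raise ValueError("p_background must lie in (0, 1)")
    binom_p = float(stats.binom.sf(k_erna - 1, n_erna, p_background))
    table = [[k_erna, n_erna - k_erna], [k_weak, n_weak - k_weak]]
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return MotifEnrichment(
        binomial_p=binom_p,
        fisher_p=fisher_p,
        z_binomial=_p_to_z(binom_p),
        z_fisher=_p_to_z(fisher_p),
    )


def ld_expand(seed_snps, ld_pairs, r2_threshold: float = 0.8) -> set:
    """One-hop strong-LD expansion of a seed SNP set (strict r2 > threshold).

    Partners of partners are *not* pulled in (no transitive closure).
    """
    if not (0.0 <= r2_threshold <= 1.0):
        raise ValueError("r2_threshold must lie in [0, 1]")
    seeds = set(seed_snps)
    expanded = set(seeds)
    for pair in ld_pairs:
        a, b, r2 = pair.snp_a, pair.snp_b, pair.r2
        if r2 > r2_threshold:
            if a in seeds:
                expanded.add(b)
            if b in seeds:
                expanded.add(a)
    return expanded


@dataclass
class EnrichmentResult:
    observed: int
    null_draws: np.ndarray
    p_value: float
    fold: float


class PlacementError(RuntimeError):
    """Domain too small to place length-matched non-overlapping loci."""


def _count_in_loci(snp_by_chrom: dict, loci) -> int:
    total = 0
    for iv in loci:
        pos = snp_by_chrom.get(iv.chrom)
        if pos is None:
            continue
        lo, hi = np.searchsorted(pos, [iv.start, iv.end], side="left")
        total += int(hi - lo)
    return total


def permutation_enrichment(snps, loci, domain, n_perm: int = 10_000,
                           rng=None) -> EnrichmentResult:
    """Permutation test of SNP enrichment in loci versus relocated loci.

    ``snps`` are ``(id, chrom, pos)`` tuples (or ``(chrom, pos)``),
    ``loci`` the observed intervals and ``domain`` the region set within
    which random length-matched, non-overlapping loci are redrawn each
    permutation.  The null model relocates loci uniformly within the
    domain, preserving the length multiset exactly.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if rng is None:
        rng = np.random.default_rng(0)

    snp_by_chrom: dict[str, np.ndarray] = {}
    for s in snps:
        chrom, pos = (s[1], s[2]) if len(s) == 3 else (s[0], s[1])
        snp_by_chrom.setdefault(chrom, []).append(pos)
    snp_by_chrom = {c: np.sort(np.asarray(v)) for c, v in snp_by_chrom.items()}

    lengths = np.array([iv.length for iv in loci], dtype=np.int64)
    pieces = list(domain)
    piece_len = np.array([iv.length for iv in pieces], dtype=np.int64)
    if lengths.sum() > piece_len.sum():
        raise PlacementError("loci do not fit in the domain")
    # valid start slots per (locus, piece)
    slots = piece_len[None, :] - lengths[:, None] + 1  # may be <= 0
    slots = np.maximum(slots, 0)
    if np.any(slots.sum(axis=1) == 0):
        raise PlacementError("a locus is longer than every domain piece")
    slot_cum = np.cumsum(slots / slots.sum(axis=1, keepdims=True), axis=1)

    observed = _count_in_loci(snp_by_chrom, loci)
    k = len(lengths)
    # place longest loci first: they have the fewest eligible pieces
    length_order = np.argsort(-lengths)
    piece_starts = np.array([p.start for p in pieces], dtype=np.int64)
    null = np.empty(n_perm, dtype=np.int64)
    for t in range(n_perm):
        occupied: dict[int, list] = {}
        total = 0
        for li in length_order:
            L = int(lengths[li])
            for attempt in range(200):
                j = int((rng.random() > slot_cum[li]).sum())
                s0 = int(piece_starts[j] + rng.integers(0, slots[li, j]))
                e0 = s0 + L
                if all(e0 <= a or s0 >= b for a, b in occupied.get(j, ())):
                    break
            else:
                raise PlacementError(
                    "could not place non-overlapping loci after 200 tries")
            occupied.setdefault(j, []).append((s0, e0))
            pos = snp_by_chrom.get(pieces[j].chrom)
            if pos is not None:
                lo, hi = np.searchsorted(pos, [s0, e0], side="left")
                total += int(hi - lo)
        null[t] = total

    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    mean_null = float(null.mean())
    fold = observed / mean_null if mean_null > 0 else float("inf")
    return EnrichmentResult(observed=observed, null_draws=null, p_value=p, fold=fold)
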