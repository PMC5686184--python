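"""Replicate-consensus peak merging and the candidate-enhancer filter cascade.

A candidate enhancer is an H3K27ac consensus peak that survives seven
conjunctive criteria (evaluated in order; the trace records every
verdict plus the first failure):

1. at least 1 kb away from every annotated TSS;
2. no spliced EST whose 5' end lies within 2 kb of the peak and which
   spans an annotated TSS;
3. not abnormally high in *both* H3K4me1 and H3K4me3 in the 2-kb window
   centred on the peak (z > 5 for both, the five-sigma rule);
4. H3K4me3 z-score below 3 in the same window;
5. an H3K4me1 consensus peak within 2 kb (edge-to-edge);
6. intergenic (no gene-body overlap);
7. not overlapping an rRNA gene.

Z-scores are standardised over the population of H3K27ac peaks that
survive criteria 1-2 (the population choice is a package decision).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    Annotation,
    GenomicInterval,
    TagSet,
    distance_to_nearest_tss,
    distance_to_point,
    edge_distance,
    merge_intervals,
)

__all__ = [
    "Peak",
    "CandidateEnhancer",
    "consensus_peaks",
    "zscore_standardize",
    "filter_candidates",
    "DegeneratePopulationError",
]

CRITERIA = (1, 2, 3, 4, 5, 6, 7)


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    replicate_support: float = 1.0
    summit: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.replicate_support <= 1.0):
            raise ValueError("replicate_support must lie in [0, 1]")


@dataclass
class CandidateEnhancer:
    """A surviving H3K27ac peak with its per-criterion filter trace."""

    interval: GenomicInterval
    filter_trace: dict = field(default_factory=dict)  # criterion -> bool (pass)
    first_fail: int | None = None
    n_i: int | None = None


class DegeneratePopulationError(ValueError):
    """Z-standardisation over fewer than 2 values or zero variance."""


def consensus_peaks(replicate_sets: list[list[GenomicInterval]],
                    min_fraction: float = 0.7) -> list[Peak]:
    """Cross-replicate consensus: keep clusters seen in > min_fraction of replicates.

    Overlapping peaks are clustered by single-linkage (>= 1 bp overlap);
    a cluster's support is the fraction of replicates contributing at
    least one peak, compared *strictly* against ``min_fraction``.  The
    output span is the union of the cluster's peaks.  An empty replicate
    set counts as a replicate with zero peaks.
    """
    if len(replicate_sets) == 0:
        raise ValueError("need at least one replicate set")
    n_rep = len(replicate_sets)
    pooled = [iv for reps in replicate_sets for iv in reps]
    clusters = merge_intervals(pooled)
    out = []
    for span in clusters:
        support = sum(
            1 for reps in replicate_sets if any(iv.overlaps(span) for iv in reps)
        ) / n_rep
        if support > min_fraction:
            out.append(Peak(interval=span, replicate_support=support))
    return out


def zscore_standardize(values) -> np.ndarray:
    """Population z-scores (x - mean) / sd with sd over the full population."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegeneratePopulationError("need at least 2 values")
    sd = x.std()  # population sd (ddof=0)
    if sd == 0.0:
        raise DegeneratePopulationError("zero variance population")
    return (x - x.mean()) / sd


def filter_candidates(
    h3k27ac: list[Peak],
    h3k4me1: list[Peak],
    me1_signal: TagSet,
    me3_signal: TagSet,
    ann: Annotation,
    tss_distance: int = 1_000,
    window_half: int = 1_000,
    z_high: float = 5.0,
    z_max: float = 3.0,
    proximity: int = 2_000,
):
    """Apply the seven-criterion cascade to H3K27ac consensus peaks.

    Returns ``(candidates, trace)``: the surviving
    :class:`CandidateEnhancer` list and a DataFrame with one row per
    input peak (columns ``c1..c7``, ``first_fail``).
    """
    peaks = list(h3k27ac)
    n = len(peaks)
    me1_ivs = [p.interval for p in h3k4me1]

    c1 = np.zeros(n, dtype=bool)
    c2 = np.zeros(n, dtype=bool)
    for i, p in enumerate(peaks):
        iv = p.interval
        c1[i] = distance_to_nearest_tss(iv, ann) >= tss_distance
        bad_est = any(
            distance_to_point(iv, est.five_prime) <= proximity
            and any(est.spans_point(t.pos) for t in ann.tss_list
                    if t.chrom == est.interval.chrom)
            for est in ann.est_records
            if est.interval.chrom == iv.chrom
        )
        c2[i] = not bad_est

    # window enrichment; z population = survivors of criteria 1-2
    raw1 = np.array([
        me1_signal.count_in(p.interval.chrom, p.interval.midpoint - window_half,
                            p.interval.midpoint + window_half) for p in peaks
    ], dtype=float)
    raw3 = np.array([
        me3_signal.count_in(p.interval.chrom, p.interval.midpoint - window_half,
                            p.interval.midpoint + window_half) for p in peaks
    ], dtype=float)
    pop = c1 & c2
    if pop.sum() < 2:
        raise DegeneratePopulationError("fewer than 2 peaks survive criteria 1-2")

    def z_against(raw):
        m, s = raw[pop].mean(), raw[pop].std()
        if s == 0.0:
            raise DegeneratePopulationError("zero-variance enrichment population")
        return (raw - m) / s

    z1 = z_against(raw1)
    z3 = z_against(raw3)
    c3 = ~((z1 > z_high) & (z3 > z_high))
    c4 = z3 < z_max

    c5 = np.zeros(n, dtype=bool)
    c6 = np.zeros(n, dtype=bool)
    c7 = np.zeros(n, dtype=bool)
    for i, p in enumerate(peaks):
        iv = p.interval
        c5[i] = any(
            m.chrom == iv.chrom and edge_distance(iv, m) <= proximity for m in me1_ivs
        )
        c6[i] = not any(iv.overlaps(g) for g in ann.gene_bodies)
        c7[i] = not any(iv.overlaps(r) for r in ann.rrna_genes)

    verdicts = np.vstack([c1, c2, c3, c4, c5, c6, c7]).T
    candidates, rows = [], []
    for i, p in enumerate(peaks):
        fails = [c for c, ok in zip(CRITERIA, verdicts[i]) if not ok]
        first_fail = fails[0] if fails else None
        trace = {c: bool(v) for c, v in zip(CRITERIA, verdicts[i])}
        rows.append(
            {"chrom": p.interval.chrom, "start": p.interval.start,
             "end": p.interval.end,
             **{f"c{c}": bool(v) for c, v in zip(CRITERIA, verdicts[i])},
             "first_fail": first_fail}
        )
        if first_fail is None:
            candidates.append(CandidateEnhancer(interval=p.interval,
                                                filter_trace=trace))
    trace_df = pd.DataFrame(rows)
    return candidates, trace_df
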