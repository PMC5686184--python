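"""Cross-cell-type master lists, saturation curves and Weibull extrapolation.

The master list is the union-merge of all per-cell-type catalogues, with
merged spans longer than 5,000 bp split into equal-length chunks, so
elements are disjoint and capped at 5,000 bp.  Saturation curves average
the number of elements (and their bp coverage) discovered by random
x-subsets of cell types, and the curve is extrapolated to its asymptote
by least-squares fitting of the Weibull form A·(1 − exp(−(x/b)^c)).

Subset counting operates on the master-element decomposition: an
element counts (with its full length) once any catalogue in the subset
overlaps it.  This is exact when catalogues are unions of a shared
disjoint element pool (as the synthetic series is) and an upper-bound
approximation for catalogues that only partially cover elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .intervals import GenomicInterval, merge_intervals

__all__ = [
    "MasterList",
    "WeibullFit",
    "build_master_list",
    "cell_specificity",
    "saturation_curve",
    "fit_weibull",
    "weibull_curve",
    "consensus_calls",
    "dedup_hits",
    "WeibullFitError",
]

MAX_ELEMENT_LEN = 5_000


@dataclass
class MasterList:
    elements: list            # disjoint GenomicIntervals, each <= 5,000 bp
    membership: list          # per-element set of cell-type keys

    def element_count(self) -> int:
        return len(self.elements)

    def coverage_bp(self) -> int:
        return sum(iv.length for iv in self.elements)


def _split_span(iv: GenomicInterval, max_len: int) -> list[GenomicInterval]:
    k = math.ceil(iv.length / max_len)
    if k <= 1:
        return [iv]
    bounds = [iv.start + round(i * iv.length / k) for i in range(k + 1)]
    return [GenomicInterval(iv.chrom, a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def build_master_list(catalogs: dict, max_len: int = MAX_ELEMENT_LEN) -> MasterList:
    """Union-merge all catalogues into disjoint elements <= ``max_len`` bp.

    ``catalogs`` maps cell-type key to an interval list.  Merged spans
    longer than ``max_len`` are split into ceil(L / max_len)
    equal-length chunks.  Membership is the set of cell types whose
    regions overlap each element.
    """
    if len(catalogs) == 0:
        raise ValueError("need at least one catalogue")
    merged = merge_intervals(iv for ivs in catalogs.values() for iv in ivs)
    elements = [piece for span in merged for piece in _split_span(span, max_len)]
    membership = []
    # sort each catalogue once for binary-search overlap
    by_cell = {
        cell: sorted(ivs, key=lambda v: (v.chrom, v.start))
        for cell, ivs in catalogs.items()
    }
    for el in elements:
        members = {
            cell for cell, ivs in by_cell.items()
            if any(iv.overlaps(el) for iv in ivs)
        }
        membership.append(members)
    return MasterList(elements=elements, membership=membership)


def cell_specificity(ml: MasterList) -> pd.DataFrame:
    """Per-element number of cell types the element was detected in."""
    counts = [len(m) for m in ml.membership]
    return pd.DataFrame(
        {
            "chrom": [e.chrom for e in ml.elements],
            "start": [e.start for e in ml.elements],
            "end": [e.end for e in ml.elements],
            "n_cell_types": counts,
        }
    )


def saturation_curve(catalogs: dict, n_samples: int = 20_000,
                     rng=None, max_len: int = MAX_ELEMENT_LEN) -> pd.DataFrame:
    """Mean discovered element count and coverage versus number of cell types.

    For each x in 1..n_cells, averages over ``n_samples`` random
    x-subsets of cell types (without replacement) the number of master
    elements discovered and their total bp.  Subsets are drawn as
    prefixes of random cell-type permutations, which makes every
    per-x marginal a uniform x-subset while sharing draws across x.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if len(catalogs) < 2:
        raise ValueError("need at least two catalogues")
    if rng is None:
        rng = np.random.default_rng(0)
    ml = build_master_list(catalogs, max_len=max_len)
    cells = list(catalogs.keys())
    n_cells, n_el = len(cells), len(ml.elements)
    M = np.zeros((n_cells, n_el), dtype=bool)
    cell_index = {c: i for i, c in enumerate(cells)}
    for e, members in enumerate(ml.membership):
        for c in members:
            M[cell_index[c], e] = True
    lengths = np.array([e.length for e in ml.elements], dtype=float)

    count_sum = np.zeros(n_cells)
    cover_sum = np.zeros(n_cells)
    batch = max(1, int(5e6 // max(1, n_cells * n_el)))
    done = 0
    while done < n_samples:
        b = min(batch, n_samples - done)
        perms = np.array([rng.permutation(n_cells) for _ in range(b)])
        # cumulative union of catalogues along each permutation
        pres = M[perms]                      # (b, n_cells, n_el)
        cum = np.maximum.accumulate(pres, axis=1)
        count_sum += cum.sum(axis=2).sum(axis=0)
        cover_sum += (cum * lengths[None, None, :]).sum(axis=2).sum(axis=0)
        done += b
    return pd.DataFrame(
        {
            "x": np.arange(1, n_cells + 1),
            "mean_count": count_sum / n_samples,
            "mean_coverage_bp": cover_sum / n_samples,
        }
    )


@dataclass
class WeibullFit:
    A: float       # asymptote
    b: float       # scale (cell types)
    c: float       # shape
    r2: float
    A_sd: float
    degenerate: bool = False

    def predict(self, x):
        return weibull_curve(np.asarray(x, dtype=float), self.A, self.b, self.c)


class WeibullFitError(RuntimeError):
    """Weibull saturation fit failed to converge."""


def weibull_curve(x, A, b, c):
    return A * (1.0 - np.exp(-((x / b) ** c)))


def fit_weibull(x, y) -> WeibullFit:
    """Least-squares Weibull saturation fit with asymptote uncertainty.

    ``A_sd`` is the linearised standard deviation from the parameter
    covariance of the fit.  A constant input produces a flagged
    degenerate fit (A ~ y, undefined covariance) rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    if np.allclose(y, y[0]):
        return WeibullFit(A=float(y[0]), b=float(x[0]), c=1.0, r2=0.0,
                          A_sd=float("nan"), degenerate=True)
    ymax = y.max()
    p0 = (ymax * 1.2, float(np.median(x)), 1.0)
    try:
        popt, pcov = curve_fit(
            weibull_curve, x, y, p0=p0,
            bounds=([1e-9, 1e-9, 1e-3], [np.inf, np.inf, 20.0]),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        resid = y - weibull_curve(x, *p0)
        raise WeibullFitError(
            f"no convergence (initial residual rms {np.sqrt(np.mean(resid ** 2)):.3g})"
        ) from exc
    yhat = weibull_curve(x, *popt)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    a_sd = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else float("nan")
    return WeibullFit(A=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
                      r2=r2, A_sd=a_sd, degenerate=not np.isfinite(a_sd))


def consensus_calls(call_sets: list[list[GenomicInterval]],
                    min_sets: int = 2) -> list[GenomicInterval]:
    """Regions supported by at least ``min_sets`` of the call sets.

    Support is counted per base over distinct sets (multiple calls from
    one set count once); maximal runs of bases with sufficient support
    are returned.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least two call sets")
    events: dict[str, list] = {}
    for cs in call_sets:
        for iv in merge_intervals(cs):  # de-duplicate within a set
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    out = []
    for chrom, evs in sorted(events.items()):
        evs.sort()
        depth, run_start = 0, None
        for pos, delta in evs:
            prev = depth
            depth += delta
            if prev < min_sets <= depth:
                run_start = pos
            elif prev >= min_sets > depth and run_start is not None:
                if pos > run_start:
                    out.append(GenomicInterval(chrom, run_start, pos))
                run_start = None
    return out


def dedup_hits(hits: list, shift_tol: int = 10) -> list:
    """Collapse same-model hits whose ends differ by <= ``shift_tol`` bp.

    ``hits`` are ``(model_label, GenomicInterval)`` pairs; hits across
    cells for the same model at the same region — or shifted by a few
    bases — are the same underlying hit.  Within each model label, hits
    are clustered greedily against the leftmost representative.
    Returns unique ``(model_label, interval, n_merged)`` tuples.
    """
    by_model: dict[str, list] = {}
    for label, iv in hits:
        by_model.setdefault(label, []).append(iv)
    out = []
    for label in sorted(by_model):
        ivs = sorted(by_model[label], key=lambda v: (v.chrom, v.start, v.end))
        reps: list[list] = []  # [representative, count]
        for iv in ivs:
            placed = False
            for rep in reps:
                r = rep[0]
                if (r.chrom == iv.chrom
                        and abs(iv.start - r.start) <= shift_tol
                        and abs(iv.end - r.end) <= shift_tol):
                    rep[1] += 1
                    placed = True
                    break
            if not placed:
                reps.append([iv, 1])
        out.extend((label, rep[0], rep[1]) for rep in reps)
    return out
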