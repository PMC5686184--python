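"""riboSNitch scoring: structural impact of single-nucleotide variants.

For each SNV a ±200-nt window around the variant is extracted (clipped
at sequence ends, never discarded), the wild-type and mutant base-pair
probability matrices are computed, and the structural difference is the
Euclidean distance over all probability entries within a sequence
interval, maximised over intervals that contain the variant and meet a
minimum length.  Because the squared terms are non-negative the
distance is monotone under interval inclusion; the literal
(un-normalised) distance is the default, with a per-entry normalised
variant behind a flag.  Significance is an empirical tail probability
against random same-window SNVs, and riboSNitches are calls with
p < 0.2 (strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import EnergyModel, base_pair_probabilities

__all__ = [
    "SNVRecord",
    "StructuralDistance",
    "snv_structural_distance",
    "empirical_structure_pvalue",
    "call_ribosnitches",
    "score_snvs",
    "WindowTooShortError",
    "DEFAULT_WINDOW",
    "DEFAULT_MIN_INTERVAL",
    "P_RIBOSNITCH",
]

DEFAULT_WINDOW = 200       # nt each side of the variant
DEFAULT_MIN_INTERVAL = 50  # nt, minimum interval length for the distance scan
P_RIBOSNITCH = 0.2


@dataclass(frozen=True)
class SNVRecord:
    seq_id: str
    pos: int      # 0-based position in the sequence
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("alt must differ from ref")

    def validate(self, seq: str) -> None:
        s = seq.upper().replace("T", "U")
        if not (0 <= self.pos < len(s)):
            raise ValueError(f"pos {self.pos} outside sequence of length {len(s)}")
        if s[self.pos] != self.ref.upper().replace("T", "U"):
            raise ValueError(
                f"ref mismatch at {self.pos}: sequence has {s[self.pos]}, record {self.ref}"
            )


@dataclass
class StructuralDistance:
    seq_id: str
    pos: int
    ref: str
    alt: str
    d_max: float
    best_interval: tuple      # (i, j) inclusive, full-sequence coordinates
    p_value: float | None = None
    is_ribosnitch: bool | None = None


class WindowTooShortError(ValueError):
    pass


def _fold_cached(seq: str, em: EnergyModel, cache: dict | None):
    if cache is None:
        return base_pair_probabilities(seq, em).p
    if seq not in cache:
        cache[seq] = base_pair_probabilities(seq, em).p
    return cache[seq]


def _window(seq: str, pos: int, window: int) -> tuple[str, int, int]:
    lo = max(0, pos - window)
    hi = min(len(seq), pos + window + 1)
    return seq[lo:hi], lo, pos - lo


def snv_structural_distance(seq: str, snv: SNVRecord,
                            window: int = DEFAULT_WINDOW,
                            min_interval: int = DEFAULT_MIN_INTERVAL,
                            em: EnergyModel | None = None,
                            normalized: bool = False,
                            _cache: dict | None = None):
    """Maximum-interval Euclidean distance between WT and MT ensembles.

    Returns ``(d_max, (i, j))`` with the interval in full-sequence
    inclusive coordinates containing the variant position.  With
    ``normalized=True`` the squared-difference sum in each interval is
    divided by its number of (k, l) entries before the square root.
    """
    seq = seq.upper().replace("T", "U")
    snv.validate(seq)
    if em is None:
        em = EnergyModel()
    sub, lo, p = _window(seq, snv.pos, window)
    m = len(sub)
    if m < min_interval:
        raise WindowTooShortError(
            f"window of {m} nt is shorter than the minimum interval {min_interval}"
        )
    mut = sub[:p] + snv.alt.upper().replace("T", "U") + sub[p + 1:]
    Pwt = _fold_cached(sub, em, _cache)
    Pmt = _fold_cached(mut, em, _cache)
    D2 = (Pwt - Pmt) ** 2
    # 2-D prefix sums of the (upper-triangular) squared-difference matrix:
    # the interval sum S(i, j) is the D2 mass in the [i..j] x [i..j] box.
    C = np.zeros((m + 1, m + 1))
    C[1:, 1:] = np.cumsum(np.cumsum(D2, axis=0), axis=1)
    best_d2, best_ij = -1.0, None
    for i in range(0, p + 1):
        j_lo = max(p, i + min_interval - 1)
        if j_lo >= m:
            continue
        js = np.arange(j_lo, m)
        s = C[js + 1, js + 1] - C[i, js + 1] - C[js + 1, i] + C[i, i]
        if normalized:
            L = js - i + 1
            s = s / (L * (L - 1) / 2.0)
        jbest = int(np.argmax(s))
        if s[jbest] > best_d2 + 1e-15:
            best_d2 = float(s[jbest])
            best_ij = (i, int(js[jbest]))
    d = float(np.sqrt(max(best_d2, 0.0)))
    return d, (best_ij[0] + lo, best_ij[1] + lo)


def empirical_structure_pvalue(seq: str, snv: SNVRecord, n_null: int = 100,
                               window: int = DEFAULT_WINDOW,
                               min_interval: int = DEFAULT_MIN_INTERVAL,
                               em: EnergyModel | None = None,
                               rng=None, _cache: dict | None = None) -> float:
    """Empirical tail probability of the SNV's structural distance.

    The null is the distance of random SNVs on the same sequence
    (uniform position, uniform non-reference base, window re-centred);
    p = (1 + #{null >= observed}) / (n_null + 1), so p is never 0.
    Distances are memoised per (position, alt), which makes large
    ``n_null`` cheap on short sequences.
    """
    if n_null < 50:
        raise ValueError("n_null must be at least 50")
    if rng is None:
        rng = np.random.default_rng(0)
    if _cache is None:
        _cache = {}
    seq = seq.upper().replace("T", "U")
    obs, _ = snv_structural_distance(seq, snv, window, min_interval, em, _cache=_cache)
    memo: dict[tuple, float] = {}
    n_ge = 0
    bases = "ACGU"
    for _ in range(n_null):
        pos = int(rng.integers(0, len(seq)))
        ref = seq[pos]
        alts = [b for b in bases if b != ref]
        alt = alts[int(rng.integers(0, 3))]
        key = (pos, alt)
        if key not in memo:
            d, _ = snv_structural_distance(
                seq, SNVRecord(snv.seq_id, pos, ref, alt),
                window, min_interval, em, _cache=_cache,
            )
            memo[key] = d
        if memo[key] >= obs:
            n_ge += 1
    return (1.0 + n_ge) / (n_null + 1.0)


def call_ribosnitches(results: list[StructuralDistance],
                      p_threshold: float = P_RIBOSNITCH) -> list[StructuralDistance]:
    """Flag riboSNitches: p-value strictly below the threshold."""
    if not results:
        raise ValueError("results must be non-empty")
    for r in results:
        if r.p_value is None:
            raise ValueError(f"missing p-value for {r.seq_id}:{r.pos}")
        r.is_ribosnitch = r.p_value < p_threshold
    return results


def score_snvs(seqs: dict, snvs, n_null: int = 100,
               window: int = DEFAULT_WINDOW,
               min_interval: int | None = None,
               em: EnergyModel | None = None, rng=None):
    """Score a batch of SNVs: distance, empirical p and riboSNitch call.

    ``snvs`` is an iterable of ``(seq_id, pos, ref, alt)`` or
    :class:`SNVRecord`.  With ``min_interval=None`` the minimum interval
    is the window length clipped to each sequence (useful for hairpin
    constructs shorter than the 50-nt default).  Returns a list of
    :class:`StructuralDistance`.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out = []
    cache: dict = {}
    for rec in snvs:
        snv = rec if isinstance(rec, SNVRecord) else SNVRecord(*rec)
        seq = seqs[snv.seq_id]
        mi = min_interval if min_interval is not None else min(
            DEFAULT_MIN_INTERVAL, len(seq))
        d, ij = snv_structural_distance(seq, snv, window, mi, em, _cache=cache)
        p = empirical_structure_pvalue(seq, snv, n_null, window, mi, em,
                                       rng=rng, _cache=cache)
        out.append(StructuralDistance(snv.seq_id, snv.pos, snv.ref, snv.alt,
                                      d_max=d, best_interval=ij, p_value=p))
    return call_ribosnitches(out)
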