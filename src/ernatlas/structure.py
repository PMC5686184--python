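"""Equilibrium base-pair probabilities for nested RNA secondary structure.

The engine computes exact pairing probabilities over the Boltzmann
ensemble of all pseudoknot-free structures under a deliberately simple
energy model: one energy per pair type (GC/CG, AU/UA, GU/UG) plus a
bonus for each stacked pair of adjacent helices, at fixed RT.  The
riboSNitch statistic downstream needs a *consistent* thermodynamic
ensemble to compare wild-type and mutant sequences — not per-motif
thermodynamic accuracy — so the full nearest-neighbour parameter set is
intentionally not reproduced; the model is pluggable.

Two independent routes are provided:

* :func:`base_pair_probabilities` — inside–outside dynamic programming,
  O(n³) time, usable up to a couple of thousand nucleotides;
* :func:`enumerate_structures_oracle` — explicit enumeration of every
  structure (guarded to short sequences), the ground truth the DP is
  validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnergyModel",
    "BasePairProbMatrix",
    "base_pair_probabilities",
    "enumerate_structures_oracle",
]

_DEFAULT_PAIRS = {
    "GC": -3.0, "CG": -3.0,
    "AU": -2.0, "UA": -2.0,
    "GU": -1.0, "UG": -1.0,
}


@dataclass(frozen=True)
class EnergyModel:
    """Pair + stacking energy model (kcal/mol) with Boltzmann factor RT.

    ``min_loop`` is the minimum number of unpaired bases a hairpin loop
    must enclose (canonical steric constraint, 3 nt).
    """

    pair_energies: dict = field(default_factory=lambda: dict(_DEFAULT_PAIRS))
    stack_bonus: float = -1.0
    temperature_RT: float = 0.616
    min_loop: int = 3

    def __post_init__(self):
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")
        if set(self.pair_energies) - set(_DEFAULT_PAIRS):
            raise ValueError("only the six canonical pair types are allowed")

    def pair_energy(self, a: str, b: str) -> float | None:
        return self.pair_energies.get(a + b)


@dataclass
class BasePairProbMatrix:
    """Upper-triangular matrix of equilibrium pairing probabilities."""

    n: int
    p: np.ndarray  # shape (n, n); p[k, l] for k < l, zero elsewhere

    def prob(self, k: int, l: int) -> float:
        if k > l:
            k, l = l, k
        return float(self.p[k, l])

    def unpaired_prob(self) -> np.ndarray:
        """Per-base probability of being unpaired."""
        return 1.0 - self.p.sum(axis=0) - self.p.sum(axis=1)


def _validate_seq(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    for i, c in enumerate(seq):
        if c not in "ACGU":
            raise ValueError(f"invalid character {c!r} at position {i}")
    return seq


def _pair_weights(seq: str, em: EnergyModel) -> np.ndarray:
    """q[k, l] = exp(-E_pair/RT) for allowed pairs respecting min_loop."""
    n = len(seq)
    q = np.zeros((n, n))
    for k in range(n):
        for l in range(k + em.min_loop + 1, n):
            e = em.pair_energy(seq[k], seq[l])
            if e is not None:
                q[k, l] = math.exp(-e / em.temperature_RT)
    return q


def _inside_outside(seq: str, em: EnergyModel, sigma: float) -> np.ndarray | None:
    """One scaled inside–outside pass; returns P or None on over/underflow.

    ``sigma`` is a per-base rescaling factor: every unpaired extension is
    divided by sigma and every pair weight by sigma²; the factors cancel
    exactly in the probability ratio, so sigma only controls dynamic range.
    """
    n = len(seq)
    ml = em.min_loop
    s = math.exp(-em.stack_bonus / em.temperature_RT)
    q = _pair_weights(seq, em) / (sigma * sigma)
    inv = 1.0 / sigma

    # Half-open span indexing: Z[i, j] covers bases i..j-1; Z[i, i] = 1.
    Z = np.zeros((n + 1, n + 1))
    Zb = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        for j in range(i, min(i + ml + 1, n) + 1):
            Z[i, j] = inv ** (j - i)

    for d in range(ml + 2, n + 1):  # span length
        for i in range(0, n - d + 1):
            j = i + d
            if q[i, j - 1] > 0.0:
                Zb[i, j] = q[i, j - 1] * (Z[i + 1, j - 1] + (s - 1.0) * Zb[i + 1, j - 1])
            acc = Z[i, j - 1] * inv
            khi = j - 1 - ml  # pairs (k, j-1) need (j-1)-k-1 >= ml
            if khi > i:
                acc += float(np.dot(Z[i, i:khi], Zb[i:khi, j]))
            Z[i, j] = acc

    Ztot = Z[0, n]
    if not np.isfinite(Ztot) or Ztot <= 0.0 or not np.all(np.isfinite(Zb)):
        return None

    OZ = np.zeros((n + 1, n + 1))
    OB = np.zeros((n + 1, n + 1))
    OZ[0, n] = 1.0
    for d in range(n, 0, -1):
        # distribute Z-spans of this length first: they feed OB at equal length
        for i in range(0, n - d + 1):
            j = i + d
            w = OZ[i, j]
            if w == 0.0:
                continue
            OZ[i, j - 1] += w * inv
            khi = j - 1 - ml
            if khi > i:
                ks = np.arange(i, khi)
                OZ[i, ks] += w * Zb[ks, j]
                OB[ks, j] += w * Z[i, ks]
        for i in range(0, n - d + 1):
            j = i + d
            w = OB[i, j]
            if w == 0.0 or q[i, j - 1] == 0.0:
                continue
            OZ[i + 1, j - 1] += w * q[i, j - 1]
            OB[i + 1, j - 1] += w * q[i, j - 1] * (s - 1.0)

    P = np.zeros((n, n))
    for i in range(n):
        for l in range(i + ml + 1, n):
            if q[i, l] > 0.0:
                P[i, l] = Zb[i, l + 1] * OB[i, l + 1] / Ztot
    if not np.all(np.isfinite(P)):
        return None
    return np.clip(P, 0.0, 1.0)


def base_pair_probabilities(seq: str, em: EnergyModel | None = None) -> BasePairProbMatrix:
    """Exact base-pair probability matrix by inside–outside DP.

    T is mapped to U on input.  Raises ``ValueError`` on characters
    outside {A, C, G, U, T} (naming the offending position).
    """
    if em is None:
        em = EnergyModel()
    seq = _validate_seq(seq)
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    # worst-case log weight per pair, used to pick the rescaling factor
    lmax = (max(-e for e in em.pair_energies.values()) - em.stack_bonus) / em.temperature_RT
    sigmas = [1.0]
    if n * lmax / 2.0 > 600.0:
        sigmas = [math.exp(lmax / 4.0), 1.0]
    for sigma in sigmas:
        P = _inside_outside(seq, em, sigma)
        if P is not None:
            return BasePairProbMatrix(n=n, p=P)
    raise OverflowError(f"partition function out of dynamic range for n={n}")


_ORACLE_MAX = 25


def enumerate_structures_oracle(seq: str, em: EnergyModel | None = None):
    """Enumerate every pseudoknot-free structure and the exact ensemble.

    Returns ``(structures, bppm)`` where ``structures`` is a list of
    ``(pairs, energy)`` tuples (pairs as frozensets of (k, l)) and
    ``bppm`` the exact probability matrix obtained by direct Boltzmann
    summation.  Guarded to sequences of length <= 25.
    """
    if em is None:
        em = EnergyModel()
    seq = _validate_seq(seq)
    n = len(seq)
    if n > _ORACLE_MAX:
        raise ValueError(f"oracle limited to length <= {_ORACLE_MAX}, got {n}")
    ml = em.min_loop

    def enum(i: int, j: int):  # structures on half-open [i, j)
        if j - i <= ml:
            return [()]
        out = list(enum(i, j - 1))  # base j-1 unpaired
        for k in range(i, j - 1 - ml):
            if em.pair_energy(seq[k], seq[j - 1]) is None:
                continue
            for left in enum(i, k):
                for inner in enum(k + 1, j - 1):
                    out.append(left + ((k, j - 1),) + inner)
        return out

    structures = []
    weights = []
    P = np.zeros((n, n))
    for pairs in enum(0, n):
        pairset = frozenset(pairs)
        e = sum(em.pair_energy(seq[k], seq[l]) for k, l in pairs)
        e += em.stack_bonus * sum(1 for k, l in pairs if (k + 1, l - 1) in pairset)
        w = math.exp(-e / em.temperature_RT)
        structures.append((pairset, e))
        weights.append(w)
        for k, l in pairs:
            P[k, l] += w
    Ztot = float(sum(weights))
    P /= Ztot
    return structures, BasePairProbMatrix(n=n, p=P)
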