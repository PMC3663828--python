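"""Equilibrium thermodynamics of the 1-D hard-rod nucleosome lattice.

The genome is modeled as a lattice of L bps on which rods of length ``a``
(the 147-bp nucleosome footprint) are placed without overlap.  A rod starting
at bp ``i`` carries Boltzmann weight ``w_i = exp(-(E_i - mu)/kBT)``.  Exact
start probabilities P_i and occupancies O_i follow from forward/backward
partition-function recursions; conversely, the energies are recovered exactly
from (P, O) by a Percus-type inversion:

    (E_i - mu)/kBT = log[(1 - O_i + P_i)/P_i]
                     + sum_{j=i}^{i+a-1} log[(1 - O_j)/(1 - O_j + P_j)]

The summation window j in [i, i+a-1] is the unique choice that makes the
inversion the exact inverse of the equilibrium recursion (verified against
exhaustive enumeration); P_j is taken as 0 beyond the last admissible start.
All energies are in kBT units (kBT = 1 internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from numba import njit

from .profiles import FilterMask, OccupancyPair, coverage_from_starts

__all__ = [
    "ThermoParams",
    "EnergyProfile",
    "equilibrium_predict",
    "invert_energy",
    "brute_force_equilibrium",
    "calibrate_mu",
]


@dataclass
class ThermoParams:
    """Chemical potential and rod length for the hard-rod lattice."""

    mu: float = 0.0
    footprint: int = 147
    kBT: float = 1.0

    def __post_init__(self) -> None:
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1")


@dataclass
class EnergyProfile:
    """Per-start-position nucleosome formation energies, in kBT units.

    Each chromosome vector has one entry per admissible start (length
    L - footprint + 1); ``defined`` flags positions where the energy is
    meaningful (False where inversion failed or a filter intervened).
    """

    E: Dict[str, np.ndarray]
    mu: float = 0.0
    footprint: int = 147
    defined: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, v in self.E.items():
            if chrom not in self.defined:
                self.defined[chrom] = np.isfinite(v)

    def chroms(self) -> List[str]:
        return list(self.E)

    def values_defined(self) -> np.ndarray:
        """All defined energies pooled across chromosomes."""
        return np.concatenate([self.E[c][self.defined[c]] for c in self.E])


@njit(cache=True)
def _logaddexp(a: float, b: float) -> float:
    if a == -np.inf:
        return b
    if b == -np.inf:
        return a
    if a < b:
        a, b = b, a
    return a + np.log1p(np.exp(b - a))


@njit(cache=True)
def _dp_start_probs(logw: np.ndarray, a: int) -> np.ndarray:
    """Exact hard-rod start probabilities by log-space forward/backward DP.

    logw has one entry per admissible start (n = L - a + 1).
    """
    n = logw.shape[0]
    L = n + a - 1
    # f[i+1] holds log F(i), the prefix partition function over bps [0, i].
    f = np.empty(L + 1)
    f[0] = 0.0
    for i in range(L):
        val = f[i]
        s = i - a + 1
        if s >= 0:
            val = _logaddexp(val, logw[s] + f[s])
        f[i + 1] = val
    # b[i] holds log B(i), the suffix partition function over bps [i, L-1].
    b = np.empty(L + a + 1)
    for i in range(L, L + a + 1):
        b[i] = 0.0
    for i in range(L - 1, -1, -1):
        val = b[i + 1]
        if i < n:
            val = _logaddexp(val, logw[i] + b[i + a])
        b[i] = val
    P = np.empty(n)
    logZ = f[L]
    for i in range(n):
        P[i] = np.exp(f[i] + logw[i] + b[i + a] - logZ)
    return P


def equilibrium_predict(E: EnergyProfile,
                        params: Optional[ThermoParams] = None) -> OccupancyPair:
    """Exact equilibrium start-probability and occupancy profiles.

    Undefined or +inf energies are treated as forbidden starts (w = 0).
    Computation is in log space, so chromosomes of arbitrary length do not
    overflow the partition function.
    """
    if params is None:
        params = ThermoParams(mu=E.mu, footprint=E.footprint)
    a = params.footprint
    P, O = {}, {}
    for chrom, Ev in E.E.items():
        e = np.array(Ev, dtype=float)
        e[~E.defined[chrom]] = np.inf
        if np.isnan(e).any():
            raise ValueError("energy profile contains NaN at defined positions")
        logw = (params.mu - e) / params.kBT  # -inf where forbidden
        Pv = _dp_start_probs(logw, a)
        L = len(e) + a - 1
        P_full = np.zeros(L)
        P_full[: len(Pv)] = Pv
        P[chrom] = P_full
        O[chrom] = coverage_from_starts(P_full, a)
    return OccupancyPair(P, O, a)


def invert_energy(pair: OccupancyPair, params: ThermoParams,
                  mask: Optional[FilterMask] = None) -> EnergyProfile:
    """Recover per-start energies from matched (P, O) profiles.

    Positions where P_i <= 0, where any occupancy in the footprint window
    reaches 1, or whose footprint window touches a masked bp are flagged
    undefined rather than raising.
    """
    a = params.footprint
    E, defined = {}, {}
    for chrom in pair.P:
        P = np.asarray(pair.P[chrom], dtype=float)
        O = np.asarray(pair.O[chrom], dtype=float)
        L = len(P)
        n = L - a + 1
        if n < 1:
            E[chrom] = np.empty(0)
            defined[chrom] = np.empty(0, dtype=bool)
            continue
        vac = 1.0 - O            # vacancy probability at each bp
        vacp = vac + P
        ok_bp = (vac > 0) & (vacp > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(ok_bp, np.log(np.where(ok_bp, vac, 1.0))
                            - np.log(np.where(ok_bp, vacp, 1.0)), np.nan)
        csum = np.concatenate([[0.0], np.nancumsum(term)])
        bad = np.concatenate([[0], np.cumsum(~ok_bp)])
        window_sum = csum[a:] - csum[:-a]                # sum over j in [i, i+a-1]
        window_bad = (bad[a:] - bad[:-a]) > 0
        Pi = P[:n]
        good = (Pi > 0) & ~window_bad & (vacp[:n] > 0)
        if mask is not None and chrom in mask.data:
            mbad = np.concatenate([[0], np.cumsum(mask[chrom].astype(np.int64))])
            good &= (mbad[a:] - mbad[:-a]) == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            e = params.mu + params.kBT * (
                np.log(np.where(good, vacp[:n], 1.0))
                - np.log(np.where(good, Pi, 1.0)) + window_sum)
        e = np.where(good, e, np.nan)
        E[chrom] = e
        defined[chrom] = good & np.isfinite(e)
    return EnergyProfile(E, params.mu, a, defined)


def brute_force_equilibrium(E: np.ndarray, params: ThermoParams,
                            L: Optional[int] = None) -> OccupancyPair:
    """Exact (P, O) by exhaustive enumeration of rod configurations.

    Intended as an independent oracle for tiny systems; the lattice length
    defaults to len(E) + footprint - 1 and must not exceed 30 bp.
    """
    a = params.footprint
    E = np.asarray(E, dtype=float)
    n = len(E)
    if L is None:
        L = n + a - 1
    if L > 30:
        raise ValueError("brute force enumeration limited to L <= 30")
    if n != L - a + 1:
        raise ValueError("energy vector must cover starts 0..L-footprint")
    w = np.exp((params.mu - E) / params.kBT)
    Z = 0.0
    num = np.zeros(n)

    def rec(next_free: int, weight: float, placed: List[int]) -> None:
        nonlocal Z
        Z += weight
        for i in placed:
            num[i] += weight
        for i in range(next_free, n):
            if w[i] > 0:
                placed.append(i)
                rec(i + a, weight * w[i], placed)
                placed.pop()

    rec(0, 1.0, [])
    P = np.zeros(L)
    P[:n] = num / Z
    return OccupancyPair({"seq": P}, {"seq": coverage_from_starts(P, a)}, a)


def calibrate_mu(E: EnergyProfile, target_mean_occupancy: float,
                 params: Optional[ThermoParams] = None,
                 mask: Optional[FilterMask] = None,
                 tol: float = 1e-6, max_iter: int = 200) -> ThermoParams:
    """Find the chemical potential giving a target genome-mean occupancy.

    Mean occupancy over unmasked bps is monotone increasing in mu, so a
    bracketed bisection converges; the bracket is expanded geometrically
    until it straddles the target.
    """
    if not 0.0 < target_mean_occupancy < 1.0:
        raise ValueError("target mean occupancy must lie in (0, 1)")
    base = params if params is not None else ThermoParams(footprint=E.footprint)

    def mean_occ(mu: float) -> float:
        pair = equilibrium_predict(E, ThermoParams(mu, base.footprint, base.kBT))
        tot, cnt = 0.0, 0
        for chrom, O in pair.O.items():
            keep = ~mask[chrom] if mask is not None and chrom in mask.data \
                else np.ones(len(O), dtype=bool)
            tot += float(O[keep].sum())
            cnt += int(keep.sum())
        return tot / cnt

    med = float(np.median(E.values_defined()))
    lo, hi = med - 5.0, med + 5.0
    for _ in range(100):
        if mean_occ(lo) < target_mean_occupancy:
            break
        lo -= 10.0
    else:
        raise ValueError("target mean occupancy unreachable (lower bracket)")
    for _ in range(100):
        if mean_occ(hi) > target_mean_occupancy:
            break
        hi += 10.0
    else:
        raise ValueError("target mean occupancy unreachable (upper bracket)")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        occ = mean_occ(mid)
        if abs(occ - target_mean_occupancy) < tol:
            return ThermoParams(mid, base.footprint, base.kBT)
        if occ < target_mean_occupancy:
            lo = mid
        else:
            hi = mid
    return ThermoParams(0.5 * (lo + hi), base.footprint, base.kBT)
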