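"""Per-bp nucleosome start and coverage profiles from mapped reads.

A mapped read is interpreted as evidence for one nucleosome of a fixed
footprint (147 bp by default): a forward-strand read starts the nucleosome at
its first base, a reverse-strand read ends it at its last base.  The module
builds the resulting start-weight profile, applies the anomaly filters (read
gaps, high-coverage regions, restriction cut sites), smooths with Gaussians
of width matched to the MNase positional imprecision, and normalizes the
smoothed profiles into start-probability / occupancy pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from .genome import GenomeAssembly

__all__ = [
    "MappedRead",
    "ReadStartProfile",
    "FilterMask",
    "SmoothingParams",
    "OccupancyPair",
    "reads_to_start_profile",
    "paired_to_start_profile",
    "gap_filter",
    "high_coverage_filter",
    "cutsite_filter",
    "gaussian_smooth",
    "coverage_from_starts",
    "normalize_to_probability",
    "normalized_occupancy",
]

logger = logging.getLogger(__name__)

DEFAULT_FOOTPRINT = 147


@dataclass
class MappedRead:
    """A mapped sequence read (0-based half-open interval).

    ``weight`` is 1/M for reads mapping equally well to M locations.
    """

    chrom: str
    start: int
    end: int
    strand: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("read end must exceed start")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("read weight must lie in (0, 1]")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


ReadsLike = Union[pd.DataFrame, Iterable[MappedRead]]


def _reads_frame(reads: ReadsLike) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        return reads
    rows = [(r.chrom, r.start, r.end, r.strand, r.weight) for r in reads]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "weight"])


@dataclass
class ReadStartProfile:
    """Per-bp nucleosome start weights, one float vector per chromosome."""

    data: Dict[str, np.ndarray]
    footprint: int = DEFAULT_FOOTPRINT
    n_dropped: float = 0.0  # weight of contributions falling outside valid starts

    @property
    def total_weight(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def chroms(self) -> List[str]:
        return list(self.data)

    def map(self, fn) -> "ReadStartProfile":
        return ReadStartProfile({c: fn(v) for c, v in self.data.items()},
                                self.footprint, self.n_dropped)


@dataclass
class FilterMask:
    """Per-chromosome boolean exclusion mask (True = excluded bp)."""

    data: Dict[str, np.ndarray]

    def __or__(self, other: "FilterMask") -> "FilterMask":
        chroms = list(dict.fromkeys(list(self.data) + list(other.data)))
        out = {}
        for c in chroms:
            a = self.data.get(c)
            b = other.data.get(c)
            if a is None:
                out[c] = b.copy()
            elif b is None:
                out[c] = a.copy()
            else:
                out[c] = a | b
        return FilterMask(out)

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def n_masked(self) -> int:
        return int(sum(int(v.sum()) for v in self.data.values()))

    def to_intervals(self) -> List[Tuple[str, int, int]]:
        """Masked regions as (chrom, start, end) half-open intervals."""
        out = []
        for chrom, m in self.data.items():
            for s, e in _bool_runs(m):
                out.append((chrom, s, e))
        return out

    @classmethod
    def empty(cls, lengths: Dict[str, int]) -> "FilterMask":
        return cls({c: np.zeros(n, dtype=bool) for c, n in lengths.items()})

    @classmethod
    def from_intervals(cls, lengths: Dict[str, int],
                       intervals: Iterable[Tuple[str, int, int]]) -> "FilterMask":
        mask = cls.empty(lengths)
        for chrom, s, e in intervals:
            L = lengths[chrom]
            mask.data[chrom][max(0, s):min(L, e)] = True
        return mask


@dataclass
class SmoothingParams:
    """Gaussian smoothing width.

    sigma = 20 bp for position-independent modeling, 2 bp for spatially
    resolved modeling; the truncation radius bounds the kernel support and the
    kernel is renormalized to unit area, so read mass is conserved exactly.
    """

    sigma: float
    truncation_radius: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.truncation_radius is None:
            self.truncation_radius = int(math.ceil(5 * self.sigma))
        if self.truncation_radius < 4 * self.sigma:
            raise ValueError("truncation radius must be at least 4 sigma")

    def kernel(self) -> np.ndarray:
        r = self.truncation_radius
        x = np.arange(-r, r + 1, dtype=float)
        k = np.exp(-0.5 * (x / self.sigma) ** 2)
        return k / k.sum()


@dataclass
class OccupancyPair:
    """Matched start-probability (P) and occupancy (O) profiles.

    O_i = sum of P_j over j in [i-footprint+1, i]: the probability that bp i
    is covered by a nucleosome starting at any admissible position.
    """

    P: Dict[str, np.ndarray]
    O: Dict[str, np.ndarray]
    footprint: int = DEFAULT_FOOTPRINT

    def chroms(self) -> List[str]:
        return list(self.P)

    def consistency_error(self) -> float:
        """Max abs deviation of O from the coverage convolution of P."""
        err = 0.0
        for c in self.P:
            err = max(err, float(np.abs(
                coverage_from_starts(self.P[c], self.footprint) - self.O[c]).max()))
        return err


def _bool_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# Profile construction


def reads_to_start_profile(reads: ReadsLike, genome: GenomeAssembly,
                           footprint: int = DEFAULT_FOOTPRINT) -> ReadStartProfile:
    """Convert single-end mapped reads into a per-bp nucleosome start profile.

    Forward reads contribute their weight at the read's first base; reverse
    reads at (last base - footprint + 1), i.e. the read's last base is taken
    as the nucleosome's last base.  Start positions outside [0, L-footprint]
    are dropped (their weight is tallied in ``n_dropped``).
    """
    if footprint < 1:
        raise ValueError("footprint must be >= 1")
    df = _reads_frame(reads)
    data = {c: np.zeros(n, dtype=float) for c, n in genome.chrom_lengths.items()}
    dropped = 0.0
    for chrom, grp in df.groupby("chrom", sort=False):
        if chrom not in genome:
            logger.warning("rejecting %d reads on unknown chromosome %r",
                           len(grp), chrom)
            continue
        L = len(genome.sequences[chrom])
        fwd = grp["strand"].to_numpy() == "+"
        starts = np.where(fwd, grp["start"].to_numpy(),
                          grp["end"].to_numpy() - footprint)
        w = grp["weight"].to_numpy(dtype=float)
        ok = (starts >= 0) & (starts <= L - footprint)
        dropped += float(w[~ok].sum())
        np.add.at(data[chrom], starts[ok].astype(np.intp), w[ok])
    return ReadStartProfile(data, footprint, dropped)


def paired_to_start_profile(pairs: pd.DataFrame, genome: GenomeAssembly,
                            footprint: int = DEFAULT_FOOTPRINT,
                            min_len: int = 130, max_len: int = 200) -> ReadStartProfile:
    """Convert paired-end fragments into a start profile via dyad assignment.

    Fragments whose span lies outside [min_len, max_len] are discarded; each
    surviving fragment places a dyad at the integer midpoint (s+e)//2 and the
    nucleosome extends footprint//2 bases in either direction.
    """
    if footprint < 1:
        raise ValueError("footprint must be >= 1")
    data = {c: np.zeros(n, dtype=float) for c, n in genome.chrom_lengths.items()}
    dropped = 0.0
    half = footprint // 2
    for chrom, grp in pairs.groupby("chrom", sort=False):
        if chrom not in genome:
            logger.warning("rejecting %d fragments on unknown chromosome %r",
                           len(grp), chrom)
            continue
        L = len(genome.sequences[chrom])
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        if (e <= s).any():
            raise ValueError("fragment end must exceed start")
        w = grp["weight"].to_numpy(dtype=float) if "weight" in grp else np.ones(len(grp))
        span = e - s
        keep = (span >= min_len) & (span <= max_len)
        starts = (s[keep] + e[keep]) // 2 - half
        wk = w[keep]
        ok = (starts >= 0) & (starts <= L - footprint)
        dropped += float(wk[~ok].sum())
        np.add.at(data[chrom], starts[ok].astype(np.intp), wk[ok])
    return ReadStartProfile(data, footprint, dropped)


# ---------------------------------------------------------------------------
# Filters


def gap_filter(profile: ReadStartProfile, min_gap: int = 1000) -> FilterMask:
    """Mask every maximal read-free stretch of at least ``min_gap`` bp."""
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    out = {}
    for chrom, v in profile.data.items():
        m = np.zeros(len(v), dtype=bool)
        for s, e in _bool_runs(v == 0):
            if e - s >= min_gap:
                m[s:e] = True
        out[chrom] = m
    return FilterMask(out)


def _running_mean(v: np.ndarray, halfwidth: int) -> np.ndarray:
    """Centered running mean over a +-halfwidth window, shrunk at boundaries."""
    L = len(v)
    c = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(L)
    lo = np.maximum(idx - halfwidth, 0)
    hi = np.minimum(idx + halfwidth + 1, L)
    return (c[hi] - c[lo]) / (hi - lo)


def high_coverage_filter(coverage: Dict[str, np.ndarray],
                         window_halfwidth: int = 75, fold: float = 3.0,
                         upstream_extension: int = 146) -> FilterMask:
    """Mask regions of anomalously high coverage.

    For every bp whose centered running average (over +-window_halfwidth)
    exceeds ``fold`` times the chromosome-wide mean coverage, the flagged
    region extends in both directions until the running average first drops
    to or below the chromosome mean.  Each masked region is then extended
    ``upstream_extension`` bp upstream (toward lower coordinates) so that no
    nucleosome start overlapping it contributes to downstream energy fits.
    """
    out = {}
    for chrom, v in coverage.items():
        L = len(v)
        m = np.zeros(L, dtype=bool)
        out[chrom] = m
        if L == 0:
            continue
        mean = float(v.mean())
        r = _running_mean(v, window_halfwidth)
        above = r > fold * mean
        if not above.any():
            continue
        at_or_below = np.flatnonzero(r <= mean)
        for s, e in _bool_runs(above):
            j = np.searchsorted(at_or_below, s) - 1
            left = at_or_below[j] + 1 if j >= 0 else 0
            k = np.searchsorted(at_or_below, e)
            right = at_or_below[k] if k < len(at_or_below) else L
            m[max(0, left - upstream_extension):right] = True
    return FilterMask(out)


def cutsite_filter(genome: GenomeAssembly, site_pattern: str,
                   flank: int = 200) -> FilterMask:
    """Mask ``flank`` bp on either side of every restriction-site match.

    The IUPAC pattern is matched on both strands (the classical Rsa I "GTAC"
    and Hinc II "GTYRAC" sites are reverse-complement palindromes, so both
    scans coincide for them).
    """
    out = {}
    for chrom, seq in genome.sequences.items():
        m = np.zeros(len(seq), dtype=bool)
        for s, e in genome.find_pattern(chrom, site_pattern, both_strands=True):
            m[max(0, s - flank):min(len(seq), e + flank)] = True
        out[chrom] = m
    return FilterMask(out)


# ---------------------------------------------------------------------------
# Smoothing and normalization


def gaussian_smooth(profile: ReadStartProfile,
                    params: SmoothingParams) -> ReadStartProfile:
    """Replace each start weight by a unit-area Gaussian centered on its bp.

    The kernel is truncated at the configured radius and renormalized, so the
    total weight is conserved except for mass pushed past chromosome ends.
    """
    k = params.kernel()
    return profile.map(lambda v: convolve1d(v, k, mode="constant", cval=0.0))


def coverage_from_starts(starts: np.ndarray, footprint: int) -> np.ndarray:
    """Occupancy/coverage profile: O_i = sum of starts over [i-footprint+1, i]."""
    c = np.concatenate([[0.0], np.cumsum(starts)])
    idx = np.arange(len(starts))
    lo = np.maximum(idx - footprint + 1, 0)
    return c[idx + 1] - c[lo]


def normalize_to_probability(smoothed_starts: ReadStartProfile,
                             mask: Optional[FilterMask] = None,
                             footprint: Optional[int] = None) -> OccupancyPair:
    """Scale start and coverage profiles into probability space.

    Coverage is computed from the (smoothed) start profile; both profiles are
    divided, per chromosome, by the maximum coverage over unmasked bps, so the
    occupancy profile is bounded by 1 off the filtered regions.
    """
    fp = footprint if footprint is not None else smoothed_starts.footprint
    P, O = {}, {}
    for chrom, v in smoothed_starts.data.items():
        cov = coverage_from_starts(v, fp)
        keep = ~mask[chrom] if mask is not None and chrom in mask.data \
            else np.ones(len(v), dtype=bool)
        if not keep.any():
            logger.warning("chromosome %r fully masked; skipped", chrom)
            continue
        scale = float(cov[keep].max())
        if scale <= 0:
            logger.warning("chromosome %r has zero coverage; skipped", chrom)
            continue
        P[chrom] = v / scale
        O[chrom] = cov / scale
    return OccupancyPair(P, O, fp)


def normalized_occupancy(O: Dict[str, np.ndarray],
                         mask: Optional[FilterMask] = None) -> Dict[str, np.ndarray]:
    """Z-score an occupancy profile over unmasked bps (pooled genome-wide).

    Returns per-chromosome arrays with mean 0 and population variance 1 over
    the unmasked positions; masked positions are NaN.
    """
    vals = []
    for chrom, v in O.items():
        keep = ~mask[chrom] if mask is not None and chrom in mask.data \
            else np.ones(len(v), dtype=bool)
        vals.append(v[keep])
    pooled = np.concatenate(vals)
    if len(pooled) < 2:
        raise ValueError("need at least 2 unmasked bps")
    mu = pooled.mean()
    sd = pooled.std()  # population convention
    if sd == 0:
        raise ValueError("zero variance: normalized occupancy undefined")
    out = {}
    for chrom, v in O.items():
        z = (v - mu) / sd
        if mask is not None and chrom in mask.data:
            z = np.where(mask[chrom], np.nan, z)
        out[chrom] = z
    return out
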