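"""Dataset-versus-dataset and model-versus-data comparisons.

Covers pooled profile correlations, selection of well-positioned nucleosomes
(raw read-count peaks), dyad-aligned dinucleotide frequency curves, predicted
start-probability enrichment around well-positioned sites, within-D overlap
between datasets, and chromosome-scale segment summaries of coverage and
composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeAssembly
from .profiles import FilterMask, ReadStartProfile

__all__ = [
    "WellPositionedSet",
    "profile_correlation",
    "select_well_positioned",
    "dyad_dinucleotide_frequencies",
    "probability_enrichment",
    "overlap_within_D",
    "chromosome_segment_summary",
    "segment_dinucleotide_composition",
    "DINUC_GROUPS",
]

#: Dinucleotide strand-symmetric composition groups.
DINUC_GROUPS = {
    "AT": ("AA", "AT", "TA", "TT"),
    "GC": ("CC", "CG", "GC", "GG"),
    "mixed": ("AC", "AG", "CA", "CT", "GA", "GT", "TC", "TG"),
}


@dataclass
class WellPositionedSet:
    """Start positions whose raw read-profile value reaches a cutoff."""

    positions: Dict[str, np.ndarray]
    cutoff: float
    read_fraction: float
    footprint: int = 147

    def n_sites(self) -> int:
        return int(sum(len(v) for v in self.positions.values()))


def _unmasked(mask: Optional[FilterMask], chrom: str, n: int) -> np.ndarray:
    if mask is not None and chrom in mask.data:
        return ~mask[chrom][:n]
    return np.ones(n, dtype=bool)


def profile_correlation(A: Dict[str, np.ndarray], B: Dict[str, np.ndarray],
                        mask: Optional[FilterMask] = None) -> float:
    """Pearson correlation pooled over all chromosomes, masked bps excluded."""
    xs, ys = [], []
    for chrom in A:
        a, b = np.asarray(A[chrom], float), np.asarray(B[chrom], float)
        if len(a) != len(b):
            raise ValueError(f"length mismatch on {chrom}")
        keep = _unmasked(mask, chrom, len(a)) & np.isfinite(a) & np.isfinite(b)
        xs.append(a[keep])
        ys.append(b[keep])
    x, y = np.concatenate(xs), np.concatenate(ys)
    if len(x) < 2:
        raise ValueError("need at least 2 unmasked bps")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def select_well_positioned(profile: ReadStartProfile, cutoff: float,
                           mask: Optional[FilterMask] = None) -> WellPositionedSet:
    """Positions of the raw start profile with weight >= cutoff.

    The cutoff thresholds the unsmoothed profile (fractional multi-mapper
    weights pass only by summation).  Dataset-specific cutoffs used for the
    published maps were 3-9 reads, capturing ~1-1.5% of all reads.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    positions = {}
    selected_weight = 0.0
    for chrom, v in profile.data.items():
        keep = _unmasked(mask, chrom, len(v))
        pos = np.flatnonzero((v >= cutoff) & keep)
        positions[chrom] = pos
        selected_weight += float(v[pos].sum())
    total = profile.total_weight
    frac = selected_weight / total if total > 0 else 0.0
    return WellPositionedSet(positions, cutoff, frac, profile.footprint)


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the boundaries."""
    if window <= 1:
        return v
    half = window // 2
    c = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(len(v))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, len(v))
    return (c[hi] - c[lo]) / (hi - lo)


def _dinuc_group_codes() -> np.ndarray:
    """Map dinucleotide code (4*a+b) -> group index {0: AT, 1: GC, 2: mixed}."""
    out = np.empty(16, dtype=np.int8)
    names = list(DINUC_GROUPS)
    for gi, (gname, words) in enumerate(DINUC_GROUPS.items()):
        for w in words:
            a = "ACGT".index(w[0])
            b = "ACGT".index(w[1])
            out[4 * a + b] = gi
    return out


_GROUP_OF = _dinuc_group_codes()


def genome_dinucleotide_group_frequencies(genome: GenomeAssembly) -> np.ndarray:
    """Genome-wide frequencies of the three dinucleotide groups (forward strand)."""
    counts = np.zeros(3)
    for chrom in genome:
        codes = genome.codes(chrom)
        ok = (codes[:-1] >= 0) & (codes[1:] >= 0)
        d = 4 * codes[:-1][ok].astype(np.int32) + codes[1:][ok]
        counts += np.bincount(_GROUP_OF[d], minlength=3)
    return counts / counts.sum()


def dyad_dinucleotide_frequencies(sites: WellPositionedSet,
                                  genome: GenomeAssembly, flank: int = 100,
                                  smoothing: int = 3) -> pd.DataFrame:
    """Dyad-aligned relative dinucleotide group frequencies.

    For every offset relative to the dyad (site start + footprint//2), the
    frequency of each group among site dinucleotides — counted on both
    strands — is divided by the genome-wide frequency of that group.  A
    centered moving average (default 3 bp) smooths the curves.
    """
    if sites.n_sites() == 0:
        raise ValueError("no sites")
    half = sites.footprint // 2
    offsets = np.arange(-flank, flank + 1)
    counts = np.zeros((len(offsets), 3))
    n_used = 0
    for chrom, pos in sites.positions.items():
        codes = genome.codes(chrom)
        L = len(codes)
        dyads = pos + half
        ok = (dyads - flank - 1 >= 0) & (dyads + flank + 1 < L)
        dyads = dyads[ok]
        if len(dyads) == 0:
            continue
        n_used += len(dyads)
        for k, d in enumerate(offsets):
            # forward strand: dinucleotide starting at dyad + d
            j = dyads + d
            valid = (codes[j] >= 0) & (codes[j + 1] >= 0)
            dc = 4 * codes[j][valid].astype(np.int32) + codes[j + 1][valid]
            counts[k] += np.bincount(_GROUP_OF[dc], minlength=3)
            # reverse strand: the revcomp window's dinucleotide at offset d
            # corresponds to the forward dinucleotide starting at dyad - d - 1
            j = dyads - d - 1
            valid = (codes[j] >= 0) & (codes[j + 1] >= 0)
            dc = 4 * codes[j][valid].astype(np.int32) + codes[j + 1][valid]
            counts[k] += np.bincount(_GROUP_OF[dc], minlength=3)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    gfreq = genome_dinucleotide_group_frequencies(genome)
    rel = freqs / gfreq[None, :]
    out = {"offset": offsets}
    for gi, gname in enumerate(DINUC_GROUPS):
        out[gname] = _moving_average(rel[:, gi], smoothing)
    df = pd.DataFrame(out)
    df.attrs["n_sites"] = n_used
    return df


def probability_enrichment(P_pred: Dict[str, np.ndarray],
                           sites: WellPositionedSet, flank: int = 100,
                           smoothing: int = 7) -> pd.DataFrame:
    """Predicted start-probability enrichment around well-positioned sites.

    The predicted probability at each offset from a site is divided by the
    genome-wide mean of the prediction and averaged over sites; curves are
    smoothed with a centered 7-bp moving average.
    """
    pooled = np.concatenate([np.asarray(v, float) for v in P_pred.values()])
    gmean = float(pooled[np.isfinite(pooled)].mean())
    if gmean == 0:
        raise ValueError("zero-mean prediction")
    offsets = np.arange(-flank, flank + 1)
    acc = np.zeros(len(offsets))
    n = 0
    for chrom, pos in sites.positions.items():
        v = np.asarray(P_pred[chrom], float)
        ok = (pos - flank >= 0) & (pos + flank < len(v))
        pos = pos[ok]
        if len(pos) == 0:
            continue
        acc += v[pos[:, None] + offsets[None, :]].sum(axis=0)
        n += len(pos)
    if n == 0:
        raise ValueError("no usable sites")
    curve = acc / (n * gmean)
    return pd.DataFrame({"offset": offsets,
                         "enrichment": _moving_average(curve, smoothing),
                         "n": n})


def overlap_within_D(sites_A: WellPositionedSet, profile_A: ReadStartProfile,
                     profile_B: ReadStartProfile, D_max: int = 50) -> pd.DataFrame:
    """Mean B-dataset read weight within +-D bp of A's well-positioned sites.

    B's profile is rescaled so its total weight matches A's (the comparison
    is between normalized coverages); for each D in 0..D_max the value is the
    average, over A sites, of the summed rescaled B weights in [p-D, p+D].
    """
    scale = profile_A.total_weight / profile_B.total_weight
    Ds = np.arange(D_max + 1)
    acc = np.zeros(len(Ds))
    n = 0
    for chrom, pos in sites_A.positions.items():
        if chrom not in profile_B.data:
            continue
        v = profile_B.data[chrom] * scale
        c = np.concatenate([[0.0], np.cumsum(v)])
        L = len(v)
        n += len(pos)
        for k, D in enumerate(Ds):
            lo = np.maximum(pos - D, 0)
            hi = np.minimum(pos + D + 1, L)
            acc[k] += (c[hi] - c[lo]).sum()
    if n == 0:
        raise ValueError("no sites")
    return pd.DataFrame({"D": Ds, "mean_reads": acc / n, "n_sites": n})


def chromosome_segment_summary(profile: np.ndarray, n_segments: int = 1000,
                               mask: Optional[np.ndarray] = None,
                               value_bins: int = 50) -> Tuple[pd.DataFrame, np.ndarray]:
    """Equal-length segment means and a (segment x value) histogram.

    Operates on a single chromosome profile.  Segment length is
    ceil(L / n_segments); the last segment may be shorter.  Means are over
    unmasked bps (NaN where a segment is fully masked).  The 2-D histogram
    counts per-bp values of unmasked positions.
    """
    v = np.asarray(profile, float)
    L = len(v)
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    seg_len = -(-L // n_segments)
    keep = ~mask if mask is not None else np.ones(L, dtype=bool)
    keep = keep & np.isfinite(v)
    edges_v = np.linspace(np.nanmin(v[keep]) if keep.any() else 0.0,
                          np.nanmax(v[keep]) if keep.any() else 1.0,
                          value_bins + 1)
    hist = np.zeros((n_segments, value_bins), dtype=np.int64)
    means = np.full(n_segments, np.nan)
    starts = np.arange(n_segments) * seg_len
    for s in range(n_segments):
        lo, hi = starts[s], min(starts[s] + seg_len, L)
        if lo >= L:
            break
        sel = keep[lo:hi]
        if sel.any():
            vals = v[lo:hi][sel]
            means[s] = vals.mean()
            hist[s] = np.histogram(vals, bins=edges_v)[0]
    df = pd.DataFrame({"segment": np.arange(n_segments),
                       "start": starts,
                       "end": np.minimum(starts + seg_len, L),
                       "mean": means})
    return df, hist


def segment_dinucleotide_composition(genome: GenomeAssembly, chrom: str,
                                     n_segments: int = 1000) -> pd.DataFrame:
    """Per-segment frequencies of the AT / GC / mixed dinucleotide groups.

    Dinucleotides containing ambiguous bases are excluded; a dinucleotide
    belongs to the segment of its first base.  Frequencies sum to 1 per
    segment (NaN for segments without countable dinucleotides).
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    codes = genome.codes(chrom)
    L = len(codes)
    seg_len = -(-L // n_segments)
    ok = (codes[:-1] >= 0) & (codes[1:] >= 0)
    j = np.flatnonzero(ok)
    dc = 4 * codes[j].astype(np.int32) + codes[j + 1]
    grp = _GROUP_OF[dc]
    seg = j // seg_len
    counts = np.zeros((n_segments, 3))
    np.add.at(counts, (seg, grp), 1.0)
    tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(tot > 0, counts / tot, np.nan)
    df = pd.DataFrame(freqs, columns=list(DINUC_GROUPS))
    df.insert(0, "segment", np.arange(n_segments))
    df.insert(1, "rel_coord", (np.arange(n_segments) + 0.5) / n_segments)
    return df
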