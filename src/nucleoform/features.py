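"""Exon/intron, splice-site, expression, and interval-group occupancy analyses.

Gene structures are held as :class:`GeneModel` objects (0-based half-open
exon intervals in genomic order); all splice-window extraction and exon
ordinal logic is strand-aware (transcript orientation), while occupancy
profiles themselves are strandless.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAssembly
from .profiles import FilterMask

__all__ = [
    "GeneModel",
    "SpliceSitePWM",
    "select_exons_introns",
    "feature_mean_occupancy",
    "gc_tertile_profiles",
    "train_splice_pwm",
    "score_splice_sites",
    "expression_groups",
    "exon_number_profile",
    "interval_group_compare",
]

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class GeneModel:
    """One gene (single transcript): ordered exons and derived introns."""

    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    expression: Optional[float] = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")

    @property
    def introns(self) -> List[Tuple[int, int]]:
        """Gaps between consecutive exons, genomic order."""
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exon_ordinals(self) -> List[int]:
        """1-based exon numbers in transcript orientation, genomic order."""
        n = len(self.exons)
        return list(range(1, n + 1)) if self.strand == "+" \
            else list(range(n, 0, -1))


def _features_frame(rows: Iterable[tuple]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "gene_id", "ordinal"])


def select_exons_introns(genes: Sequence[GeneModel], min_intron: int = 125,
                         exon_range: Tuple[int, int] = (50, 500),
                         ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Qualifying exon and intron sets for occupancy analyses.

    An exon qualifies if it is internal (first and last exons of every gene
    are excluded), its length lies within ``exon_range`` (inclusive), and
    both flanking introns are at least ``min_intron`` bp.  The intron set
    holds all introns of at least ``min_intron`` bp.
    """
    lo, hi = exon_range
    exon_rows, intron_rows = [], []
    for g in genes:
        introns = g.introns
        ordinals = g.exon_ordinals()
        for k, (s, e) in enumerate(introns):
            if e - s >= min_intron:
                intron_rows.append((g.chrom, s, e, g.strand, g.gene_id, k + 1))
        for k, (s, e) in enumerate(g.exons):
            if k == 0 or k == len(g.exons) - 1:
                continue
            if not lo <= e - s <= hi:
                continue
            left, right = introns[k - 1], introns[k]
            if (left[1] - left[0]) >= min_intron and \
                    (right[1] - right[0]) >= min_intron:
                exon_rows.append((g.chrom, s, e, g.strand, g.gene_id,
                                  ordinals[k]))
    return _features_frame(exon_rows), _features_frame(intron_rows)


def _per_feature_means(features: pd.DataFrame, Nz: Dict[str, np.ndarray],
                       mask: Optional[FilterMask] = None) -> np.ndarray:
    """Mean occupancy per feature over unmasked, finite bps (NaN if none)."""
    out = np.full(len(features), np.nan)
    for i, row in enumerate(features.itertuples(index=False)):
        v = Nz[row.chrom][row.start:row.end]
        if mask is not None and row.chrom in mask.data:
            v = np.where(mask[row.chrom][row.start:row.end], np.nan, v)
        v = v[np.isfinite(v)]
        if len(v):
            out[i] = v.mean()
    return out


def feature_mean_occupancy(features: pd.DataFrame, Nz: Dict[str, np.ndarray],
                           mask: Optional[FilterMask] = None
                           ) -> Tuple[float, float, np.ndarray]:
    """Mean +- standard error of per-feature mean occupancy.

    Each feature is first averaged over its own unmasked bps; fully masked
    features are dropped.  Returns (mean, SE, per-feature means).
    """
    if len(features) == 0:
        raise ValueError("empty feature set")
    per = _per_feature_means(features, Nz, mask)
    vals = per[np.isfinite(per)]
    if len(vals) == 0:
        raise ValueError("all features fully masked")
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return float(vals.mean()), se, per


def _feature_gc(features: pd.DataFrame, genome: GenomeAssembly) -> np.ndarray:
    """GC fraction per feature, ambiguous bases excluded from both tallies."""
    out = np.full(len(features), np.nan)
    for i, row in enumerate(features.itertuples(index=False)):
        codes = genome.codes(row.chrom)[row.start:row.end]
        valid = codes >= 0
        if valid.any():
            out[i] = ((codes == 1) | (codes == 2))[valid].mean()
    return out


def gc_tertile_profiles(features: pd.DataFrame, genome: GenomeAssembly,
                        Nz: Dict[str, np.ndarray], alignment: str = "3end",
                        max_offset: int = 200, min_length_factor: int = 1
                        ) -> Dict[str, pd.DataFrame]:
    """Aligned average occupancy curves for GC-content tertiles.

    Features are split into three equally sized groups of low, medium and
    high GC content (ties and equal GC broken by stable input order).  For
    boundary alignments the value at offset x (bases into the feature from
    the 5' or 3' boundary, transcript orientation) averages only features of
    length >= min_length_factor * x — pass factor 2 for introns so the
    averaged position also keeps x bases clear of the opposite boundary.
    ``center`` alignment uses signed offsets from the feature midpoint.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 features")
    if alignment not in ("center", "5end", "3end"):
        raise ValueError(f"unknown alignment {alignment!r}")
    gc = _feature_gc(features, genome)
    order = np.argsort(gc, kind="stable")
    tertiles = np.array_split(order, 3)
    names = ("low", "mid", "high")

    if alignment == "center":
        offsets = np.arange(-max_offset, max_offset + 1)
    else:
        offsets = np.arange(max_offset + 1)

    out = {}
    for name, idx in zip(names, tertiles):
        sub = features.iloc[np.sort(idx)]
        acc = [[] for _ in offsets]
        for row in sub.itertuples(index=False):
            length = row.end - row.start
            v = Nz[row.chrom]
            for k, x in enumerate(offsets):
                if alignment == "center":
                    mid = (row.start + row.end) // 2
                    pos = mid + (x if row.strand == "+" else -x)
                    if not row.start <= pos < row.end:
                        continue
                elif alignment == "5end":
                    if length < min_length_factor * max(x, 1):
                        continue
                    pos = row.start + x if row.strand == "+" else row.end - 1 - x
                else:  # 3end: x bases upstream of the 3' boundary
                    if length < min_length_factor * max(x, 1):
                        continue
                    pos = row.end - 1 - x if row.strand == "+" else row.start + x
                val = v[pos]
                if np.isfinite(val):
                    acc[k].append(val)
        means = np.array([np.mean(a) if a else np.nan for a in acc])
        ses = np.array([np.std(a, ddof=1) / np.sqrt(len(a))
                        if len(a) > 1 else (0.0 if a else np.nan) for a in acc])
        ns = np.array([len(a) for a in acc])
        out[name] = pd.DataFrame({"offset": offsets, "mean": means,
                                  "se": ses, "n": ns})
        out[name].attrs["gc_range"] = (float(np.nanmin(gc[idx])),
                                       float(np.nanmax(gc[idx])))
    return out


# ---------------------------------------------------------------------------
# Splice sites


@dataclass
class SpliceSitePWM:
    """Position-specific weight matrix for donor or acceptor splice sites.

    Donor (5') windows span 3 exonic + 7 intronic bases; acceptor (3')
    windows span 26 intronic + 3 exonic bases, both in transcript
    orientation.  ``probs`` holds per-position base probabilities (W x 4);
    ``background`` the genome-wide base frequencies.
    """

    site_kind: str
    probs: np.ndarray
    background: np.ndarray
    exon_bases: int = 3
    intron_bases: int = 7

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def score(self, seq: str) -> float:
        """S = sum over positions of log(p_i(base) / b(base))."""
        if len(seq) != self.width:
            raise ValueError("sequence length does not match PWM width")
        s = 0.0
        for i, base in enumerate(seq):
            j = _BASE_IDX.get(base)
            if j is None:
                return float("nan")
            s += np.log(self.probs[i, j] / self.background[j])
        return float(s)


def _splice_windows(gene: GeneModel, site_kind: str, exon_bases: int,
                    intron_bases: int) -> List[Tuple[int, int, int]]:
    """(genomic start, end, exon index) of every internal junction window.

    Windows are reported as forward-genomic intervals; the caller
    reverse-complements for minus-strand genes.  Donor windows belong to the
    exon 5' of the junction, acceptor windows to the exon 3' of it
    (transcript orientation).
    """
    wins = []
    n = len(gene.exons)
    plus = gene.strand == "+"
    for k, (s, e) in enumerate(gene.exons):
        if site_kind == "donor":
            # junction at the exon's transcript-3' edge; needs a following intron
            if plus and k < n - 1:
                wins.append((e - exon_bases, e + intron_bases, k))
            elif not plus and k > 0:
                wins.append((s - intron_bases, s + exon_bases, k))
        elif site_kind == "acceptor":
            # junction at the exon's transcript-5' edge; needs a preceding intron
            if plus and k > 0:
                wins.append((s - intron_bases, s + exon_bases, k))
            elif not plus and k < n - 1:
                wins.append((e - exon_bases, e + intron_bases, k))
        else:
            raise ValueError(f"unknown site kind {site_kind!r}")
    return wins


def _default_intron_bases(site_kind: str) -> int:
    return 7 if site_kind == "donor" else 26


def _window_sequences(genes: Sequence[GeneModel], genome: GenomeAssembly,
                      site_kind: str, exon_bases: int, intron_bases: int):
    """Yield (gene, exon index, window sequence in transcript orientation)."""
    for g in genes:
        L = len(genome.sequences[g.chrom])
        for ws, we, k in _splice_windows(g, site_kind, exon_bases, intron_bases):
            if ws < 0 or we > L:
                continue
            seq = genome.fetch(g.chrom, ws, we, g.strand)
            yield g, k, seq


def train_splice_pwm(genes: Sequence[GeneModel], genome: GenomeAssembly,
                     site_kind: str, exon_bases: int = 3,
                     intron_bases: Optional[int] = None,
                     pseudocount: float = 0.5) -> SpliceSitePWM:
    """Estimate a splice-site PWM by aligning all sites of one kind.

    Base frequencies are tallied per window position (with a pseudocount to
    avoid zero probabilities) and the background is the genome-wide base
    composition.
    """
    if intron_bases is None:
        intron_bases = _default_intron_bases(site_kind)
    width = exon_bases + intron_bases
    counts = np.full((width, 4), pseudocount)
    n_sites = 0
    for _, _, seq in _window_sequences(genes, genome, site_kind,
                                       exon_bases, intron_bases):
        for i, base in enumerate(seq):
            j = _BASE_IDX.get(base)
            if j is not None:
                counts[i, j] += 1
        n_sites += 1
    if n_sites == 0:
        raise ValueError("no splice sites found")
    probs = counts / counts.sum(axis=1, keepdims=True)
    bg = np.zeros(4)
    for chrom in genome:
        codes = genome.codes(chrom)
        bg += np.bincount(codes[codes >= 0], minlength=4)
    bg /= bg.sum()
    return SpliceSitePWM(site_kind, probs, bg, exon_bases, intron_bases)


def score_splice_sites(pwm: SpliceSitePWM, genes: Sequence[GeneModel],
                       genome: GenomeAssembly, quantile: float = 0.10
                       ) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Score all sites of the PWM's kind and split exons by site strength.

    Returns (scores, strong, weak): per-exon site scores and the top and
    bottom ``quantile`` of exons ranked by score (stable order on ties).
    """
    rows = []
    for g, k, seq in _window_sequences(genes, genome, pwm.site_kind,
                                       pwm.exon_bases, pwm.intron_bases):
        s, e = g.exons[k]
        score = pwm.score(seq)
        if np.isfinite(score):
            rows.append((g.chrom, s, e, g.strand, g.gene_id,
                         g.exon_ordinals()[k], score))
    scores = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                         "gene_id", "ordinal", "score"])
    n = len(scores)
    k = int(n * quantile)
    if k < 1:
        raise ValueError("too few sites for the requested quantile")
    order = np.argsort(-scores["score"].to_numpy(), kind="stable")
    strong = scores.iloc[order[:k]].reset_index(drop=True)
    weak = scores.iloc[order[::-1][:k][::-1]].reset_index(drop=True)
    return scores, strong, weak


# ---------------------------------------------------------------------------
# Expression and interval groups


def expression_groups(tag_counts: Dict[str, float], quantile: float = 0.10
                      ) -> Tuple[List[str], List[str]]:
    """Strong and weak expression gene groups from per-gene tag counts.

    Genes without any tags are omitted; the remaining genes are ranked by
    count (ties broken by stable input order) and the top and bottom
    ``quantile`` fractions returned as (strong, weak).
    """
    genes = [g for g, c in tag_counts.items() if c > 0]
    counts = np.array([tag_counts[g] for g in genes], dtype=float)
    if (counts < 0).any():
        raise ValueError("tag counts must be non-negative")
    n = len(genes)
    k = int(n * quantile)
    if k < 1:
        raise ValueError("fewer than 1/quantile genes with tags")
    order = np.argsort(-counts, kind="stable")
    strong = [genes[i] for i in order[:k]]
    weak = [genes[i] for i in order[::-1][:k]]
    return strong, weak


def exon_number_profile(exons: pd.DataFrame, Nz: Dict[str, np.ndarray],
                        mask: Optional[FilterMask] = None,
                        min_exons: int = 20) -> pd.DataFrame:
    """Mean occupancy by exon ordinal (transcript orientation).

    ``exons`` is a qualifying-exon frame from :func:`select_exons_introns`
    (which preserves ordinals); ordinals with fewer than ``min_exons``
    contributing exons are dropped.
    """
    per = _per_feature_means(exons, Nz, mask)
    df = pd.DataFrame({"ordinal": exons["ordinal"].to_numpy(), "mean_occ": per})
    df = df[np.isfinite(df["mean_occ"])]
    rows = []
    for ordinal, grp in df.groupby("ordinal"):
        if len(grp) >= min_exons:
            v = grp["mean_occ"].to_numpy()
            se = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
            rows.append((int(ordinal), v.mean(), se, len(v)))
    return pd.DataFrame(rows, columns=["ordinal", "mean", "se", "n"])


def interval_group_compare(groups: Dict[str, pd.DataFrame],
                           Nz: Dict[str, np.ndarray],
                           mask: Optional[FilterMask] = None
                           ) -> Tuple[pd.DataFrame, Dict[Tuple[str, str], float]]:
    """Per-group mean occupancy and Welch t-tests between group pairs.

    Each group is a feature frame (chrom/start/end[/strand] columns); returns
    a summary frame (group, mean, se, n) and a dict of two-sided Welch
    p-values keyed by group-name pair.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    per_group = {}
    rows = []
    for name, feats in groups.items():
        if len(feats) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 features")
        mean, se, per = feature_mean_occupancy(feats, Nz, mask)
        vals = per[np.isfinite(per)]
        per_group[name] = vals
        rows.append((name, mean, se, len(vals)))
    pvals = {}
    for a, b in itertools.combinations(per_group, 2):
        va, vb = per_group[a], per_group[b]
        if va.std() == 0 and vb.std() == 0:
            raise ValueError(f"degenerate variance in groups {a!r}, {b!r}")
        t, p = stats.ttest_ind(va, vb, equal_var=False)
        pvals[(a, b)] = float(p)
    return pd.DataFrame(rows, columns=["group", "mean", "se", "n"]), pvals
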