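"""Sequence-energy models of nucleosome formation.

Three models relate the per-start formation energy E_i to the underlying DNA
sequence of the 147-bp site, always excluding words that extend into the
3 terminal bps on each end of the site:

* ``PositionIndependentModel`` (order N): E_i is linear in the counts of
  words of length 1..N inside the site interior, with sum-to-zero marginal
  constraints on the word energies.  For N = 2 this has 13 free parameters
  (offset + 3 mononucleotide + 9 dinucleotide energies).
* ``SpatiallyResolvedModel``: a separate mono- and dinucleotide energy for
  every interior position, constrained to sum to zero per position; for a
  147-bp footprint this has 1684 free parameters.
* ``BioinformaticsModel``: a dinucleotide scoring model in which each word's
  score P_w derives from the reciprocal coverage-weighted average of its
  occurrences, and E_i is the sum of log-scores over interior dinucleotides.

The first two are fitted by constrained least squares in an explicit reduced
(sum-to-zero contrast) basis, per genome segment, with parameters averaged
across segments.  All three follow the scikit-learn estimator protocol:
hyperparameters in ``__init__``, ``fit`` / ``predict``, fitted attributes
with trailing underscores.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import lstsq as _lstsq, solve as _solve
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .energetics import EnergyProfile, ThermoParams, equilibrium_predict
from .genome import GenomeAssembly
from .profiles import FilterMask, OccupancyPair

__all__ = [
    "BASES",
    "DINUCLEOTIDES",
    "count_words",
    "count_free_parameters",
    "PositionIndependentModel",
    "SpatiallyResolvedModel",
    "BioinformaticsModel",
    "fit_position_independent",
    "fit_spatially_resolved",
    "fit_bioinformatics",
    "predict_occupancy_from_model",
]

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

# Sum-to-zero contrast basis: columns span {x in R^4 : sum(x) = 0}.
_C4 = np.array([[1.0, 0.0, 0.0],
                [0.0, 1.0, 0.0],
                [0.0, 0.0, 1.0],
                [-1.0, -1.0, -1.0]])
# 16x9 basis for 4x4 energy matrices with zero row and column sums.
_K16 = np.kron(_C4, _C4)


def count_words(genome: GenomeAssembly, chrom: str, start: int,
                footprint: int = 147, N: int = 2,
                terminal_exclusion: int = 3) -> Dict[str, int]:
    """Word counts inside one nucleosomal site.

    Counts words of length 1..N lying entirely within
    [start + terminal_exclusion, start + footprint - terminal_exclusion),
    forward strand only.  Raises if the site runs off the chromosome; windows
    containing N bases are reported with an ``"usable"`` flag of 0.
    """
    L = len(genome.sequences[chrom])
    if start < 0 or start + footprint > L:
        raise ValueError("site extends beyond chromosome bounds")
    interior = genome.sequences[chrom][
        start + terminal_exclusion: start + footprint - terminal_exclusion]
    counts: Dict[str, int] = {"usable": int("N" not in interior)}
    for n in range(1, N + 1):
        for i in range(len(interior) - n + 1):
            word = interior[i:i + n]
            if "N" not in word:
                counts[word] = counts.get(word, 0) + 1
    return counts


def count_free_parameters(model_kind: str, footprint: int = 147,
                          terminal_exclusion: int = 3, N: int = 2) -> int:
    """Number of linearly independent parameters of a sequence-energy model.

    ``position_independent``: 1 offset + sum_{n<=N} 3^n constrained word
    energies.  ``spatially_resolved``: 1 offset + 3 per interior
    mononucleotide position + 9 per interior dinucleotide start.
    """
    interior = footprint - 2 * terminal_exclusion
    if model_kind == "position_independent":
        return 1 + sum(3 ** n for n in range(1, N + 1))
    if model_kind == "spatially_resolved":
        return 1 + 3 * interior + 9 * (interior - 1)
    raise ValueError(f"unknown model kind {model_kind!r}")


# ---------------------------------------------------------------------------
# Vectorized per-chromosome word-count design blocks


def _sliding_blocks(codes: np.ndarray, footprint: int, t: int):
    """Sliding word counts for every admissible start on one chromosome.

    Returns (mono, dinuc, usable): mono is (n,4) counts of each base in the
    site interior, dinuc is (n,16) counts of interior dinucleotides, usable
    flags rows whose interior contains no ambiguous base.
    """
    L = len(codes)
    n = L - footprint + 1
    if n < 1:
        z = np.zeros((0,), dtype=bool)
        return np.zeros((0, 4), np.int32), np.zeros((0, 16), np.int32), z
    onehot = np.zeros((L + 1, 4), dtype=np.int32)
    valid = codes >= 0
    onehot[1:][valid, codes[valid]] = 1
    C = np.cumsum(onehot, axis=0)
    idx = np.arange(n)
    mono = C[idx + footprint - t] - C[idx + t]

    d_ok = valid[:-1] & valid[1:]
    dcodes = np.where(d_ok, 4 * codes[:-1].astype(np.int32) + codes[1:], 0)
    dhot = np.zeros((L, 16), dtype=np.int32)
    dhot[1:][d_ok, dcodes[d_ok]] = 1
    D = np.cumsum(dhot, axis=0)
    # dinucleotide starts j in [s+t, s+footprint-t-1)
    dinuc = D[idx + footprint - t - 1] - D[idx + t]

    nbad = np.cumsum(np.concatenate([[0], (~valid).astype(np.int64)]))
    usable = (nbad[idx + footprint - t] - nbad[idx + t]) == 0
    return mono, dinuc, usable


def _window_codes(codes: np.ndarray, starts: np.ndarray, offsets: np.ndarray):
    """Gather codes[starts[r] + offsets[c]] as an (R, C) matrix."""
    return codes[starts[:, None] + offsets[None, :]]


def _usable_rows(genome: GenomeAssembly, chrom: str, energy: EnergyProfile,
                 footprint: int, t: int) -> Tuple[np.ndarray, np.ndarray]:
    """(start indices, energies) of rows usable for fitting on one chromosome."""
    codes = genome.codes(chrom)
    L = len(codes)
    n = L - footprint + 1
    Ev = energy.E[chrom]
    if len(Ev) != n:
        raise ValueError(f"energy profile length mismatch on {chrom}")
    nbad = np.cumsum(np.concatenate([[0], (codes < 0).astype(np.int64)]))
    idx = np.arange(n)
    no_n = (nbad[idx + footprint - t] - nbad[idx + t]) == 0
    ok = energy.defined[chrom] & np.isfinite(Ev) & no_n
    return idx[ok], Ev[ok]


def _genome_segments(genome: GenomeAssembly, n_segments: int):
    """Assign every (chrom, start) to one of n_segments equal-size genomic bins."""
    total = genome.total_length
    offsets = {}
    off = 0
    for c in genome:
        offsets[c] = off
        off += len(genome.sequences[c])
    def seg_of(chrom: str, starts: np.ndarray) -> np.ndarray:
        g = offsets[chrom] + starts
        return np.minimum((g * n_segments) // total, n_segments - 1)
    return seg_of


class _SegmentedLinearFit:
    """Accumulate per-segment reduced design matrices and solve each."""

    def __init__(self, n_params: int, min_rows_factor: int = 10):
        self.n_params = n_params
        self.min_rows = min_rows_factor * n_params
        self.X: Dict[int, List[np.ndarray]] = {}
        self.y: Dict[int, List[np.ndarray]] = {}

    def add(self, seg_ids: np.ndarray, X: np.ndarray, y: np.ndarray) -> None:
        for s in np.unique(seg_ids):
            pick = seg_ids == s
            self.X.setdefault(int(s), []).append(X[pick])
            self.y.setdefault(int(s), []).append(y[pick])

    def solve(self) -> Tuple[np.ndarray, int]:
        thetas = []
        for s in sorted(self.X):
            X = np.vstack(self.X[s])
            y = np.concatenate(self.y[s])
            if len(y) < self.min_rows:
                logger.warning("segment %d skipped: %d rows < %d required",
                               s, len(y), self.min_rows)
                continue
            if self.n_params > 200:
                # normal equations: X is tall and well-conditioned at this
                # parameter count, and the direct solve is ~10x faster
                G = X.T @ X
                b = X.T @ y
                try:
                    theta = _solve(G, b, assume_a="pos")
                except np.linalg.LinAlgError:
                    theta, *_ = _lstsq(G, b)
            else:
                theta, *_ = _lstsq(X, y, lapack_driver="gelsy")
            thetas.append(theta)
        if not thetas:
            raise ValueError("no segment had enough usable rows to fit")
        return np.mean(thetas, axis=0), len(thetas)


# ---------------------------------------------------------------------------
# Position-independent model


class PositionIndependentModel(BaseEstimator):
    """Order-N position-independent sequence-energy model.

    E_i = offset + sum over word lengths n <= N of m^i_word * eps_word, with
    word counts taken in the site interior and word energies constrained to
    zero marginal sums.  Fitted per genome segment by constrained least
    squares; word energies are averaged across segments.

    Parameters
    ----------
    N : word order (only 1 and 2 supported; the analysis uses N=2).
    footprint : nucleosome length in bp.
    terminal_exclusion : bps excluded from each end of the site.
    n_segments : number of equal-size genome segments fitted separately.
    """

    def __init__(self, N: int = 2, footprint: int = 147,
                 terminal_exclusion: int = 3, n_segments: int = 8):
        self.N = N
        self.footprint = footprint
        self.terminal_exclusion = terminal_exclusion
        self.n_segments = n_segments

    def _n_params(self) -> int:
        return count_free_parameters("position_independent", self.footprint,
                                     self.terminal_exclusion, self.N)

    def _reduced_design(self, mono: np.ndarray, dinuc: np.ndarray) -> np.ndarray:
        cols = [np.ones((len(mono), 1))]
        cols.append(mono @ _C4)
        if self.N >= 2:
            cols.append(dinuc @ _K16)
        return np.hstack(cols)

    def fit(self, genome: GenomeAssembly, energy: EnergyProfile,
            mask: Optional[FilterMask] = None) -> "PositionIndependentModel":
        """Fit word energies to an inverted energy profile.

        ``mask`` is accepted for interface symmetry; masked positions are
        normally already undefined in ``energy`` (the inversion flags them).
        """
        if self.N not in (1, 2):
            raise ValueError("only N in {1, 2} is supported")
        t = self.terminal_exclusion
        fit = _SegmentedLinearFit(self._n_params())
        seg_of = _genome_segments(genome, self.n_segments)
        for chrom in energy.chroms():
            starts, y = _usable_rows(genome, chrom, energy, self.footprint, t)
            if mask is not None and chrom in mask.data:
                mbad = np.cumsum(np.concatenate(
                    [[0], mask[chrom].astype(np.int64)]))
                keep = (mbad[starts + self.footprint] - mbad[starts]) == 0
                starts, y = starts[keep], y[keep]
            if len(starts) == 0:
                continue
            mono, dinuc, _ = _sliding_blocks(genome.codes(chrom),
                                             self.footprint, t)
            X = self._reduced_design(mono[starts], dinuc[starts])
            fit.add(seg_of(chrom, starts), X, y)
        theta, self.n_segments_used_ = fit.solve()
        self.offset_ = float(theta[0])
        self.mono_energies_ = _C4 @ theta[1:4]
        if self.N >= 2:
            self.dinuc_energies_ = _K16 @ theta[4:13]
        else:
            self.dinuc_energies_ = np.zeros(16)
        self.residual_variance_ = self._residual_variance(genome, energy)
        return self

    def _residual_variance(self, genome: GenomeAssembly,
                           energy: EnergyProfile) -> float:
        pred = self.predict(genome)
        res = []
        for chrom in energy.chroms():
            d = energy.defined[chrom] & pred.defined[chrom]
            res.append(energy.E[chrom][d] - pred.E[chrom][d])
        r = np.concatenate(res)
        return float(r.var()) if len(r) else float("nan")

    def effective_dinucleotide_energies(self) -> np.ndarray:
        """Per-dinucleotide contribution to the total site energy (16,).

        eps_ab + (eps_a + eps_b)/2: each interior base is shared by the two
        dinucleotides containing it, so half of its mononucleotide energy is
        attributed to each.  This is the quantity whose ranking is tabulated
        when models are compared (G/C most favorable in vitro, etc.).
        """
        check_is_fitted(self, "offset_")
        mono = self.mono_energies_
        pair_mono = (mono[:, None] + mono[None, :]).ravel() / 2.0
        return self.dinuc_energies_ + pair_mono

    def word_energies(self) -> Dict[str, float]:
        """Fitted energies keyed by word string (kBT per occurrence)."""
        check_is_fitted(self, "offset_")
        out = {b: float(e) for b, e in zip(BASES, self.mono_energies_)}
        out.update({w: float(e) for w, e in zip(DINUCLEOTIDES,
                                                self.dinuc_energies_)})
        return out

    def predict(self, genome: GenomeAssembly) -> EnergyProfile:
        """Score every admissible start; positions with N bases are undefined."""
        check_is_fitted(self, "offset_")
        t = self.terminal_exclusion
        E, defined = {}, {}
        for chrom in genome:
            mono, dinuc, usable = _sliding_blocks(genome.codes(chrom),
                                                  self.footprint, t)
            e = self.offset_ + mono @ self.mono_energies_
            if self.N >= 2:
                e = e + dinuc @ self.dinuc_energies_
            E[chrom] = np.where(usable, e, np.nan)
            defined[chrom] = usable
        return EnergyProfile(E, 0.0, self.footprint, defined)


# ---------------------------------------------------------------------------
# Spatially resolved model


class SpatiallyResolvedModel(BaseEstimator):
    """Position-specific mono- and dinucleotide sequence-energy model.

    A separate energy is fitted for every base at every interior position and
    for every dinucleotide at every interior start, each position constrained
    to a zero energy sum.  Fitting uses a random subset of fixed-size genome
    segments (the full genome is computationally out of reach at this
    parameter count), and the predicted energies can be affinely rescaled per
    chromosome to restore the dynamic range of the training energies.

    Parameters
    ----------
    segment_size : genomic segment length in bp; None divides the genome into
        ``total_segments`` equal parts.
    n_fit_segments : number of randomly chosen segments actually fitted.
    total_segments : partition granularity used when segment_size is None.
    variance_rescale : match per-chromosome mean/variance of predictions to
        the training energies.
    random_state : seed for the segment draw.
    """

    def __init__(self, footprint: int = 147, terminal_exclusion: int = 3,
                 segment_size: Optional[int] = None, n_fit_segments: int = 40,
                 total_segments: int = 405, variance_rescale: bool = True,
                 random_state: Optional[int] = 0):
        self.footprint = footprint
        self.terminal_exclusion = terminal_exclusion
        self.segment_size = segment_size
        self.n_fit_segments = n_fit_segments
        self.total_segments = total_segments
        self.variance_rescale = variance_rescale
        self.random_state = random_state

    def _n_params(self) -> int:
        return count_free_parameters("spatially_resolved", self.footprint,
                                     self.terminal_exclusion)

    def _offsets(self):
        t = self.terminal_exclusion
        mono_off = np.arange(t, self.footprint - t)
        di_off = np.arange(t, self.footprint - t - 1)
        return mono_off, di_off

    def _design(self, codes: np.ndarray, starts: np.ndarray) -> np.ndarray:
        mono_off, di_off = self._offsets()
        R = len(starts)
        cm = _window_codes(codes, starts, mono_off)
        dm_first = _window_codes(codes, starts, di_off)
        dm_second = _window_codes(codes, starts, di_off + 1)
        dcodes = 4 * dm_first.astype(np.int32) + dm_second
        X = np.empty((R, self._n_params()))
        X[:, 0] = 1.0
        nm = len(mono_off)
        X[:, 1:1 + 3 * nm] = _C4[cm].reshape(R, 3 * nm)
        X[:, 1 + 3 * nm:] = _K16[dcodes].reshape(R, 9 * len(di_off))
        return X

    def fit(self, genome: GenomeAssembly, energy: EnergyProfile,
            mask: Optional[FilterMask] = None) -> "SpatiallyResolvedModel":
        t = self.terminal_exclusion
        total = genome.total_length
        seg_size = self.segment_size
        if seg_size is None:
            seg_size = max(1, total // self.total_segments)
        n_total = -(-total // seg_size)
        rng = np.random.default_rng(self.random_state)
        chosen = set(rng.choice(n_total, size=min(self.n_fit_segments, n_total),
                                replace=False).tolist())

        offsets = {}
        off = 0
        for c in genome:
            offsets[c] = off
            off += len(genome.sequences[c])

        fit = _SegmentedLinearFit(self._n_params())
        train_stats: Dict[str, Tuple[float, float]] = {}
        for chrom in energy.chroms():
            starts, y = _usable_rows(genome, chrom, energy, self.footprint, t)
            if mask is not None and chrom in mask.data:
                mbad = np.cumsum(np.concatenate(
                    [[0], mask[chrom].astype(np.int64)]))
                keep = (mbad[starts + self.footprint] - mbad[starts]) == 0
                starts, y = starts[keep], y[keep]
            if len(starts) == 0:
                continue
            train_stats[chrom] = (float(y.mean()), float(y.var()))
            segs = (offsets[chrom] + starts) // seg_size
            sel = np.isin(segs, list(chosen))
            if not sel.any():
                continue
            codes = genome.codes(chrom)
            for s in np.unique(segs[sel]):
                pick = starts[segs == s]
                X = self._design(codes, pick)
                fit.add(np.full(len(pick), s), X, y[segs == s])
        theta, self.n_segments_used_ = fit.solve()
        mono_off, di_off = self._offsets()
        nm = len(mono_off)
        self.offset_ = float(theta[0])
        self.mono_energies_ = (_C4 @ theta[1:1 + 3 * nm].reshape(nm, 3).T).T
        self.dinuc_energies_ = (_K16 @ theta[1 + 3 * nm:]
                                .reshape(len(di_off), 9).T).T
        self.train_stats_ = train_stats
        return self

    def position_averaged_dinuc_energies(self) -> np.ndarray:
        """Dinucleotide energies averaged over interior positions (16,)."""
        check_is_fitted(self, "offset_")
        return self.dinuc_energies_.mean(axis=0)

    def predict(self, genome: GenomeAssembly,
                chunk: int = 200_000) -> EnergyProfile:
        check_is_fitted(self, "offset_")
        t = self.terminal_exclusion
        mono_off, di_off = self._offsets()
        E, defined = {}, {}
        for chrom in genome:
            codes = genome.codes(chrom)
            L = len(codes)
            n = L - self.footprint + 1
            if n < 1:
                E[chrom] = np.empty(0)
                defined[chrom] = np.empty(0, dtype=bool)
                continue
            e = np.full(n, np.nan)
            nbad = np.cumsum(np.concatenate([[0], (codes < 0).astype(np.int64)]))
            idx = np.arange(n)
            usable = (nbad[idx + self.footprint - t] - nbad[idx + t]) == 0
            ustarts = idx[usable]
            for lo in range(0, len(ustarts), chunk):
                st = ustarts[lo:lo + chunk]
                cm = _window_codes(codes, st, mono_off)
                v = np.full(len(st), self.offset_)
                v += self.mono_energies_[np.arange(len(mono_off))[None, :],
                                         cm].sum(axis=1)
                dfirst = _window_codes(codes, st, di_off)
                dsecond = _window_codes(codes, st, di_off + 1)
                dc = 4 * dfirst.astype(np.int32) + dsecond
                v += self.dinuc_energies_[np.arange(len(di_off))[None, :],
                                          dc].sum(axis=1)
                e[st] = v
            if self.variance_rescale and chrom in getattr(self, "train_stats_", {}):
                m_tr, v_tr = self.train_stats_[chrom]
                vals = e[usable]
                sd = vals.std()
                if sd > 0 and v_tr > 0:
                    e[usable] = m_tr + (vals - vals.mean()) * np.sqrt(v_tr) / sd
            E[chrom] = e
            defined[chrom] = usable
        return EnergyProfile(E, 0.0, self.footprint, defined)


# ---------------------------------------------------------------------------
# Bioinformatics (dinucleotide scoring) model


class BioinformaticsModel(BaseEstimator):
    """Dinucleotide positioning model scored from raw read coverage.

    For each dinucleotide w, mu_w is the reciprocal of the coverage-weighted
    average occurrence rate over all sites containing w; scores are
    normalized to P_w = mu_w / sum(mu) and the site energy is the sum of
    ln P_w over interior dinucleotide starts.
    """

    def __init__(self, footprint: int = 147, terminal_exclusion: int = 3):
        self.footprint = footprint
        self.terminal_exclusion = terminal_exclusion

    def fit(self, genome: GenomeAssembly, coverage: Dict[str, np.ndarray],
            mask: Optional[FilterMask] = None) -> "BioinformaticsModel":
        """Fit scores from un-normalized per-bp read coverage."""
        t = self.terminal_exclusion
        num = np.zeros(16)
        den = np.zeros(16)
        for chrom in genome:
            codes = genome.codes(chrom)
            n = len(codes) - self.footprint + 1
            if n < 1:
                continue
            if chrom not in coverage:
                continue
            O = np.asarray(coverage[chrom], dtype=float)[:n]
            if (O < 0).any():
                raise ValueError("coverage must be non-negative")
            mono, dinuc, usable = _sliding_blocks(codes, self.footprint, t)
            keep = usable
            if mask is not None and chrom in mask.data:
                mbad = np.cumsum(np.concatenate(
                    [[0], mask[chrom].astype(np.int64)]))
                idx = np.arange(n)
                keep = keep & ((mbad[idx + self.footprint] - mbad[idx]) == 0)
            m = dinuc[keep].astype(float)
            num += m.T @ O[keep]
            den += m.sum(axis=0)
        if (den == 0).any():
            missing = [w for w, d in zip(DINUCLEOTIDES, den) if d == 0]
            raise ValueError(f"dinucleotides absent genome-wide: {missing}")
        if (num == 0).any():
            raise ValueError("zero weighted coverage for some dinucleotide; "
                             "mu_w undefined")
        self.mu_w_ = den / num          # reciprocal weighted average
        self.P_w_ = self.mu_w_ / self.mu_w_.sum()
        return self

    def scores(self) -> Dict[str, float]:
        check_is_fitted(self, "P_w_")
        return {w: float(p) for w, p in zip(DINUCLEOTIDES, self.P_w_)}

    def predict(self, genome: GenomeAssembly) -> EnergyProfile:
        """E_i = sum of ln P_w over interior dinucleotide starts of site i."""
        check_is_fitted(self, "P_w_")
        t = self.terminal_exclusion
        logp = np.log(self.P_w_)
        E, defined = {}, {}
        for chrom in genome:
            mono, dinuc, usable = _sliding_blocks(genome.codes(chrom),
                                                  self.footprint, t)
            e = dinuc @ logp
            E[chrom] = np.where(usable, e, np.nan)
            defined[chrom] = usable
        return EnergyProfile(E, 0.0, self.footprint, defined)


# ---------------------------------------------------------------------------
# Thin functional wrappers


def fit_position_independent(energy: EnergyProfile, genome: GenomeAssembly,
                             mask: Optional[FilterMask] = None, N: int = 2,
                             n_segments: int = 8) -> PositionIndependentModel:
    return PositionIndependentModel(
        N=N, footprint=energy.footprint, n_segments=n_segments,
    ).fit(genome, energy, mask)


def fit_spatially_resolved(energy: EnergyProfile, genome: GenomeAssembly,
                           mask: Optional[FilterMask] = None,
                           **kwargs) -> SpatiallyResolvedModel:
    return SpatiallyResolvedModel(
        footprint=energy.footprint, **kwargs,
    ).fit(genome, energy, mask)


def fit_bioinformatics(coverage: Dict[str, np.ndarray], genome: GenomeAssembly,
                       mask: Optional[FilterMask] = None,
                       footprint: int = 147) -> BioinformaticsModel:
    return BioinformaticsModel(footprint=footprint).fit(genome, coverage, mask)


def predict_occupancy_from_model(model, genome: GenomeAssembly,
                                 params: ThermoParams) -> OccupancyPair:
    """Score the genome with a fitted model and convert to equilibrium (P, O)."""
    return equilibrium_predict(model.predict(genome), params)
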