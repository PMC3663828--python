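"""Convenience chains over the standard pre-processing and inversion steps."""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from .energetics import EnergyProfile, ThermoParams, invert_energy
from .genome import GenomeAssembly
from .profiles import (FilterMask, OccupancyPair, ReadStartProfile,
                       SmoothingParams, coverage_from_starts, cutsite_filter,
                       gap_filter, gaussian_smooth, high_coverage_filter,
                       normalize_to_probability, reads_to_start_profile)

__all__ = ["preprocess_reads", "invert_from_reads"]


def preprocess_reads(reads, genome: GenomeAssembly, sigma: float = 20.0,
                     footprint: int = 147, min_gap: int = 1000,
                     cutsite_pattern: Optional[str] = None,
                     cutsite_flank: int = 200,
                     ) -> Tuple[ReadStartProfile, FilterMask, OccupancyPair]:
    """Standard read pre-processing chain.

    Builds the start profile, applies the gap and high-coverage filters (plus
    the cut-site filter when a restriction pattern is given), smooths with a
    Gaussian of width ``sigma``, and normalizes to a probability/occupancy
    pair.  Filters are constructed on the raw profile; smoothing is applied
    to the full profile and masks matter only for normalization and fitting.
    """
    profile = reads_to_start_profile(reads, genome, footprint)
    mask = gap_filter(profile, min_gap)
    coverage = {c: coverage_from_starts(profile.data[c], footprint)
                for c in profile.data}
    mask = mask | high_coverage_filter(coverage,
                                       upstream_extension=footprint - 1)
    if cutsite_pattern is not None:
        mask = mask | cutsite_filter(genome, cutsite_pattern, cutsite_flank)
    smoothed = gaussian_smooth(profile, SmoothingParams(sigma))
    pair = normalize_to_probability(smoothed, mask, footprint)
    return profile, mask, pair


def invert_from_reads(reads, genome: GenomeAssembly, sigma: float = 20.0,
                      footprint: int = 147, mu: float = 0.0, **kwargs
                      ) -> Tuple[EnergyProfile, FilterMask, OccupancyPair]:
    """Pre-process reads and invert to per-start energies (kBT, given mu)."""
    _, mask, pair = preprocess_reads(reads, genome, sigma, footprint, **kwargs)
    energy = invert_energy(pair, ThermoParams(mu, footprint), mask)
    return energy, mask, pair
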