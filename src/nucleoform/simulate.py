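"""Synthetic genomes, reads, annotations and expression data.

The generator emulates the statistical structure the analysis assumes:

* a multi-chromosome genome sampled from a first-order Markov chain over the
  strong (G/C) / weak (A/T) base classes, whose stationary dinucleotide group
  frequencies interpolate between arm and center targets (the center-vs-arm
  composition gradient seen in nematode autosomes);
* reads sampled from the exact equilibrium of a hard-rod lattice with a known
  position-independent dinucleotide energy model, with MNase-style positional
  jitter, Bernoulli strand assignment, optional sequence-independent regional
  coverage modulation (arm depletion), optional sequence-coupled modulation
  penalizing G/C-rich sites (a remodeler-action proxy), and optional
  restriction-cut-site read enrichment;
* gene models with exon/intron structures honoring the analysis constraints
  (introns >= 125 bp, internal exons 50-500 bp) and embedded splice-site
  consensus with controllable degeneracy;
* per-gene expression tag counts (log-normal, with a zero-inflated fraction).

Every output is a deterministic function of the configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from numba import njit

from .energetics import EnergyProfile, ThermoParams, calibrate_mu, \
    equilibrium_predict
from .features import GeneModel
from .genome import GenomeAssembly

__all__ = [
    "SimulationConfig",
    "smoke_config",
    "study_config",
    "default_dinucleotide_energies",
    "default_mononucleotide_energies",
    "generate_genome",
    "true_energy_profile",
    "sample_reads",
    "generate_genes",
    "make_fixture_bundle",
]

#: Splice-site consensus strings (transcript orientation).
DONOR_CONSENSUS = "CAGGTAAGTT"            # 3 exonic + 7 intronic
ACCEPTOR_CONSENSUS = "TTTTTTTTTTTTTTTTTTTTTTACAGGTT"  # 26 intronic + 3 exonic


def default_mononucleotide_energies() -> np.ndarray:
    """Intrinsic base energies (kBT per interior base), zero-sum.

    G and C favorable, A and T unfavorable — the in-vitro ranking in which
    G/C-rich sequence promotes nucleosome formation.
    """
    return np.array([0.12, -0.12, -0.12, 0.12])  # A, C, G, T


def default_dinucleotide_energies() -> np.ndarray:
    """Intrinsic dinucleotide energies (kBT per occurrence), 16-vector.

    A fixed, well-spread set (magnitudes up to ~0.06 kBT, the scale of
    fitted dinucleotide energies in published maps) projected exactly onto
    the zero-marginal-sum constraint space.
    """
    raw = np.array([
        [0.050, -0.010, 0.020, 0.060],    # AA AC AG AT
        [0.010, -0.055, -0.040, 0.030],   # CA CC CG CT
        [-0.020, -0.030, -0.060, 0.015],  # GA GC GG GT
        [0.040, 0.005, -0.025, 0.045],    # TA TC TG TT
    ])
    raw = raw - raw.mean(axis=1, keepdims=True)
    raw = raw - raw.mean(axis=0, keepdims=True)
    return raw.ravel()


@dataclass
class SimulationConfig:
    """Full specification of one synthetic dataset (seed-deterministic)."""

    seed: int = 0
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chrI": 1_000_000, "chrII": 1_000_000})
    footprint: int = 147
    terminal_exclusion: int = 3
    # true sequence-energy model (position-independent form)
    mono_energies: np.ndarray = field(
        default_factory=default_mononucleotide_energies)
    dinuc_energies: np.ndarray = field(
        default_factory=default_dinucleotide_energies)
    target_mean_occupancy: float = 0.75
    # read sampling
    n_reads: int = 200_000
    read_length: int = 36
    strand_prob: float = 0.5
    jitter_sd: float = 2.0
    # coverage modulation
    arm_depletion: float = 0.0      # 0 = off; 0.5 halves coverage at arms
    gc_coupling: float = 0.0        # lambda: E += lambda * site GC fraction
    # composition gradient: (AT, GC, mixed) dinucleotide group targets
    comp_arm: Tuple[float, float, float] = (0.45, 0.13, 0.42)
    comp_center: Tuple[float, float, float] = (0.39, 0.13, 0.48)
    # restriction cut sites
    cut_site_pattern: Optional[str] = None
    cut_enrichment: float = 3.0
    cut_enrichment_flank: int = 50
    # gene generation
    n_genes: int = 30
    exons_per_gene: Tuple[int, int] = (3, 7)
    exon_length: Tuple[int, int] = (60, 400)
    intron_length: Tuple[int, int] = (130, 400)
    consensus_degeneracy: float = 0.1
    # expression (log-normal tag counts)
    expr_log_mean: float = 2.0
    expr_log_sd: float = 1.5
    expr_zero_fraction: float = 0.1

    def __post_init__(self) -> None:
        self.mono_energies = np.asarray(self.mono_energies, dtype=float)
        self.dinuc_energies = np.asarray(self.dinuc_energies, dtype=float)
        for comp in (self.comp_arm, self.comp_center):
            if abs(sum(comp) - 1.0) > 1e-9:
                raise ValueError("composition targets must sum to 1")
            if any(c < 0 or c > 1 for c in comp):
                raise ValueError("composition targets must lie in [0, 1]")
        if not 0.0 <= self.strand_prob <= 1.0:
            raise ValueError("strand probability must lie in [0, 1]")

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["mono_energies"] = [float(x) for x in self.mono_energies]
        d["dinuc_energies"] = [float(x) for x in self.dinuc_energies]
        d["chrom_lengths"] = dict(self.chrom_lengths)
        for key in ("exons_per_gene", "exon_length", "intron_length",
                    "comp_arm", "comp_center"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("exons_per_gene", "exon_length", "intron_length",
                    "comp_arm", "comp_center"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def smoke_config(seed: int = 0) -> SimulationConfig:
    """A small configuration that runs the full pipeline in well under a minute."""
    return SimulationConfig(
        seed=seed,
        chrom_lengths={"chrI": 150_000, "chrII": 150_000},
        n_reads=30_000,
        n_genes=12,
    )


def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The reference study-scale conditions: 2 Mb genome, 200k reads."""
    return SimulationConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Genome generation


@njit(cache=True)
def _class_chain(p_ss: np.ndarray, p_ww: np.ndarray, pi_s0: float,
                 u: np.ndarray) -> np.ndarray:
    """Two-state (W=0, S=1) Markov chain with position-dependent transitions."""
    L = len(u)
    out = np.empty(L, dtype=np.int8)
    out[0] = 1 if u[0] < pi_s0 else 0
    for i in range(1, L):
        if out[i - 1] == 1:
            out[i] = 1 if u[i] < p_ss[i] else 0
        else:
            out[i] = 0 if u[i] < p_ww[i] else 1
    return out


def _gradient_targets(L: int, arm: Tuple[float, float, float],
                      center: Tuple[float, float, float]):
    """Per-bp (AT, GC, mixed) targets: sinusoidal dome from arm to center."""
    x = (np.arange(L) + 0.5) / L
    shape = np.sin(np.pi * x)
    a = np.asarray(arm)
    c = np.asarray(center)
    return a[None, :] + (c - a)[None, :] * shape[:, None]


def generate_genome(config: SimulationConfig) -> GenomeAssembly:
    """Sample a genome whose local dinucleotide group composition follows
    the configured arm-to-center gradient."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    seqs = {}
    base_w = np.array(list("AT"))
    base_s = np.array(list("CG"))
    for chrom, L in config.chrom_lengths.items():
        t = _gradient_targets(L, config.comp_arm, config.comp_center)
        at, gc, mx = t[:, 0], t[:, 1], t[:, 2]
        pi_s = gc + mx / 2.0
        pi_w = at + mx / 2.0
        p_ss = gc / pi_s
        p_ww = at / pi_w
        u = rng.random(L)
        cls = _class_chain(p_ss, p_ww, float(pi_s[0]), u)
        pick = rng.integers(0, 2, size=L)
        chars = np.where(cls == 1, base_s[pick], base_w[pick])
        seqs[chrom] = "".join(chars)
    return GenomeAssembly(seqs)


# ---------------------------------------------------------------------------
# Equilibrium read sampling


def true_energy_profile(genome: GenomeAssembly,
                        config: SimulationConfig) -> EnergyProfile:
    """Ground-truth per-start energies implied by the configured model.

    E_i = mono/dinuc word-count energies of the site interior, plus the
    optional sequence-coupled term gc_coupling * (site GC fraction).
    """
    from .seqmodels import _sliding_blocks  # deferred: avoid import cycle

    E, defined = {}, {}
    f, t = config.footprint, config.terminal_exclusion
    for chrom in genome:
        mono, dinuc, usable = _sliding_blocks(genome.codes(chrom), f, t)
        e = mono @ config.mono_energies + dinuc @ config.dinuc_energies
        if config.gc_coupling != 0.0:
            gc_frac = (mono[:, 1] + mono[:, 2]) / mono.sum(axis=1).clip(min=1)
            e = e + config.gc_coupling * gc_frac
        E[chrom] = np.where(usable, e, np.nan)
        defined[chrom] = usable
    return EnergyProfile(E, 0.0, f, defined)


def _regional_modulation(L: int, amplitude: float) -> np.ndarray:
    """Smooth arms-depleted coverage factor g(x): 1 at center, 1-amp at ends."""
    if amplitude == 0.0:
        return np.ones(L)
    x = (np.arange(L) + 0.5) / L
    return 1.0 - amplitude * np.cos(np.pi * x) ** 2


def sample_reads(genome: GenomeAssembly, config: SimulationConfig,
                 ) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Sample mapped reads from the equilibrium hard-rod model.

    Start positions are drawn multinomially with probabilities proportional
    to the equilibrium start probability times the regional modulation (and
    the near-cut-site enrichment if configured); Gaussian positional jitter
    and Bernoulli strand assignment follow.  Returns the read table and a
    truth record (energies, chemical potential, start probabilities).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    energy = true_energy_profile(genome, config)
    params = calibrate_mu(energy, config.target_mean_occupancy)
    pair = equilibrium_predict(energy, params)

    probs, keys = [], []
    for chrom in genome:
        L = len(genome.sequences[chrom])
        n = L - config.footprint + 1
        p = pair.P[chrom][:n].copy()
        g = _regional_modulation(L, config.arm_depletion)[:n]
        p *= g
        if config.cut_site_pattern:
            boost = np.ones(n)
            for s, e in genome.find_pattern(chrom, config.cut_site_pattern):
                lo = max(0, s - config.cut_enrichment_flank)
                hi = min(n, e + config.cut_enrichment_flank)
                boost[lo:hi] = config.cut_enrichment
            p *= boost
        probs.append(p)
        keys.append(chrom)
    flat = np.concatenate(probs)
    flat /= flat.sum()
    counts = rng.multinomial(config.n_reads, flat)

    rows = []
    off = 0
    for chrom, p in zip(keys, probs):
        n = len(p)
        c = counts[off:off + n]
        off += n
        starts = np.repeat(np.arange(n), c)
        if len(starts) == 0:
            continue
        if config.jitter_sd > 0:
            starts = starts + np.rint(
                rng.normal(0.0, config.jitter_sd, len(starts))).astype(np.int64)
        L = len(genome.sequences[chrom])
        starts = np.clip(starts, 0, L - config.footprint)
        fwd = rng.random(len(starts)) < config.strand_prob
        rl = config.read_length
        r_start = np.where(fwd, starts, starts + config.footprint - rl)
        r_end = np.where(fwd, starts + rl, starts + config.footprint)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": r_start, "end": r_end,
            "strand": np.where(fwd, "+", "-"), "weight": 1.0}))
    reads = pd.concat(rows, ignore_index=True)
    truth = {"energy": energy, "mu": params.mu, "pair": pair,
             "mono_energies": config.mono_energies.copy(),
             "dinuc_energies": config.dinuc_energies.copy()}
    return reads, truth


# ---------------------------------------------------------------------------
# Gene generation


def _mutate(seq: str, degeneracy: float, rng) -> str:
    if degeneracy <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < degeneracy:
            chars[i] = "ACGT"[rng.integers(0, 4)]
    return "".join(chars)


def generate_genes(genome: GenomeAssembly, config: SimulationConfig,
                   ) -> Tuple[List[GeneModel], GenomeAssembly]:
    """Place non-overlapping genes and embed splice-site consensus.

    Returns the gene models plus a genome copy in which donor/acceptor
    consensus strings (mutated with the configured degeneracy) replace the
    sequence at every internal splice junction.  Expression tag counts are
    log-normal with a zero-inflated fraction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    chroms = list(genome)
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    genes: List[GeneModel] = []
    edits: Dict[str, List[Tuple[int, str]]] = {c: [] for c in chroms}

    n_placed = 0
    attempts = 0
    while n_placed < config.n_genes:
        attempts += 1
        if attempts > 200 * config.n_genes:
            raise ValueError("genome too short for the requested gene count")
        chrom = chroms[rng.integers(0, len(chroms))]
        L = len(genome.sequences[chrom])
        n_ex = int(rng.integers(config.exons_per_gene[0],
                                config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_length[0],
                               config.exon_length[1] + 1, n_ex)
        in_lens = rng.integers(config.intron_length[0],
                               config.intron_length[1] + 1, max(n_ex - 1, 0))
        span = int(ex_lens.sum() + in_lens.sum())
        if span + 200 >= L:
            continue
        start = int(rng.integers(100, L - span - 100))
        interval = (start - 50, start + span + 50)
        if any(not (interval[1] <= s or e <= interval[0])
               for s, e in occupied[chrom]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = start
        for k in range(n_ex):
            exons.append((pos, pos + int(ex_lens[k])))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(in_lens[k])
        gid = f"gene{n_placed + 1:04d}"
        if rng.random() < config.expr_zero_fraction:
            expr = 0.0
        else:
            expr = float(np.rint(rng.lognormal(config.expr_log_mean,
                                               config.expr_log_sd)))
        g = GeneModel(gid, chrom, strand, exons, expression=expr)
        genes.append(g)
        occupied[chrom].append(interval)
        n_placed += 1

        # embed splice consensus at internal junctions (transcript orientation)
        from .genome import reverse_complement
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if strand == "+":
                donor = _mutate(DONOR_CONSENSUS, config.consensus_degeneracy, rng)
                edits[chrom].append((e1 - 3, donor))
                acc = _mutate(ACCEPTOR_CONSENSUS, config.consensus_degeneracy, rng)
                edits[chrom].append((s2 - 26, acc))
            else:
                # transcript-upstream exon is the genomic-right one: its donor
                # window spans [s2 - 7, s2 + 3) on the forward strand
                donor = _mutate(DONOR_CONSENSUS, config.consensus_degeneracy, rng)
                edits[chrom].append((s2 - 7, reverse_complement(donor)))
                acc = _mutate(ACCEPTOR_CONSENSUS, config.consensus_degeneracy, rng)
                edits[chrom].append((e1 - 3, reverse_complement(acc)))

    new_seqs = {}
    for chrom in chroms:
        if not edits[chrom]:
            continue
        buf = bytearray(genome.sequences[chrom], "ascii")
        for pos, s in edits[chrom]:
            buf[pos:pos + len(s)] = s.encode("ascii")
        new_seqs[chrom] = buf.decode("ascii")
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes, genome.with_sequences(new_seqs)


# ---------------------------------------------------------------------------
# Fixture bundle


def make_fixture_bundle(config: SimulationConfig, out_dir: str) -> Dict[str, str]:
    """Write a complete synthetic dataset plus ground-truth tables to disk.

    Emits FASTA (genome with embedded splice sites), BED6 (reads), GFF3
    (genes), TSV (expression tags), the true word-energy table, and a
    manifest recording the configuration and file paths.
    """
    from . import io as nio

    os.makedirs(out_dir, exist_ok=True)
    genome = generate_genome(config)
    genes, genome = generate_genes(genome, config)
    reads, truth = sample_reads(genome, config)

    paths = {
        "config": os.path.join(out_dir, "config.yaml"),
        "fasta": os.path.join(out_dir, "genome.fa"),
        "reads": os.path.join(out_dir, "reads.bed"),
        "gff3": os.path.join(out_dir, "genes.gff3"),
        "expression": os.path.join(out_dir, "expression.tsv"),
        "truth_model": os.path.join(out_dir, "truth_word_energies.tsv"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    config.to_yaml(paths["config"])
    nio.write_fasta(genome, paths["fasta"])
    nio.write_bed_reads(reads, paths["reads"])
    nio.write_gff3(genes, paths["gff3"])
    nio.write_tag_counts({g.gene_id: g.expression or 0.0 for g in genes},
                         paths["expression"])

    from .seqmodels import BASES, DINUCLEOTIDES
    rows = [("offset", 0.0)]
    rows += list(zip(BASES, truth["mono_energies"]))
    rows += list(zip(DINUCLEOTIDES, truth["dinuc_energies"]))
    pd.DataFrame(rows, columns=["word", "energy"]).to_csv(
        paths["truth_model"], sep="\t", index=False, float_format="%.17g")

    manifest = {"seed": config.seed, "mu": truth["mu"],
                "n_reads": int(config.n_reads),
                "paths": {k: os.path.basename(v) for k, v in paths.items()}}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
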