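# Methods

## The hard-rod lattice model

The genome is a 1-D lattice of L bps; a nucleosome is a rod occupying `a`
consecutive bps (default 147, a parameter everywhere). A configuration is a
set of non-overlapping rod placements; a rod starting at bp i carries weight
`w_i = exp(-(E_i - mu)/kBT)` where E_i is the per-site formation energy, mu
the histone chemical potential, and kBT ≡ 1 internally (all energies are
reported in kBT units). The grand partition function factorizes into prefix
and suffix sums:

    F(i) = F(i-1) + w_{i-a+1} F(i-a),   F(-1) = 1
    B(i) = B(i+1) + w_i B(i+a),         B(j >= L) = 1
    P_i  = F(i-1) w_i B(i+a) / F(L-1)

Occupancy is the coverage convolution `O_i = sum_{j=i-a+1..i} P_j`. Both
recursions are evaluated in log space (numba kernels with an inlined
log-add-exp), so partition functions never overflow at genome scale; masked
or undefined starts get w = 0.

**Exact inversion.** The inverse map from (P, O) to energies is

    (E_i - mu)/kBT = log[(1 - O_i + P_i)/P_i]
                     + sum_{j=i}^{i+a-1} log[(1 - O_j)/(1 - O_j + P_j)]

with P_j taken as 0 beyond the last admissible start. The summation window
j ∈ [i, i+a-1] is a *derived* constant: it is the unique index range for
which inversion composed with the forward recursion is the identity, which
we verified analytically on one- and two-site lattices and numerically
against exhaustive enumeration (≤ 1e-12) and on 10-kb round trips
(≤ 1e-8 kBT). Positions where P_i = 0, where any O_j in the window reaches
1, or whose footprint window touches a filter mask are flagged undefined
rather than raising.

`brute_force_equilibrium` enumerates all rod configurations for L ≤ 30 and
is the independent oracle for the dynamic program in the tests.

**Chemical potential.** Mean occupancy is monotone increasing in mu, so
`calibrate_mu` brackets and bisects to hit a target genome-mean occupancy to
1e-6. When predicting occupancy from a fitted sequence model we calibrate mu
to the training data's mean (normalized) occupancy — the upstream
experimental analyses do not pin mu down, so matching the training density
is the natural closure.

## Profile pre-processing

Reads are extended to the footprint: a forward read contributes its weight
(1/M for M-fold multi-mappers) at its first base; a reverse read's last base
is the nucleosome end, so its start is `end - footprint`. Paired-end
fragments with span in [130, 200] place a dyad at the integer midpoint
`(start + end) // 2` (round half up; fixed for determinism) and the
nucleosome extends `footprint // 2` bases either way.

Filters: (i) read-free stretches ≥ 1000 bp; (ii) bps whose ±75 bp running
mean coverage exceeds 3× the chromosome mean, extended outward until the
running mean first drops to ≤ the mean (discrete profiles rarely hit
equality exactly, so "equals" is implemented as the first crossing), then
extended `footprint - 1` bp upstream so no admissible start overlapping the
region survives; (iii) ±200 bp around each IUPAC restriction-site match on
either strand. Masks are unions of boolean per-bp vectors; smoothing is
applied to the full profile and masks matter only when selecting positions
for normalization, fitting and statistics.

Smoothing replaces each start weight with a Gaussian centered on its bp
(σ = 20 for position-independent fitting, σ = 2 for spatially resolved
fitting — the 2-bp scale mirrors MNase positional imprecision). Kernels are
truncated at ±5σ and renormalized to unit area, so mass is conserved
exactly except at chromosome ends. Coverage is computed from the smoothed
starts, and both profiles are divided per chromosome by the maximum coverage
over unmasked bps; the results are interpreted as start probability and
occupancy. Normalized (z-scored) occupancy uses the population-σ convention
pooled over all chromosomes of a profile.

## Sequence-energy models

Words extending into the 3 terminal bps of the site are excluded
everywhere, leaving a 141-bp interior for a 147-bp footprint (141
mononucleotide positions, 140 dinucleotide starts). Counting is on the
forward strand for model fitting; dyad-aligned frequency *analyses* count
both strands.

* **Position-independent (order N)**: E_i = offset + Σ m_word ε_word with
  zero marginal sums on the word energies. The fit works in an explicit
  reduced basis — mononucleotide energies as C4·θ with C4 the 4×3
  sum-to-zero contrast matrix, dinucleotide energies as kron(C4, C4)·θ — so
  the constraints hold exactly by construction and the design has full
  column rank (13 parameters at N = 2, verified as a matrix rank). The
  genome is split into 8 equal segments fitted separately (the published
  practice is 6–8) and word energies are averaged across segments; segments
  with fewer than 10× parameter-count usable rows are skipped.
* **Spatially resolved**: separate mono- and dinucleotide energies per
  interior position, constrained per position (1684 parameters); the
  words-entirely-within-interior convention is applied uniformly, which is
  the convention that yields the 1684 count. The fit uses a random subset of
  fixed-size genome segments (seeded); on the 2 Mb synthetic bundle the
  default is 8 segments of 25 kb — the same ~10% genome fraction as the
  published 40-of-405 scheme, with segment size raised so each segment
  clears the 10×-parameters row minimum. Large-p solves use normal
  equations (Cholesky); the small PI design, whose mono/dinuc blocks are
  nearly collinear, uses a rank-revealing QR solve instead.
* **Variance rescaling**: averaging over segments shrinks the dynamic range
  of spatially resolved predictions, and an optional per-chromosome affine
  rescale restores it to the variance of the training energies. At desk
  scale (0.1 reads/bp, σ = 2) the training-energy variance is dominated by
  counting noise (~12 kBT² empirically vs ~2 kBT² of true signal), so the
  rescale inflates predictions and saturates predicted occupancy; the
  model-agreement analysis therefore runs with the rescale off. The flag is
  implemented and unit-tested either way.
* **Bioinformatics model**: for each dinucleotide w, μ_w is the reciprocal
  of the coverage-weighted mean occurrence rate over all sites containing w
  (raw, un-normalized coverage), P_w = μ_w/Σμ, and
  E_i = Σ ln P_w over the 140 interior dinucleotide starts — the same
  terminal-exclusion convention as the other models.

**Effective dinucleotide energies.** Published model comparisons rank
per-dinucleotide contributions to the total site energy. Under the
zero-marginal-sum constraints, additive base preferences live in the
mononucleotide terms, so the tabulated quantity is
`eps_ab + (eps_a + eps_b)/2` (each interior base is shared by two
dinucleotides). `PositionIndependentModel.effective_dinucleotide_energies`
exposes it; recovery and sign-flip analyses are stated in terms of it. The
constrained interaction energies alone are provably invariant to any energy
term that is linear in base composition (such as the remodeler proxy below)
and could not express the in vitro/in vivo contrast.

## Synthetic data: what it emulates, what it does not

The generator is the package's study-conditions module; all randomness
derives from one seed.

* **Genome**: a first-order Markov chain over strong (G/C) / weak (A/T)
  base classes whose stationary dinucleotide group frequencies interpolate
  sinusoidally between arm and center targets (defaults AT/GC/mixed =
  0.45/0.13/0.42 at arms, 0.39/0.13/0.48 at center — a worm-autosome-like
  ~35% GC with a center-enriched mixed fraction). Within a class, the two
  bases are equiprobable.
* **True energy model**: position-independent, with per-base energies
  ±0.12 kBT (G/C favorable) and a fixed, well-spread zero-sum dinucleotide
  interaction matrix with magnitudes up to ~0.06 kBT. This puts site-to-site
  energy spreads at 1–2 kBT and total sequence-driven variation within the
  few-kcal/mol range direct affinity measurements report.
* **Reads**: multinomial draws from the exact equilibrium start
  probabilities (mu calibrated to a target mean occupancy of 0.75), times a
  smooth sequence-independent modulation g(x) (arms-depleted dome) when
  enabled, times a near-cut-site enrichment factor when enabled. Rounded
  Gaussian jitter (SD 2 bp, the σ = 2 smoothing scale) emulates MNase
  imprecision; strands are Bernoulli(1/2) and reverse reads are emitted so
  that profile construction inverts them exactly.
* **Remodeler proxy**: an optional sequence-coupled term adds
  λ × (site GC fraction) to the true energy before sampling. λ = 40 makes
  the net true per-base G/C contribution (+0.16 kBT) about as unfavorable
  as A/T (+0.12), the strongest reported in vivo regime; smoothing
  soft-min-attenuates large-amplitude energy signals, so a λ chosen to
  merely cancel the intrinsic preference does not produce a fitted flip.
* **Genes and expression**: non-overlapping genes on both strands with
  exon/intron lengths honoring the 125 bp / 50–500 bp analysis constraints,
  donor (CAG|GTAAGTT) and acceptor (…ACAG|GTT) consensus embedded at every
  internal junction with configurable per-base mutation probability, and
  zero-inflated log-normal tag counts.

Not emulated: sequencing errors, PCR duplicates, mappability structure, and
any MNase *sequence* bias beyond positional jitter. Passing tests therefore
demonstrate correctness of the inference chain under the model's own
assumptions, not robustness to those artifacts on real libraries.

## Problem sizes and numerical choices

The end-to-end analyses run on a 2 Mb two-chromosome bundle with 200k reads
(0.1 reads/bp, the coverage class of the denser in vitro library), chosen so
the whole suite completes on a single CPU in minutes. At this scale the
effective dinucleotide ranking is recovered from sampled reads at Spearman
≈ 0.97–0.99, and PI- vs SR-predicted occupancy correlates at r ≈ 0.97.
Other fixed choices: Gaussian truncation ±5σ (renormalized); PWM
pseudocount 0.5 per base per position (avoids −∞ scores); GC tertiles split
ties by stable feature order; Welch's t-test for interval-group
comparisons; dyad = start + footprint//2; moving averages are centered and
shrink at boundaries; bisection tolerance 1e-6 on mean occupancy.

## Known limitations

* The inversion needs O < 1 over the whole footprint window; bps at or near
  the per-chromosome coverage maximum are undefined by construction.
* Per-chromosome max-coverage normalization sets the probability scale from
  an extreme statistic of a noisy profile; fitted energies are therefore
  determined up to a smooth monotone distortion of scale. Rankings and
  cross-model comparisons are insensitive to this; absolute kBT magnitudes
  shrink relative to truth at realistic coverage.
* The spatially resolved fit at desk scale is noise-limited per position;
  only coverage-scale (composition) structure is meaningfully constrained,
  which is why the variance rescale is off by default in the bundled
  comparison.
* Partial unwrapping, remodeler kinetics, and footprints other than a
  single fixed rod length per analysis are out of scope.
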