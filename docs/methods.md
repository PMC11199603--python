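# Methods

`genefold` has two halves: an analysis layer that quantifies how genes fold
in binned chromosome-contact data, and a biophysical model that couples
RNA Pol II traffic along a gene to the 3D dynamics of a lattice polymer.
This note records the models, the parameter choices, the numerical
decisions, and what the synthetic data do and do not emulate.

## Scores on contact maps

Contact matrices are distance-normalized per chromosome: the expected value
at genomic separation `d` is the mean of all valid pixels on that diagonal,
and the observed/expected (obs/exp) map divides each pixel by the expected
value at its separation.  Masked bins (unmappable regions) are excluded from
every numerator and denominator; a diagonal with no valid pixel propagates
as masked.  By construction the mean of each unmasked diagonal of the
obs/exp map is 1.

For a gene covering `N` matrix bins (bins fully contained in the gene body),

* `IC = sum_{i<j} c_ij / (N(N-1)/2)` — the mean obs/exp over intra-gene bin
  pairs, a dimensionless condensation score (diagonal excluded; pairs
  touching masked bins excluded from both sums);
* `IR = sum_i p_i / N` — the mean coverage-track signal (e.g. Pol II
  ChIP) over the gene's bins, base-pair weighted within bins.

Tracks are assumed already input-normalized; IR is the raw mean and log2 is
applied only when binning genes into clusters.  Because absolute IR depends
on how the source track was normalized, the integer log2(IR) cluster labels
are dataset-dependent.

Per gene, the analysis resolution is the coarsest available `r` satisfying
`gene length > 20 r`: the floor keeps at least ~20 bins across the gene
while the coarsest choice maximizes counts per pixel.  Genes shorter than
1 kb are dropped by default (resolution limitations of the data this
pipeline targets).  Gene strand never affects IC or IR (means are
orientation-invariant); it only orients meta-gene pileups.

Clusters are formed by integer-rounded log2(IR) and dyadic length intervals
(..., 32-64 kb, 64-128 kb, ...); clusters under 25 genes are flagged as
under-powered for map pileups.  Condition comparisons report per-gene log2
fold-changes of IC and IR and their Spearman correlation (average ranks on
ties; a constant fold-change vector makes the correlation undefined and is
flagged instead of silently returning a number).

## Pile-up meta-gene analysis (PMGA)

For each gene of `l` bins the `(3l) x (3l)` obs/exp block (gene body plus
equal flanks) is rescaled to 60 x 60 by area-weighted averaging: each
destination pixel is the mean of the source pixels it covers, with
fractional overlap weights, so the block mean is preserved exactly at
integer ratios and to rounding at non-integer ratios.  Masked source pixels
are excluded per destination pixel; a destination pixel is masked only when
all its contributors are (valid-count normalization, also used when
aggregating across genes).  Reverse-strand blocks are rotated 180 degrees so
the pileup is always in the transcription forward direction.  Upsampling is
refused — genes below the resolution floor never reach the pileup.

Inter-gene pileups take the off-diagonal `(3 l1) x (3 l2)` region centered
on the two gene midpoints, rescale each axis independently to 30 bins, and
flip each axis by its own gene's strand ("parallel forward" alignment).
Pairs default to midpoint separations of 128 kb to 2 Mb; pairs whose 3l
windows overlap or leave the matrix are skipped and logged.  Peak-pair
pileups average fixed windows centered on peak-center pixel pairs at 160 to
320 kb separation.  Coverage meta-genes split the 3l domain (in bp) into 60
equal pseudo-bins with base-pair-weighted coverage, rather than
nearest-bin sampling.

## Synthetic data

The generator implants known structure on a power-law background:
`contact(d) = (d/resolution + 1)^-decay_exponent` (exponent 1 by default — a
generic chromatin-like decay, close enough to exercise distance
normalization), multiplied by a factor field holding per-gene intra-body
enrichment `g >= 1`, TSS-TTS loop pixels, and TSS stripes.  Noise is
multiplicative lognormal, symmetrized by averaging the two triangles and
rescaled to unit mean so it adds variance without biasing the expectation.
Tracks are a plateau over the gene body with Gaussian TSS/TTS peaks
(reverse-strand genes peak at their genomic right edge) on a constant
background.  Coordinates are 0-based half-open in memory and on disk (BED);
GTF input is converted on read.

What passing round-trip tests show: the scoring and pileup stages recover
implanted enrichments, loops, stripes and track levels under controlled
noise.  What they do not show: robustness to read-level artifacts (ligation
noise, fragment-length bias), unbalanced matrices, compartment
checkerboards, or genome-scale gene-density patterns — none of which the
generator emulates.  One known systematic: the implanted gene inflates the
expected curve of its own chromosome, so recovered IC underestimates `g` by
roughly the gene's share of each diagonal; tests use genes small relative
to the chromosome (< ~5 % of bins) where this bias is under 5 %.

## Pol II traffic (TASEP)

A gene is `n` monomers with binary occupancy.  Each Monte Carlo step (MCS)
performs: one attempt to load at the TSS with rate `alpha` (site 1 empty and
promoter on), one attempt to unload at the TTS with rate `beta`, and `n-1`
elongation attempts, each picking a uniform random site in `[1, n-1]` and
moving its Pol II forward if the next site is free — the 1->2 hop uses the
initiation rate `gamma0` (default `gamma`), all others `gamma`.  Exclusion
is enforced by construction; Pol IIs never bypass.  The optional two-state
promoter switches with rates `k_on`/`k_off` after the elongation sweep, and
every loaded Pol II is tagged with its burst episode so "trains" (sets of
Pol IIs loaded in one on-period) can be counted.

Rates are per minute and converted to per-attempt probabilities as
`rate * dt`, with `dt` the MCS duration; `rate * dt` is capped at 0.1 to
bound time-discretization bias.  The default `dt` is 3 ms — the mobility
calibration described below — and one monomer is 2 kbp, so `gamma = 1/min`
is the biological ~2 kb/min elongation speed.  With `gamma0 = gamma` and
`beta = gamma - alpha` the stationary profile is uniform at
`rho = alpha/gamma` (checked against the exact stationary distribution of
the composite per-MCS Markov chain at small `n`, and against the printed
density series at `n = 50`).

The continuum mean-field steady state solves
`(2n)^-1 rho'' + (2 rho - 1) rho' = 0` with Dirichlet boundaries, here via a
collocation boundary-value solver; equal boundary values return the exact
constant solution.  The entrance boundary is `rho(0) = alpha/gamma` and the
exit boundary is taken as `rho(1) = 1 - beta/gamma` (the matched uniform
case is `beta = gamma - alpha`); the solver accepts general values in
[0, 1].  Derived bursting observables are closed-form:
`alpha_eff = alpha k_on/(k_on+k_off)`, burst frequency
`k_on k_off/(k_on+k_off)`, train size `alpha/k_off` (infinite as
`k_off -> 0`, flagged).

The unobstructed transit time is `1/gamma0 + (n-2)/gamma + 1/beta` (there
are `n-1` hops of which the first is initiation, plus unloading); the
normalized effective elongation rate divides this by the measured mean
transit time.

## Lattice polymer with valency-limited attraction

Chromatin is a self-avoiding, semi-flexible chain on an FCC lattice
(integer triples with even coordinate sum; 12 neighbors, the permutations
of (+-1, +-1, 0)) in a periodic box, one monomer = 2 kbp = 50 nm (bond
length).  The Hamiltonian is

    H = kappa * sum (1 - cos theta_i)  +  E * sum_pairs f_ij s_i s_j,

`kappa = 1.2 kT` (Kuhn length ~100 nm), `E = -3 kT` between Pol II-bound
monomers on nearest-neighbor sites, kT = 1.  The default box puts the chain
at a 50 % lattice fill (crowded, melt-like environment; boxes are the
smallest even cube meeting the fill, so the realized fill can sit a few
percent off the target).

Moves are single-monomer relocations: an interior monomer may move to any
site simultaneously adjacent to both chain neighbors, an end monomer to any
neighbor of its single neighbor.  The geometric candidate set depends only
on the fixed neighbors, so proposals are symmetric and Metropolis
acceptance `min(1, e^-dH)` satisfies detailed balance at fixed occupancy
(verified against exhaustive enumeration of 5-mer configurations).  One MCS
= one TASEP sweep followed by `N` trial moves.  TASEP transitions are never
filtered by the interaction energy (Pol II's stall force far exceeds these
interactions), which makes the coupled system a driven, out-of-equilibrium
model.

Initial conformations are boustrophedon (snake) paths over the lattice —
planar-layered, hence unknotted and self-avoiding.  The chain initially
occupies the lower part of the box and spreads during burn-in; gene-level
observables are always measured after an explicit burn-in whose
stationarity was checked on windowed IC and RG series.

### Valency bookkeeping

With limited valency each bound monomer keeps a partner list (at most
`valency` entries; pairs symmetric, both members bound and adjacent).  Two
kinetic rules are implemented:

* persistent pairing (`reshuffle_every = 0`, the default): pairs survive
  while valid; freed slots are refilled, in random scan order, when their
  owner next moves or changes occupancy;
* stochastic re-resolution (`reshuffle_every = k`): every `k` MCS all lists
  are rebuilt from scratch in random monomer order, so chain-neighbor bound
  pairs — which are always adjacent — repeatedly compete with long-range
  pairs for the limited slots.

The energy counts `E` per listed pair, including bound chain neighbors:
that competition is precisely the screening mechanism that suppresses
long-range condensation at high occupancy.  For a proposed polymer move the
interaction term of `dH` is computed against the deterministically
re-resolved list of the moved monomer (surviving partners plus eligible new
ones up to the cap), and the post-acceptance update applies exactly that
re-resolution — so the incremental `dH` equals the global Hamiltonian
difference exactly, which the tests assert against a from-scratch energy
oracle.  Cascade refills of third parties happen only on TASEP-driven
occupancy changes, which are not Metropolis-filtered.  At unlimited valency
(cap 12, the coordination number) the lists provably equal the set of all
adjacent bound pairs under either rule.

### Pre-equilibration of occupancy

At the calibrated clock the TASEP relaxation time (~`n/gamma`, i.e. about
10^6 MCS for a 50-monomer gene) would dominate any affordable burn-in, so
coupled runs first draw the gene occupancy as independent Bernoulli samples
at the target density and then run a configurable number of TASEP-only
sweeps before the polymer moves start.  This seeds the occupancy at its
steady-state mean (per-replicate means fluctuate by `sqrt(rho(1-rho)/n)`,
averaged out across replicates) without touching the polymer statistics.

## Trajectory observables

Contacts are nearest-neighbor site pairs — the same proximity notion as
`f_ij` — counted once per snapshot per pair.  Simulated IC uses the
snapshot-averaged contact map of a region around the gene, an expected curve
estimated per diagonal from background pairs only (pairs inside a declared
signal span are excluded: on a scaled chain the gene is a sizeable fraction
of each diagonal and would contaminate its own null — the genome-scale
analog is a single gene among thousands), and the mean obs/exp over
intra-gene pairs.

Radius of gyration follows `RG = sqrt(mean |r_i - r_m|^2)`, with positions
re-unwrapped along the chain within each snapshot (the stored coordinates
are continuous per monomer over time for MSD purposes, but not across
monomers once their periodic wrap counts differ).  MSD is time- and
ensemble-averaged over log-spaced lags for the interior monomers of the
analyzed span (outer quarters dropped against end effects), and fitted as
`MSD = D * dt^delta` by linear least squares in log-log space.  The default
fit window is 20-3000 MCS: below ~20 MCS single-move discreteness distorts
the slope, and beyond a few thousand MCS the finite chain crosses over from
the Rouse-like regime toward center-of-mass motion.  No center-of-mass
drift subtraction is applied by default.

The MCS-to-real-time calibration solves `D_lat * c / tau^delta = 0.01` for
`tau`, matching the fitted lattice prefactor (converted by
`c = (bond/sqrt(2) / 1000)^2` um^2 per squared grid unit) to the reference
chromatin mobility 0.01 um^2/s^0.5 from live imaging; it refuses fits whose
exponent is far from the 0.5 reference since the units would not match.
On this kernel the neutral crowded chain gives delta ~ 0.54 and tau of a
few ms, consistent with the 3 ms default used for the rate conversion.

## Study conditions and problem sizes

The desk-scale simulations use chains of 200-1024 monomers at 50 % lattice
fill with genes of 50-64 monomers (100-128 kb), E = -3 kT, kappa = 1.2 kT,
gamma = 2 kb/min at the 3 ms clock, run for 10^5 to 2x10^6 MCS after
pre-equilibrated occupancy — the package's chosen desk-scale conditions.
Burn-ins were set from windowed stationarity of IC and RG.  The
reproduction script (`scripts/acceptance.py`) uses: the uniform TASEP at
n = 50 for 1.2x10^6 MCS; mobility runs on a 1024-monomer chain (valency 2,
three densities, two replicates, 3.6x10^4 MCS at 10-MCS snapshots, fit
window 20-3000 MCS); valency screening on a 432-monomer chain with three
matched seed pairs (unlimited arm 1.2x10^6 MCS with 4x10^5 burn-in,
valency-2 arm 5x10^5 MCS); and the density sweep of a 64-monomer gene on
the same chain (7x10^5 MCS per arm).

One honest caveat recorded here: with strong attraction the
unlimited-valency collapse coarsens slowly (sticky, glass-like kinetics in
a crowded melt under single-monomer moves), and windowed IC still drifts
upward after 10^6 MCS when the collapse is incomplete (on a 1024-monomer
chain, windowed IC rose 6.8 -> 10.6 over 2x10^6 MCS and had not plateaued).
Scaled-down runs therefore systematically underestimate the contrast
between unlimited and valency-limited condensation relative to runs one to
two orders of magnitude longer: the measured unlimited-to-valency-2 IC fold
at desk scale is ~2.5-3 (stable across matched seed pairs) where far longer
trajectories would be needed for the fully coarsened globule.

## Known limitations

* The polymer move set is minimal (single-monomer kink/end moves); it is
  ergodic for local rearrangement but slow for large-scale reorganization,
  which matters in the glassy strong-attraction regime.
* The synthetic contact generator does not produce compartment
  checkerboards or read-level noise; conclusions from its tests are about
  estimator correctness, not robustness to raw-data artifacts.
* Absolute IR bin labels depend on the normalization of the input track.
* The two valency pairing kinetics (persistent vs re-resolved) are both
  defensible readings of "the list is updated after any move"; they bracket
  the screening strength and are exposed as a parameter rather than hidden.
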