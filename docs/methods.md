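# Methods

`nlchrom` implements a two-tier, experimentally informed polymer model of
chromatin and the analysis suite used to interrogate the resulting
conformational ensembles. This note records the model, its assumptions,
every tunable that matters, the numerical choices, and what the synthetic
data used for validation does and does not establish.

## The two-tier model

**Stage 1 — coarse folding against contact data.** A genomic region is
represented as a homopolymer of 5-kb beads. From a balanced
contact-probability map, the persistent contacts are selected per
genomic-separation diagonal `d = |i−j| ≥ 2`: an entry is retained when it
exceeds that diagonal's mean plus one standard deviation (diagonals with
fewer than three entries are skipped; `|i−j| = 1` pairs are excluded
because the chain backbone already bonds them). The retained set is then
stochastically decomposed into M replicate restraint sets: each pair is
included in each replicate by an independent Bernoulli draw with
probability `q_ij = p_ij / max p`, clamped to `[0.02, 1]`, so the
replicate-averaged inclusion indicator reproduces the retained
probabilities up to the max-normalisation (verified to 3 binomial SE in
the tests). Replicates whose restraint graph would be disconnected (or
empty) receive the highest-q bridging pairs; this repair is a practical
safeguard — an unrestrained replicate cannot fold — and can be disabled.
Normalisation is global across the retained set; a per-diagonal variant
would emphasise long-range contacts more strongly and is a one-line
change in `preprocess.decompose`.

Each replicate is folded by Langevin dynamics from a pivot-equilibrated
self-avoiding walk under harmonic bonds, WCA excluded volume (restrained
pairs exempt — the restraint well replaces their excluded volume), and
flat-bottom harmonic contact restraints, until at least 95% of restraints
are simultaneously within 2.5 bead contact distances.

**Stage 2 — nucleosome-linker (NL) resolution.** Consensus dyad positions
(DANPOS-style input, or the synthetic generator) define a copolymer:
each nucleosome bead represents exactly 142 bp centred on its dyad; each
inter-core gap of L bp becomes `round(L/8)` equal-bp linker beads
(nominally ~8 bp of B-DNA each). Because dyads are required to be at
least 147 bp apart, interior gaps are always ≥ 5 bp; gaps of 1–3 bp can
only occur at the region edges, where a single short terminal linker is
emitted (there is no flanking linker to absorb them into). Base pairs are
conserved exactly: bead spans tile the region edge-to-edge.

NL beads are assigned to the 5-kb domain of their genomic midpoint and
initialised uniformly at random inside a 90-nm-radius sphere centred on
their domain's coarse scaffold coordinate. A deterministic relaxation
(forward bond projection to the rest length, plus pushing non-bonded
pairs out of the repulsive core) removes the stored energy that would
otherwise detonate the first dynamics steps. Production dynamics run
under FENE bonds, a bending penalty `k_θ(1 + cos θ)` on consecutive
all-linker triplets, WCA excluded volume, a short-range non-specific
nucleosome–nucleosome attraction, and two centre-of-mass (COM) terms that
transfer the stage-1 contacts onto whole domains: a flat-bottom COM
restraint between contact-restrained domain pairs and a COM-level WCA
between the remaining non-adjacent domain pairs (restrained pairs are
exempt from the COM WCA, mirroring the bead-level exemption). After the
COM restraints reach 95% satisfaction, production continues for
`n_steps`, saving a frame every `save_interval` (the full-scale protocol,
6,500,000 steps at a 50,000-step stride, yields 130 frames per
replicate; the desk-scale defaults below use shorter runs).

## Reduced units and the integrator

Lengths are measured in σ = 2.5 nm (the linker bead diameter; nucleosome
beads are 4 σ = 10 nm), energies in ε, temperature k_BT = 1, bead mass
m = 1, and time in the fundamental simulation time unit τ. The integrator
is BAOAB velocity-Verlet Langevin with **Δt = 0.005 τ** and friction
γ = 1/τ. τ is the unit of time: its value in physical units never enters
the equations of motion. At the coarse level one bead diameter (1 σ_CG)
corresponds to 90 nm, the 5-kb domain envelope.

Setting γ = 0 with zero noise reduces the update to plain velocity
Verlet; the tests verify symplectic behaviour (no secular energy drift
over 10⁴ steps) and thermostat accuracy (sampled temperature within 2%
over 10⁵ steps).

During the *folding* loops (stage-1 restraint satisfaction and stage-2
phase A) the friction is raised to γ = 2/τ. The reason is mechanical:
restraint forces are capped at f_cap, and the resulting drift speed
f_cap/γ must stay below the distance a bead may travel per step without
tunnelling through the WCA core. Production always runs at γ = 1/τ.

## Force-field defaults

All parameters live in `ForceField` and are plain keyword overrides.

| term | default | why |
|---|---|---|
| WCA | ε = 1, σ_ij = (d_i+d_j)/2 (Lorentz) | standard athermal excluded volume |
| FENE bond | k = 30 ε/σ_ij², R0 = 1.5 σ_ij | Kremer–Grest in dimensionless per-pair form; a flat k would make mixed-size nucleosome–linker bonds 6× over-stiff and unstable at Δt = 0.005 τ |
| harmonic bond (coarse) | k = 200 ε/σ², r0 = σ | stiff connectivity for 5-kb beads |
| bending | k_θ = 5 k_BT on linker triplets | bare-DNA-like local stiffness at ~8 bp per bead |
| contact restraint | flat-bottom harmonic, k_c = 10 ε/σ², contact radius 2.5 × pair contact distance, well at 0.8 × that radius, force cap f_cap = 5 ε/σ | see below |
| nucleosome attraction | truncated-shifted LJ, ε_nn = 0.5 ε, cutoff 2.5 σ_NN | short-range non-specific inter-nucleosome attraction driving local compaction; set ε_nn = 0 to disable |
| COM restraint / COM WCA | k_com = 10, radius = 90 nm | transfers 5-kb contacts onto domains |

Two restraint choices deserve explanation. First, the harmonic wall of
each flat-bottom restraint sits at 0.8 × the contact radius while
*satisfaction is always checked at the full contact radius*: with the
wall exactly at the check radius, thermal fluctuations keep a third of
the pairs marginally outside at any instant and 95% simultaneous
satisfaction is unreachable at k_BT = 1. Second, the restraint force is
capped (linear continuation beyond f_cap/k_c): an uncapped harmonic
acting over tens of σ produces forces that destroy the integration.

## Coarse-graining and map analyses

Simulated frames are coarse-grained by grouping beads into genomic bins
(200 bp or 5 kb) and taking per-bin centres of mass; two bins are in
contact when their COM distance is below a cutoff — 2.5 nucleosome
diameters (25 nm) at sub-kb resolutions (the same criterion used for the
tetra-nucleosome motifs), and 1.5 × the 90-nm domain envelope radius
(135 nm) at 5 kb, where the contact partner is a whole domain. Maps are
contact frequencies over frames, hence quantised in units of 1/n_frames.

* **P(s)**: per-diagonal means, geometric binning for reporting,
  log-log least-squares slopes over caller-chosen separation ranges.
* **Correlation**: Pearson and Spearman over the upper triangle;
  **dcPCC** subtracts each diagonal's mean from both maps before a
  global Pearson over off-diagonal entries (a per-diagonal-correlation
  average is the obvious alternative dialect; the global form is used
  because short maps leave too few entries per diagonal).
* **Insulation boundaries**: score at bin i is the mean contact in the
  window × window box straddling i (default window 10 bins, i.e. 2 kb at
  200 bp); boundaries are local minima with prominence ≥ 0.1 of the
  score range; map edges are excluded; matching between boundary sets is
  greedy nearest-neighbour within a 1-bin default tolerance.
* **State enrichment**: with binary per-bin activity labels, contact
  weight per pair class is normalised by class abundance and the
  effective Flory–Huggins parameter is
  χ_eff = −½ ln(P_AB² / (P_AA·P_BB)); positive χ means like-like
  preference, and the measure is invariant under swapping the labels.

## Blob morphometrics

Nucleosome blobs are DBSCAN clusters of nucleosome bead centres
(defaults eps = 20 nm — two nucleosome diameters — and min_pts = 3,
chosen so a 3–4 nucleosome, ~600–700 bp aggregate is detectable; both
are configurable, and the implementation is verified against a
brute-force neighbourhood-expansion oracle). Morphometrics per blob:
convex-hull surface area (μm²), bp content, principal semi-axes from the
member-coordinate covariance eigenvalues, and eccentricity
e = √(1 − (b/a)²) of the extreme axes. Blob-area ensembles are
summarised by a maximum-likelihood lognormal fit reporting the *mode*
and the *distribution SD* separately — for wide lognormals the SD far
exceeds the mode, and a bare "mean ± SD" would be ambiguous.

The compaction index uses r₀ = 2 × the frame-wide median
nearest-neighbour distance; ρ_fixed is the mean count density in
r₀-spheres around blob members and ρ_bg the same statistic over all
nucleosomes, so CI = ρ_fixed/ρ_bg is exactly 1 in expectation for a
homogeneous frame (a quantified null test). Retained blobs must have a
DBSCAN core-member fraction ≥ 0.8 (our reading of a "density threshold";
the alternative reading ρ_fixed ≥ 0.8 × frame maximum is available by
flag) and a radius of gyration within 10–40 nm; each frame is summarised
by the top quartile ranked by ρ_fixed. Inter-blob statistics pool
centroid-to-centroid distances over frames and normalise the RDF by a
Monte-Carlo Poisson control of equal intensity inside the pooled-centroid
convex hull. Noise nucleosomes count as singleton blobs of size 1 in
per-nucleosome size profiles, so the profile is defined everywhere.

Eccentricity is singular near zero: covariance eigen-noise of order
√(2/n) inflates the eccentricity of a perfectly isotropic cloud to
roughly (8/n)^¼ (about 0.3 at n = 10⁴ members). Small-blob eccentricities
are therefore biased up, which is why shape claims rest on the
distribution rather than single blobs.

## Tetra-nucleosome motifs

Every window of four consecutive nucleosomes in every frame yields a
6-entry binary vector of the unique pairs (contact iff centre distance
≤ 2.5 nucleosome diameters). The 6-vector is used rather than the
redundant 4×4 matrix — identical information, better-conditioned
k-means. Vectors are pooled over windows and frames and clustered with
k-means (k = 10, 20 restarts, best inertia), clusters ranked by
prevalence. Binary vectors (not real-valued distances) are clustered, as
contacts are what the threshold defines.

## Free-energy surfaces and entropy

Conformations are rigid-body aligned (iterated Kabsch superposition to
the ensemble mean — unaligned Cartesian covariance is dominated by
global rotation; alignment is on by default and flaggable), the
flattened coordinates are decomposed by PCA, and the first two PC scores
are histogrammed on a grid spanning ±3 SD per PC (default 150×150;
desk-scale analyses use coarser grids scaled to the frame count).
F = −k_BT ln P with k_BT = 1. A basin is an occupied bin whose F is not
exceeded by any occupied 8-neighbour, with connected equal-F plateaus
merged; the count is invariant under constant shifts of F and, with
alignment, under global rotations of the ensemble. The Boltzmann entropy
is S = −Σ P ln P over occupied bins (so S ≤ ln(occupied bins), with
equality for uniform occupancy). Basin counts and S depend on the grid;
cross-condition comparisons are only meaningful at a fixed grid and
frame count.

## Worm-like-chain rigidity

The fibre at 200-bp coarse-graining has an effective segment length
b_eff = geometric mean of adjacent bead distances over all frames
(geometric, to be robust to the mixed nucleosome–linker composition).
Tangent autocorrelations C(s) = ⟨t_i · t_{i+s}⟩ are fit to
C(s) = exp(−s·b_eff/ℓ_p); K_b = k_BT·ℓ_p with k_BT = 4.114 pN·nm (the
value used for the conversion at 300 K; `kbt_pn_nm` is a field if the
caller prefers k_B × 300 K = 4.142 pN·nm).

Two estimators:

* **lag-wise** — C(s) per conformation at short lags (default
  s = 1..5), averaged with equal weight per conformation; the averaged
  correlations are fit by weighted log-linear least squares through the
  origin, with inverse-variance weights on the log scale (delta method,
  w ∝ C̄²/var). Averaging before the log fit matters: a log fit inside
  each conformation censors noisy negative C(s) values and biases ℓ_p
  upward by several percent — enough to break CI coverage.
* **global** — pooled C(s) up to a long maximum lag (default 50), same
  weighting, with lags whose weight falls below 5% of the maximum
  trimmed away; at least the three earliest usable lags are always
  retained (long lags must never be force-included: their s² leverage
  through the origin lets pure noise dominate the fit). The kept-lag
  count is reported.

Both report percentile bootstrap 95% CIs over conformations (default
1000 resamples, seeded). On synthetic chains with exactly exponential
tangent statistics (see below), both estimators recover
ℓ_p ∈ {10, 20, 50} nm within 10% with ≥ 90% CI coverage over 50
repeats. Non-decaying correlations (rigid rods) are capped at 10⁶ nm and
flagged.

Sliding-window R_g (default 10-kb windows, 1-kb step) and TSS distance
profiles (mean distance of every 200-bp segment's COM to the
TSS-containing segment's COM) use the same binning conventions as the
contact maps. The composite activity score z-scores each omics signal
across loci (sample SD, so two loci give ±1/√2), flips repressive marks
(H3K27me3), averages, and reports the Spearman correlation against K_b.

## Synthetic data: what it emulates, and what it does not

* `gen_hic` — power-law distance decay `|i−j|^−α` with TAD-like block
  enrichment, multiplicative lognormal noise of chosen CV, diagonal set
  to the row maximum, then symmetric Sinkhorn scaling to unit row sums
  (the same fixed-point class as KR balancing, chosen for simplicity).
* `gen_nucleosomes` — dyads on an NRL grid with Gaussian positional
  jitter ("fuzziness"), redrawn on 147-bp core conflicts, excluded from
  NDR intervals; occupancies are uniform random scores.
* `gen_wlc` — per-step polar angle drawn from p(cos θ) ∝ exp(κ cos θ)
  with κ solved so ⟨cos θ⟩ = exp(−b/ℓ_p), uniform azimuth. The Markov
  construction makes ⟨t_i·t_{i+s}⟩ = exp(−s·b/ℓ_p) *exact* in
  expectation, giving the rigidity estimators an analytic ground truth
  that molecular dynamics could not provide.
* `gen_blob_cloud` — k isotropic or anisotropic Gaussian clusters plus
  uniform noise, with ground-truth labels, as the clustering and
  morphometry oracle.

All generators are pure functions of (spec, seed). Passing tests on
these inputs establishes that the estimators and the pipeline recover
*planted* structure under the stated noise models. It does not establish
that real Hi-C bias structure, cell-to-cell nucleosome heterogeneity,
sequencing depth effects, or locus-specific chromatin states are
captured: synthetic maps have exchangeable noise, synthetic arrays have
a single NRL, and the WLC chains have no excluded volume.

## Desk-scale defaults and degenerate inputs

The test and pipeline configurations use 20-kb loci, M = 4 replicates,
and 10⁵-step production saving every 10⁴ steps; the full-scale protocol
values (0.2-Mb loci, M = 100, 6.5 M steps, 50 k stride) remain the
`SimulationParams` defaults. A 20-kb region at 5-kb resolution has only
four bins, so no diagonal has the three entries required for contact
selection; the pipeline then folds unrestrained replicates and says so.
Other degenerate inputs are rejected loudly: all-zero maps, empty
restraint sets (at the operation level), dyads closer than 147 bp,
FENE bonds reaching R0 (a blow-up diagnostic, not a warning), and
rank-deficient ensembles for PCA.

## Known limitations

* Nucleosomes are spheres, not disks, and there are no histone tails or
  mark-specific interaction potentials; the single ε_nn is a deliberate
  non-specific stand-in.
* The decomposition law (independent Bernoulli, global max-normalisation,
  q_min = 0.02) is one member of the family of laws whose replicate
  average reproduces the input; results that depend on replicate-level
  contact correlations would need a different law.
* Stage-1 folding samples restraint-satisfying conformations, not the
  Boltzmann ensemble of any particular free-energy model of the locus.
* Entropy and basin counts are grid-dependent summaries; only
  like-for-like comparisons are meaningful.
* CPU-only; the desk-scale problem sizes above are the intended regime.
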