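# Methods

This note records the models, conventions and numerical choices behind
`fuzzyens`, and what the synthetic generators do and do not emulate.

## Data model and conventions

Coordinates are stored in nm; PDB files are treated as Å on disk and
converted on read/write (mdtraj's convention). The XYZ format carries no
unit convention, so the package defines on-disk XYZ as nm. Residue indices
are 1-based and all residue intervals (domains, β-strands) are inclusive,
matching conventional sequence numbering. Each residue owns one or more
named beads with exactly one designated backbone bead; multi-molecule frames
concatenate molecules in a fixed order, so molecule identity is positional.
The galectin-3 annotation tables ship as constants: NTD = residues 1–112,
CRD = 113–250, and the eleven CRD β-strand intervals (β1 = 118–121 through
β11 = 240–249).

## Size metrics and block error analysis

`Rg` is the unweighted RMS distance of a molecule's beads from their
centroid; coarse-grained beads have no canonical masses, so equal weights
are the default and per-bead weights are an option. `Dmax` is the exact
maximum over all bead pairs (exhaustive O(n²) search — frames here are
hundreds of beads, and exactness is worth more than a convex-hull
shortcut). `d_ee` is the distance between the backbone beads of the first
and last residue.

Errors of trajectory means use block averaging: the series is cut into
contiguous blocks, and the standard error of block means is tracked as the
block size doubles. For a correlated series this rises to a plateau equal
to the true standard error of the mean. The reported value is the estimate
at the largest default block size; the default ladder stops where at least
64 blocks remain, so the plateau estimate itself has ~8% relative precision
(the variance of a sample standard deviation with B blocks scales as
1/√(2(B−1))). Series with correlation times approaching n/64 frames need
explicitly larger `block_sizes`. Histograms default to 50 equal-width bins
over the observed range, normalised to unit mass.

## Polymer scaling and θ-point

The inter-residue distance curve R(s) averages the residue–residue distance
over all frames and all pairs at fixed sequence separation s within a
domain. Two conventions are supported, because the literature uses both and
they differ by a known constant for Gaussian chains:

- *arithmetic mean of minimum bead–bead distances* — the literal
  contact-analysis convention (default);
- *RMS of backbone-bead distances* — the convention for which ideal-chain
  closed forms hold exactly (R(s) = b√s), used by the recovery tests.

For Gaussian inter-residue vectors the two averages differ by the Maxwell
factor √(8/3π) ≈ 0.921 (verified as a test).

The Flory fit R(s) = b·s^ν is a nonlinear least squares with the Kuhn
length pinned at 0.55 nm (the standard IDP value) or free. Separations
below `s_min = 2` are excluded: the bonded-pair distance is fixed by
geometry, not chain statistics. Fitted ν outside (0, 1) is treated as a fit
failure rather than reported.

The θ-scan takes (control, ν) points from any solvent-quality scan, puts a
shape-preserving monotone cubic (PCHIP) through them — projecting the ν
values onto the closest monotone sequence first (pool-adjacent-violators)
when sampling noise breaks monotonicity — and locates the root of ν = 1/2
by Brent bisection. If 1/2 is not bracketed by the scan the result is
explicitly "no crossing" rather than an extrapolation.

## Gaussian-chain end-to-end fit

The Gaussian-chain end-to-end distance density is

    p(d) = 4 d² exp[−(d/ξ)²] / (√π ξ³),

i.e. the norm of a 3-vector of independent Gaussians with standard
deviation ξ/√2 (this identity is also how `sample_gaussian_dee` draws
exactly from the density — no rejection sampling). The fit bins samples
into 50 equal-width bins on [0, max], keeps zero-count bins, least-squares
fits ξ at bin centers (moment-based start ξ₀ = mean·√π/2) and reports the
squared Pearson correlation between histogram and fitted densities. R²
close to 1 (> 0.98) marks Gaussian-chain-like ensembles; collapsed or
multi-modal end-to-end distributions fall well below (< 0.9).

## Contacts

Two residues are in contact when the smallest distance between any of their
beads is below 0.7 nm. Within a molecule, pairs (i, i+1), (i, i+2),
(i, i+3) are excluded; across molecules every pair is eligible and bead
displacements use the minimum-image convention in the cubic box. The
minimum-image rule is equivalent to whole-molecule reconstruction for
contact detection as long as each molecule's coordinates are whole, which
the generators guarantee and the I/O layer assumes (no "make-whole"
reconstruction is performed).

Contact probabilities are frame fractions; per-pair errors come from block
means over 10 contiguous trajectory blocks (the same machinery as the
scalar block error analysis). Domain-level probabilities are union events —
p_i(D) is the fraction of frames in which residue i touches *any* residue
of domain D — so p_i(D) ≥ max_{j∈D} p_ij holds exactly and is asserted as a
property test. Inter-molecular variants (π_i(D), π(D1, D2)) aggregate over
all ordered molecule pairs, symmetrised.

Map comparison runs a per-pair one-way ANOVA on the stored block means,
with blocks as replicates — trajectories are internally correlated, so
frames are not valid replicates but long blocks approximately are. The
two-group F statistic is computed in closed form (vectorised over pairs)
and matches `scipy.stats.f_oneway` to machine precision (tested). Pairs
with zero within- and between-group variance get p = 1. A pair is flagged
at a threshold only if additionally |Δp| > 0.001, which suppresses
vanishing differences that are merely well resolved. Because residue pairs
share frames, flagged-pair fractions fluctuate more than binomially in a
single comparison; the calibration test therefore averages over replicate
ensemble pairs.

## SAXS

Scattering profiles of bead structures use the Debye sum with per-bead form
factors (default 1; electron counts may be supplied to emulate contrast
weighting). `sin(x)/x` is evaluated through `np.sinc`, which is exact and
stable through x = 0, so I(0) = (Σf)² holds analytically. No hydration
shell or atomic form-factor model is included: the calculator is a
coarse-grained Debye model, adequate for ensemble-shape comparison at low
and intermediate q. The ensemble profile is the per-q arithmetic mean over
structures.

The comparison statistic is the reduced

    χ²(a, b) = (1/n) Σ_i [I_ref(q_i) − a·I_sim(q_i) − b]² / σ_i²,

minimised in closed form over scale a and offset b (weighted normal
equations); the model is linearly interpolated onto the reference q grid.
With correctly scaled noise, χ² ≈ 1 (expectation (n−2)/n after the
two-parameter fit).

## Oligomer clustering

Molecules are clustered per frame by agglomerative merging: all singletons
initially, two clusters merged when any molecule of one contacts any
molecule of the other (same 0.7 nm contact rule, minimum image), repeated
to a fixed point. That fixed point equals the connected components of the
molecule contact graph; the implementation keeps the agglomerative loop and
the equivalence is asserted against an independent connected-components
oracle in the tests, rather than assumed. Histograms of cluster count and
largest-cluster size are normalised over frames.

## Synthetic generators

The generators replace MD trajectories and define the conditions under
which every analysis is validated. All are pure functions of their integer
seed.

- **Freely jointed chain** — one bead per residue, bonds of exactly b in
  uniformly random directions, independent frames. This is the exact
  ideal-chain reference: ⟨R_ee²⟩ = (n−1)b², ⟨Rg²⟩ = (n²−1)b²/(6n),
  R(s) = b√s.
- **Solvent-quality chain** — Metropolis Monte Carlo of a fixed-bond-length
  chain with a hard core of radius `excluded_radius` and, for negative
  `pair_well`, a square well of that depth (kT units) extending to 1.5·b.
  Moves are bond-preserving pivots (30%) and crankshaft/terminal rotations
  (70%); a frame is saved every `sweeps` sweeps (n moves each) after
  20·`sweeps` equilibration sweeps. Rigid bonds with pivot moves were
  chosen over harmonic bonds with displacement moves because the ideal
  limit (no core, no well) then coincides *exactly* with the freely jointed
  chain, and pivots decorrelate global size in a few sweeps — the lag-1
  autocorrelation of Rg between saved frames stays below 0.2 at the default
  settings (tested). The well depth is a solvent-quality knob in the same
  sense that rescaled protein–water interactions are in coarse-grained
  force fields: attraction collapses the chain (ν < 1/2), repulsion swells
  it (ν > 1/2), and ν is monotone in the depth. The mapping to any
  particular force-field parameter is qualitative by design; no
  thermodynamic calibration is attempted.
- **Two-domain builder** — a rigid domain template (supplied, or the
  packed-sphere stand-in from `make_domain_template`, which is synthetic
  and labelled as such) is rotated rigidly per frame and tethered one bond
  beyond the last tail bead; the tail is generated by the solvent-chain
  sampler with the same spec and seed, so the tail sub-ensemble is
  bitwise-identical to a standalone run. Tail–domain excluded volume is
  *not* enforced: the two parts are statistically independent, which keeps
  the tail's reference statistics exact but means tail–domain contact
  probabilities reflect random co-location, not sequence-specific
  interactions.
- **Box packer** — draws conformations from a single-molecule ensemble,
  places them at uniform random positions and orientations in a cubic
  periodic box (20 nm default edge, 6 molecules default), rejecting
  placements with any inter-molecular bead distance below the 0.4 nm
  tolerance, with a bounded retry budget.
- **Reference scattering** — an affine transform a·I(q) + b of a model
  curve plus Gaussian noise of standard deviation `noise_level`·|a·I(q)|,
  with σ(q) set to exactly that value, so the generating model scores
  χ² ≈ 1 by construction.

What these generators do *not* emulate: real force-field energetics,
sequence-specific interactions (aromatic/charge patterning), solvent and
ions, kinetics (frames are equilibrium samples, not a dynamical
trajectory), and tail–domain coupling. Passing tests therefore demonstrate
that the *analyses* are correct and calibrated on ensembles with known
ground truth — not that any particular protein behaves like the synthetic
ensembles.

## Problem sizes

The validation suite uses desk-scale problem sizes chosen to make the
statistical checks sharp at interactive runtimes: 10⁴–2·10⁴ frames for
ideal-chain closed-form recoveries (standard errors well below the asserted
tolerances), 150–200 Monte Carlo frames of 36–40-bead chains for the
solvent-quality scans, 10⁵ draws for density-recovery fits, and
10³ random boxes for the clustering oracle. Each quantitative assertion is
a 3σ-style bound or an explicit tolerance derived from the corresponding
closed form.

## Known limitations

- The Monte Carlo chain has no persistence length or sequence heterogeneity;
  ν ranges are controlled by a single global well depth.
- The coarse-grained Debye calculator omits hydration-shell contrast, so
  absolute intensities are arbitrary; only shape comparison via (a, b, χ²)
  is meaningful.
- The ANOVA replicate structure (10 blocks) is a pragmatic default; for
  trajectories with correlation times near a tenth of their length the
  block means are not independent and p-values become anti-conservative.
- Inter-molecular analyses assume whole molecules in a cubic box; no
  triclinic cells, no PBC reconstruction of broken molecules.
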