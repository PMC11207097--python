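# fuzzyens

Conformational-ensemble analysis for proteins that combine folded domains
with intrinsically disordered regions, modelled as coarse-grained bead
ensembles. The motivating system is galectin-3: a folded carbohydrate
recognition domain (CRD, residues 113–250) carrying a 112-residue
disordered, Pro-Gly-rich N-terminal tail (NTD) that drives transient,
"fuzzy" self-association. The library quantifies such ensembles with the
standard polymer-physics and scattering toolkit:

- **Size metrics** — per-frame radius of gyration `Rg`, maximum bead-pair
  diameter `Dmax` and N-to-C end-to-end distance `d_ee`, with trajectory
  averages and **block error analysis** for correlated series.
- **Polymer scaling** — inter-residue distance curves `R(s)` versus sequence
  separation `s = |i − j|`, Flory fits `R(s) = b·s^ν` (Kuhn length
  `b = 0.55 nm` by default, ν free), and θ-point location: the solvent
  condition where a smoothed ν(control) scan crosses the ideal-chain value
  ν = 1/2.
- **Gaussian-chain end-to-end fitting** — least squares of
  `p(d) = 4 d² exp[−(d/ξ)²] / (√π ξ³)` to an end-to-end histogram, with the
  Pearson `R²` between histogram and fit as the Gaussianity diagnostic.
- **Contact statistics** — residue–residue contact maps (minimum bead–bead
  distance < 0.7 nm, nearest 3 sequence neighbours excluded), per-residue
  probabilities `p_i(D)` of contacting a domain `D`, β-strand and
  domain–domain contact probabilities, inter-molecular variants under the
  minimum-image convention, and map comparison by per-pair ANOVA on block
  means.
- **SAXS comparison** — coarse-grained Debye profiles
  `I(q) = Σ f_u f_v sin(q r_uv)/(q r_uv)`, ensemble averaging, and the
  reduced `χ²(a, b)` fit of scale and offset against a reference curve.
- **Oligomer clustering** — per-frame agglomerative clustering of molecules
  by inter-molecular contact connectivity in periodic boxes, with cluster
  count and largest-cluster-size histograms.
- **Synthetic generators** — seeded freely jointed chains, a Metropolis
  Monte Carlo chain whose pairwise well depth tunes the solvent quality
  across the coil–globule transition, exact Gaussian-chain end-to-end
  samplers, rigid-domain + flexible-tail builders, periodic-box packers and
  noisy reference scattering curves. These provide ground-truth ensembles
  for every analysis.

Ensembles are read and written as multi-model PDB or XYZ trajectories (via
mdtraj) with a JSON topology config (residues, beads, domains, β-strands);
SAXS curves are 3-column `q I σ` text. All coordinates are in nm, q in
nm⁻¹.

## Worked example

Fitting the Flory scaling law to an ideal chain with the IDP Kuhn length
(`examples/flory_scaling.py`):

```python
import fuzzyens as fz

ens = fz.generate_fjc(fz.ChainSpec(n_residues=112, bond_length=0.55, seed=1), 10_000)
curve = fz.scaling_curve(ens, mode="rms", distance="backbone")
fit = fz.fit_flory(curve, b_fixed=None)
```

prints

```
fitted Kuhn length b = 0.5469 nm   (generating bond length: 0.55 nm)
fitted Flory exponent nu = 0.5019   (ideal chain: 0.5)
```

The two-parameter fit recovers the bond length as the Kuhn length and the
ideal-chain exponent ν = 1/2 — the θ-state signature. On real ensembles the
same fit classifies the disordered region as collapsed (ν ≈ 1/3), ideal
(ν = 1/2) or swollen (ν ≈ 0.59). The Gaussian-chain end-to-end fit behaves
the same way (`examples/end_to_end_distribution.py`):

```
generating scale xi = 5.44 nm
fitted     scale xi = 5.441 nm   (recovery within ~1%)
Pearson R^2 of histogram vs fit = 0.9997  (> 0.98: Gaussian-chain-like)

bimodal control sample: R^2 = 0.000  (< 0.9: not Gaussian-chain-like)
```

The other scripts in `examples/` walk through the θ-point scan, contact
maps and domain profiles, the Debye/χ² SAXS fit, and oligomer clustering;
each prints the quantities it computes and one line on how to read them.

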