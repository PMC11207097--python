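"""Intra-molecular contact statistics of a tail + domain architecture.

Builds a synthetic two-domain molecule — a 30-residue flexible tail (NTD-like)
tethered to a 40-bead rigid globule (CRD-like) — and computes the residue
contact map (0.7 nm cutoff, nearest 3 sequence neighbours excluded), the
per-residue probability of contacting each domain, and the size metrics with
block errors.
"""

import numpy as np

import fuzzyens as fz

template = fz.make_domain_template(n_residues=40, radius=1.2, seed=4)
spec = fz.ChainSpec(n_residues=30, sweeps=6, seed=5)
ens = fz.generate_two_domain(30, template, spec, 200)

metrics = fz.metrics_series(ens)
rg = fz.block_error(metrics.rg)
print(f"Rg   = {rg.mean:.3f} +/- {rg.error:.3f} nm  (mean with block-error estimate)")
print(f"Dmax = {metrics.dmax.mean():.3f} nm, dee = {metrics.dee.mean():.3f} nm (frame means)")

cmap = fz.contact_probability_map(ens)
print(f"\ncontact map: {np.count_nonzero(cmap.p)} of {cmap.p.size} eligible residue "
      f"pairs ever in contact (cutoff 0.7 nm, |i-j| > 3)")

prof = fz.domain_profile(ens)
p_tail = prof.residue_profiles["NTD"][:30]
p_cross = prof.residue_profiles["CRD"][:30]
print(f"tail residues: mean p_i(NTD) = {p_tail.mean():.2f}  "
      f"(fraction of frames touching any other tail residue)")
print(f"tail residues: mean p_i(CRD) = {p_cross.mean():.2f}  "
      f"(fraction of frames touching the folded domain)")
print("\nhigh p_i(D) across many residues with no single dominant pair is the")
print("signature of fuzzy (multivalent, unspecific) interactions.")
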