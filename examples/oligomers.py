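"""Oligomer clustering in a crowded periodic box.

Packs six copies of a two-domain molecule into a periodic cubic box, detects
inter-molecular contacts (0.7 nm, minimum image) and clusters molecules by
contact connectivity frame by frame.  The histograms over the trajectory
show how often the system forms monomers, partial oligomers, or a single
cluster of all six molecules — transient, unspecific association is the
hallmark of fuzzy complexes.
"""

import fuzzyens as fz

template = fz.make_domain_template(n_residues=40, radius=1.2, seed=8)
spec = fz.ChainSpec(n_residues=30, sweeps=6, seed=9)
molecule = fz.generate_two_domain(30, template, spec, 150)

# a small box to make encounters frequent at this molecule size
box = fz.BoxSpec(box_edge=9.0, n_molecules=6, tolerance=0.4, seed=10)
packed = fz.generate_box(molecule, box, 80)

series = fz.cluster_series(packed)
print("frames:", len(series.n_clusters), " molecules per frame:", series.n_molecules)
print("mean number of clusters:", f"{series.n_clusters.mean():.2f}")
print("mean largest-cluster size:", f"{series.largest_size.mean():.2f}")
print("\nP(number of clusters = k), k = 1..6:")
print("  ", [f"{p:.2f}" for p in series.hist_n_clusters])
print("P(largest cluster size = k), k = 1..6:")
print("  ", [f"{p:.2f}" for p in series.hist_largest])
print(f"\nP(all six molecules in one cluster) = {series.p_all_in_one:.2f}")
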