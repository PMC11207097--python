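"""Contact determination, probability maps, domain profiles, map comparison."""

import numpy as np
import pytest
from scipy import stats

import fuzzyens as fz


def _one_bead_frame(positions, box=None):
    positions = np.asarray(positions, dtype=float)
    top = fz.simple_chain_topology(positions.shape[0])
    return fz.ConformationFrame(topology=top, coords=positions, box_edge=box)


def _multi_bead_topology(n_res, beads_per_res):
    residues = [
        fz.Residue(i + 1, "GLY", beads=tuple(f"B{k}" for k in range(beads_per_res)))
        for i in range(n_res)
    ]
    return fz.BeadTopology([fz.MoleculeTopology(residues)], domains={"chain": (1, n_res)})


def brute_force_intra_contacts(frame, cutoff=0.7, n_ignored=3, molecule=0):
    """Independent oracle: exhaustive bead-pair double loop."""
    top = frame.topology
    mol = top.molecules[molecule]
    x = frame.molecule_coords(molecule)
    out = set()
    for i in range(1, mol.n_residues + 1):
        for j in range(i + n_ignored + 1, mol.n_residues + 1):
            bi = x[mol.residue_bead_slice(i)]
            bj = x[mol.residue_bead_slice(j)]
            dmin = min(
                float(np.linalg.norm(a - b)) for a in bi for b in bj
            )
            if dmin < cutoff:
                out.add((i, j))
    return out


class TestFrameContacts:
    def test_cutoff_boundary(self):
        # residues 1 and 6 (|i-j| = 5) separated by 0.69 / 0.71 nm
        far = [[k * 10.0, 0, 0] for k in range(6)]
        pos = np.array(far)
        pos[5] = [0.69, 0, 0]
        assert (1, 6) in fz.frame_contacts(_one_bead_frame(pos))
        pos[5] = [0.71, 0, 0]
        assert (1, 6) not in fz.frame_contacts(_one_bead_frame(pos))

    def test_near_diagonal_exclusion(self):
        # |i-j| = 3 at 0.3 nm is excluded; |i-j| = 4 at the same distance is not
        pos = np.array([[k * 10.0, 0, 0] for k in range(6)])
        pos[3] = [0.3, 0, 0]
        contacts = fz.frame_contacts(_one_bead_frame(pos))
        assert (1, 4) not in contacts
        pos2 = np.array([[k * 10.0, 0, 0] for k in range(6)])
        pos2[4] = [0.3, 0, 0]
        assert (1, 5) in fz.frame_contacts(_one_bead_frame(pos2))

    def test_matches_brute_force_on_multibead_residues(self):
        rng = np.random.default_rng(71)
        top = _multi_bead_topology(10, 2)
        for _ in range(20):
            coords = rng.uniform(0, 2.5, size=(20, 3))
            frame = fz.ConformationFrame(topology=top, coords=coords)
            assert fz.frame_contacts(frame) == brute_force_intra_contacts(frame)

    def test_inter_requires_box(self):
        top = fz.simple_chain_topology(3, n_molecules=2)
        frame = fz.ConformationFrame(topology=top, coords=np.zeros((6, 3)))
        with pytest.raises(ValueError, match="box"):
            fz.frame_contacts(frame, scope="inter")

    def test_inter_uses_minimum_image(self):
        top = fz.simple_chain_topology(1, n_molecules=2)
        # beads at x = 0.1 and x = 9.9 in a box of 10: minimum-image distance 0.2
        coords = np.array([[0.1, 0, 0], [9.9, 0, 0]])
        frame = fz.ConformationFrame(topology=top, coords=coords, box_edge=10.0)
        assert fz.frame_contacts(frame, scope="inter") == {((0, 1), (1, 1))}

    def test_inter_invariant_under_lattice_translation(self):
        rng = np.random.default_rng(72)
        top = fz.simple_chain_topology(4, n_molecules=3)
        coords = rng.uniform(0, 8.0, size=(12, 3))
        frame = fz.ConformationFrame(topology=top, coords=coords, box_edge=8.0)
        ref = fz.frame_contacts(frame, scope="inter")
        for shift in ([8, 0, 0], [0, -16, 8], [24, 8, -8]):
            moved = fz.ConformationFrame(
                topology=top, coords=coords + np.asarray(shift, dtype=float), box_edge=8.0
            )
            assert fz.frame_contacts(moved, scope="inter") == ref

    def test_no_sequence_exclusion_across_molecules(self):
        top = fz.simple_chain_topology(4, n_molecules=2)
        coords = np.zeros((8, 3))
        coords[:4, 0] = np.arange(4) * 10.0
        coords[4:, 0] = np.arange(4) * 10.0
        coords[4:, 1] = 0.5  # residue i of mol 0 touches residue i of mol 1
        frame = fz.ConformationFrame(topology=top, coords=coords, box_edge=100.0)
        contacts = fz.frame_contacts(frame, scope="inter")
        assert ((0, 1), (1, 1)) in contacts  # |i-j| = 0 is eligible across molecules


class TestContactProbabilityMap:
    def test_frequency_is_frame_fraction(self):
        # contact present in exactly 10 of 100 frames
        base = np.array([[k * 10.0, 0, 0] for k in range(6)])
        frames = np.tile(base, (100, 1, 1))
        frames[:10, 5] = [0.5, 0, 0]
        ens = fz.Ensemble(fz.simple_chain_topology(6), frames)
        cmap = fz.contact_probability_map(ens)
        assert cmap.probability(1, 6) == pytest.approx(0.1)

    def test_all_far_gives_empty_map(self):
        base = np.array([[k * 10.0, 0, 0] for k in range(8)])
        ens = fz.Ensemble(fz.simple_chain_topology(8), np.tile(base, (20, 1, 1)))
        cmap = fz.contact_probability_map(ens)
        assert cmap.p.sum() == 0.0

    def test_matches_per_frame_oracle(self):
        rng = np.random.default_rng(73)
        top = _multi_bead_topology(8, 2)
        xyz = rng.uniform(0, 2.2, size=(60, 16, 3))
        ens = fz.Ensemble(top, xyz)
        cmap = fz.contact_probability_map(ens)
        counts: dict[tuple[int, int], int] = {}
        for frame in ens:
            for pair in brute_force_intra_contacts(frame):
                counts[pair] = counts.get(pair, 0) + 1
        for (i, j), c in counts.items():
            assert cmap.probability(i, j) == pytest.approx(c / 60)
        # and no extra probability mass anywhere else
        assert cmap.p.sum() * 60 == pytest.approx(sum(counts.values()))

    def test_union_bound_consistency(self, two_domain_small):
        """p_i(D) >= max_{j in D} p_ij: the union event contains each pair event."""
        cmap = fz.contact_probability_map(two_domain_small)
        prof = fz.domain_profile(two_domain_small)
        m = cmap.matrix()
        top = two_domain_small.topology
        for dom in ("NTD", "CRD"):
            dsel = top.domain_residues(dom) - 1
            pmax = np.nanmax(np.where(np.isnan(m[:, dsel]), -1, m[:, dsel]), axis=1)
            pi = prof.residue_profiles[dom]
            assert (pi >= pmax - 1e-12).all()


class TestDomainProfile:
    def test_persistent_contact_gives_probability_one(self):
        # residue 6 touches residue 1 (in domain A) in every frame
        pos = np.array([[k * 10.0, 0, 0] for k in range(6)])
        pos[5] = [0.5, 0, 0]
        top = fz.simple_chain_topology(6, domains={"A": (1, 3), "B": (4, 6)})
        ens = fz.Ensemble(top, np.tile(pos, (15, 1, 1)))
        prof = fz.domain_profile(ens)
        assert prof.residue_profiles["A"][5] == pytest.approx(1.0)

    def test_distant_molecules_have_zero_inter_probability(self):
        top = fz.simple_chain_topology(4, n_molecules=2, domains={"A": (1, 2), "B": (3, 4)})
        coords = np.zeros((2, 8, 3))
        coords[:, :4, 0] = np.arange(4) * 0.5
        coords[:, 4:, 0] = np.arange(4) * 0.5 + 30.0
        ens = fz.Ensemble(top, coords, box_edge=100.0)
        prof = fz.domain_profile(ens, scope="inter")
        assert all(p == 0.0 for p, _ in prof.domain_matrix.values())

    def test_three_frame_hand_count(self):
        """Inter-molecular domain contact in exactly 1 of 3 frames -> pi = 1/3."""
        top = fz.simple_chain_topology(2, n_molecules=2, domains={"A": (1, 1), "B": (2, 2)})
        coords = np.zeros((3, 4, 3))
        coords[:, 1, 0] = 1.0  # chain geometry within each molecule
        coords[:, 3, 0] = 1.0
        coords[:, 2:, 1] = 20.0  # molecule 2 far away ...
        coords[1, 2:, 1] = 0.5  # ... except in frame 1
        ens = fz.Ensemble(top, coords, box_edge=100.0)
        prof = fz.domain_profile(ens, scope="inter")
        # frame 1: residue 1 of each molecule 0.5 nm apart (A-A contact), same
        # for residue 2 (B-B); the cross pairs sit at sqrt(1 + 0.25) > 0.7 nm
        assert prof.domain_matrix[("A", "A")][0] == pytest.approx(1 / 3)
        assert prof.domain_matrix[("A", "B")][0] == 0.0
        assert prof.domain_matrix[("B", "B")][0] == pytest.approx(1 / 3)

    def test_strand_probabilities_cover_member_residues(self, two_domain_small):
        top = two_domain_small.topology
        top.strands.update({"s1": (35, 40)})
        try:
            prof = fz.domain_profile(two_domain_small)
            p_strand = prof.strand_profiles[("s1", "NTD")]
            p_res = prof.residue_profiles["NTD"][34:40]
            assert p_strand >= p_res.max() - 1e-12
        finally:
            top.strands.clear()

    def test_missing_domains_rejected(self):
        top = fz.simple_chain_topology(5)
        top.domains.clear()
        ens = fz.Ensemble(top, np.zeros((2, 5, 3)))
        with pytest.raises(fz.TopologyError):
            fz.domain_profile(ens)


def _engineered_pair_ensemble(p_contact, n_frames, seed):
    """8-residue rod; residue 6 jumps next to residue 1 in a Bernoulli(p) subset."""
    rng = np.random.default_rng(seed)
    base = np.array([[k * 10.0, 0, 0] for k in range(8)], dtype=float)
    xyz = np.tile(base, (n_frames, 1, 1))
    hit = rng.random(n_frames) < p_contact
    xyz[hit, 5] = [0.5, 0.0, 0.0]
    return fz.Ensemble(fz.simple_chain_topology(8), xyz)


class TestCompareMaps:
    def test_map_vs_itself_has_no_significant_pairs(self, two_domain_small):
        cmap = fz.contact_probability_map(two_domain_small)
        cmp = fz.compare_maps(cmap, cmap)
        assert all(mask.sum() == 0 for mask in cmp.masks.values())

    def test_masks_are_nested(self):
        a = _engineered_pair_ensemble(0.3, 400, seed=81)
        b = _engineered_pair_ensemble(0.1, 400, seed=82)
        cmp = fz.compare_maps(
            fz.contact_probability_map(a), fz.contact_probability_map(b)
        )
        m005, m01, m05 = cmp.masks[0.005], cmp.masks[0.01], cmp.masks[0.05]
        assert (m005 <= m01).all() and (m01 <= m05).all()

    def test_engineered_difference_is_flagged(self):
        """A persistent Delta p = 0.2 difference must be caught at p < 0.005."""
        a = _engineered_pair_ensemble(0.3, 1000, seed=83)
        b = _engineered_pair_ensemble(0.1, 1000, seed=84)
        map_a, map_b = fz.contact_probability_map(a), fz.contact_probability_map(b)
        cmp = fz.compare_maps(map_a, map_b)
        sel = (cmp.i_idx == 0) & (cmp.j_idx == 5)
        assert cmp.masks[0.005][sel][0]
        assert cmp.delta[sel][0] == pytest.approx(0.2, abs=0.06)

    def test_anova_matches_scipy_f_oneway(self):
        a = _engineered_pair_ensemble(0.4, 500, seed=85)
        b = _engineered_pair_ensemble(0.25, 500, seed=86)
        map_a, map_b = fz.contact_probability_map(a), fz.contact_probability_map(b)
        cmp = fz.compare_maps(map_a, map_b)
        for k in range(map_a.p.size):
            ga, gb = map_a.block_means[:, k], map_b.block_means[:, k]
            if ga.std() == 0 and gb.std() == 0:
                continue
            expect = stats.f_oneway(ga, gb).pvalue
            assert cmp.p_values[k] == pytest.approx(expect, rel=1e-9)

    def test_too_few_blocks_rejected(self):
        ens = _engineered_pair_ensemble(0.5, 30, seed=87)
        cmap = fz.contact_probability_map(ens, n_blocks=1)
        with pytest.raises(ValueError):
            fz.compare_maps(cmap, cmap)
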