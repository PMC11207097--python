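"""Synthetic-ensemble generators: closed-form checks and seeding guarantees."""

import numpy as np
import pytest
from scipy import stats

import fuzzyens as fz


# ---------------------------------------------------------------------------
# freely jointed chain
# ---------------------------------------------------------------------------


class TestFJC:
    def test_all_bond_lengths_equal_b(self, fjc_medium):
        bonds = np.linalg.norm(np.diff(fjc_medium.xyz, axis=1), axis=2)
        assert np.abs(bonds - 0.55).max() < 1e-9

    def test_mean_squared_end_to_end(self):
        # <R_ee^2> = (n-1) b^2 for an ideal chain
        n, b, frames = 50, 0.55, 10_000
        ens = fz.generate_fjc(fz.ChainSpec(n_residues=n, bond_length=b, seed=5), frames)
        r2 = fz.metrics_series(ens).dee ** 2
        expected = (n - 1) * b**2
        # Var(R^2) = (n-1) b^4 * (2/3) * ... use empirical SE, 3 sigma
        se = r2.std(ddof=1) / np.sqrt(frames)
        assert abs(r2.mean() - expected) < 3 * se

    def test_same_seed_identical(self):
        spec = fz.ChainSpec(n_residues=12, seed=77)
        a = fz.generate_fjc(spec, 10)
        b = fz.generate_fjc(spec, 10)
        assert np.array_equal(a.xyz, b.xyz)

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            fz.generate_fjc(fz.ChainSpec(n_residues=10), 0)
        with pytest.raises(ValueError):
            fz.generate_fjc(fz.ChainSpec(n_residues=10, pair_well=-1.0), 5)


# ---------------------------------------------------------------------------
# Gaussian-chain end-to-end sampler
# ---------------------------------------------------------------------------


class TestGaussianDee:
    def test_mean_matches_analytic_moment(self):
        xi, n = 5.44, 50_000
        d = fz.sample_gaussian_dee(xi, n, seed=1)
        expected = 2 * xi / np.sqrt(np.pi)
        se = d.std(ddof=1) / np.sqrt(n)
        assert abs(d.mean() - expected) < 3 * se

    def test_samples_positive(self):
        assert (fz.sample_gaussian_dee(2.0, 1000, seed=2) > 0).all()

    def test_ks_distance_shrinks_with_n(self):
        xi = 3.0
        stats_by_n = []
        for n in (500, 50_000):
            d = fz.sample_gaussian_dee(xi, n, seed=3)
            ks = stats.kstest(d, lambda x: fz.gaussian_dee_cdf(x, xi))
            stats_by_n.append(ks.statistic)
        assert stats_by_n[1] < stats_by_n[0]
        # at n = 50k the empirical CDF should be within ~0.01 of the analytic one
        assert stats_by_n[1] < 0.01

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            fz.sample_gaussian_dee(0.0, 10)


# ---------------------------------------------------------------------------
# solvent-quality Monte Carlo chain
# ---------------------------------------------------------------------------


class TestSolventChain:
    def test_ideal_limit_is_theta_like(self, mc_ideal):
        curve = fz.scaling_curve(mc_ideal, mode="rms", distance="backbone")
        fit = fz.fit_flory(curve)
        assert fit.nu == pytest.approx(0.5, abs=0.02)

    def test_bonds_are_rigid(self, mc_ideal):
        bonds = np.linalg.norm(np.diff(mc_ideal.xyz, axis=1), axis=2)
        assert np.abs(bonds - 0.55).max() < 1e-9

    def test_strong_attraction_collapses(self):
        spec = fz.ChainSpec(
            n_residues=40, excluded_radius=0.3, pair_well=-1.5, sweeps=6, seed=204
        )
        ens = fz.generate_solvent_chain(spec, 150)
        fit = fz.fit_flory(fz.scaling_curve(ens, mode="rms", distance="backbone"))
        assert fit.nu < 0.45

    def test_repulsive_core_swells(self):
        spec = fz.ChainSpec(n_residues=40, excluded_radius=0.45, sweeps=6, seed=205)
        ens = fz.generate_solvent_chain(spec, 150)
        fit = fz.fit_flory(fz.scaling_curve(ens, mode="rms", distance="backbone"))
        assert fit.nu > 0.55

    def test_nu_monotone_in_attraction(self):
        """Deeper pairwise wells never swell the chain (solvent-quality scan)."""
        nus = []
        for k, eps in enumerate([0.0, -0.4, -0.8, -1.2, -1.6]):
            spec = fz.ChainSpec(
                n_residues=36, excluded_radius=0.3, pair_well=eps, sweeps=6, seed=300 + k
            )
            ens = fz.generate_solvent_chain(spec, 150)
            curve = fz.scaling_curve(ens, mode="rms", distance="backbone")
            nus.append(fz.fit_flory(curve).nu)
        assert all(a >= b - 0.02 for a, b in zip(nus, nus[1:])), nus

    def test_saved_frames_decorrelated(self, mc_ideal):
        rg = fz.metrics_series(mc_ideal).rg
        lag1 = np.corrcoef(rg[:-1], rg[1:])[0, 1]
        assert abs(lag1) < 0.2

    def test_seeded_reproducibility_bitwise(self):
        spec = fz.ChainSpec(n_residues=15, sweeps=3, seed=9)
        a = fz.generate_solvent_chain(spec, 20)
        b = fz.generate_solvent_chain(spec, 20)
        assert np.array_equal(a.xyz, b.xyz)

    def test_bad_sweep_count(self):
        with pytest.raises(ValueError):
            fz.generate_solvent_chain(fz.ChainSpec(n_residues=12, sweeps=0), 5)


# ---------------------------------------------------------------------------
# two-domain architecture
# ---------------------------------------------------------------------------


class TestTwoDomain:
    def test_domain_is_rigid(self, two_domain_small):
        from scipy.spatial.distance import pdist

        ens = two_domain_small
        ref = pdist(ens.xyz[0][30:])
        for k in (1, 40, 119):
            assert np.abs(pdist(ens.xyz[k][30:]) - ref).max() < 1e-6

    def test_domain_labels_fixed(self, two_domain_small):
        top = two_domain_small.topology
        assert top.domains == {"NTD": (1, 30), "CRD": (31, 70)}
        assert list(top.domain_residues("CRD")) == list(range(31, 71))

    def test_tail_matches_standalone_sampler(self, two_domain_small):
        """Same spec and seed: the tail sub-ensemble is the solvent-chain run."""
        spec = fz.ChainSpec(n_residues=30, sweeps=6, seed=8)
        standalone = fz.generate_solvent_chain(spec, 120)
        assert np.array_equal(two_domain_small.xyz[:, :30, :], standalone.xyz)

    def test_missing_tether_rejected(self):
        template = fz.make_domain_template(n_residues=10, radius=1.0, seed=1)
        spec = fz.ChainSpec(n_residues=12, sweeps=2, seed=2)
        with pytest.raises(ValueError, match="tether"):
            fz.generate_two_domain(12, template, spec, 3, tether_index=10)


# ---------------------------------------------------------------------------
# periodic boxes
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def packed(two_domain_small):
    box = fz.BoxSpec(box_edge=20.0, n_molecules=6, tolerance=0.4, seed=11)
    return fz.generate_box(two_domain_small, box, 10)


class TestBox:
    def test_molecule_count_and_box(self, packed):
        assert packed.topology.n_molecules == 6
        assert np.allclose(packed.box_edges, 20.0)

    def test_min_separation_respected(self, packed):
        from itertools import combinations

        from fuzzyens._distances import minimum_image_diffs

        for frame in packed:
            for ma, mb in combinations(range(6), 2):
                d = np.linalg.norm(
                    minimum_image_diffs(
                        frame.molecule_coords(ma), frame.molecule_coords(mb), 20.0
                    ),
                    axis=2,
                )
                assert d.min() >= 0.4

    def test_single_molecule_preserves_internal_distances(self, two_domain_small):
        from scipy.spatial.distance import pdist

        box = fz.BoxSpec(box_edge=30.0, n_molecules=1, seed=13)
        packed = fz.generate_box(two_domain_small, box, 5)
        src = two_domain_small.molecule_xyz(0)
        src_d = {tuple(np.round(pdist(x), 6)): None for x in src}
        for frame in packed:
            key = tuple(np.round(pdist(frame.molecule_coords(0)), 6))
            assert key in src_d  # rigid motion of one of the source frames

    def test_impossible_packing_raises(self, two_domain_small):
        box = fz.BoxSpec(box_edge=4.0, n_molecules=6, tolerance=2.0, seed=14, max_attempts=20)
        with pytest.raises(fz.PackingError):
            fz.generate_box(two_domain_small, box, 1)


# ---------------------------------------------------------------------------
# synthetic reference scattering
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def model():
    q = np.linspace(0.0, 3.0, 120)
    return fz.ScatteringProfile(q=q, intensity=100.0 * fz.debye_function(q**2 * 4.0))


class TestReferenceSaxs:
    def test_zero_noise_is_exact_affine(self, model):
        ref = fz.generate_reference_saxs(model, a=2.0, b_offset=5.0, noise_level=0.0, seed=1)
        assert np.allclose(ref.intensity, 2.0 * model.intensity + 5.0)

    def test_chi2_of_generating_model_near_one(self, model):
        ref = fz.generate_reference_saxs(model, a=3.0, b_offset=1.0, noise_level=0.03, seed=2)
        fit = fz.chi2_fit(ref, model)
        n = model.n_points
        assert abs(fit.chi2 - 1.0) < 3 * np.sqrt(2.0 / n)

    def test_seeded_reproducibility(self, model):
        a = fz.generate_reference_saxs(model, noise_level=0.05, seed=3)
        b = fz.generate_reference_saxs(model, noise_level=0.05, seed=3)
        assert np.array_equal(a.intensity, b.intensity)

    def test_negative_noise_rejected(self, model):
        with pytest.raises(ValueError):
            fz.generate_reference_saxs(model, noise_level=-0.1)
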