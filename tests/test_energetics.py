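"""Energy terms against closed forms and brute-force oracles."""

import numpy as np
import pytest

from httscan import (
    EnergyModelConfig,
    SolvationConfig,
    build_ideal_helix,
    coulomb_energy,
    delta_e,
    lj_energy,
    minimize,
    sasa,
    solvation_energy,
    total_energy,
)
from httscan.energetics import COULOMB_CONSTANT, register_solvation_model

from conftest import AtomCloud, random_rotation

NO_CUTOFF = EnergyModelConfig(cutoff=1e6)


def separated_cloud(rng, n, lo=2.0, box=12.0):
    """Random coordinates with a minimum pairwise separation (keeps LJ finite)."""
    pts = []
    while len(pts) < n:
        cand = rng.uniform(0, box, size=3)
        if all(np.linalg.norm(cand - p) >= lo for p in pts):
            pts.append(cand)
    return np.array(pts)


def brute_force_lj(cloud, cutoff=np.inf):
    """Independent all-pairs double loop (Lorentz-Berthelot combining)."""
    e = 0.0
    n = cloud.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            r = np.linalg.norm(cloud.coords[i] - cloud.coords[j])
            if r > cutoff:
                continue
            sig = 0.5 * (cloud.lj_sigma[i] + cloud.lj_sigma[j])
            eps = np.sqrt(cloud.lj_epsilon[i] * cloud.lj_epsilon[j])
            e += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
    return e


def brute_force_coulomb(cloud, cutoff=np.inf, k=COULOMB_CONSTANT, eps_r=1.0):
    e = 0.0
    n = cloud.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            r = np.linalg.norm(cloud.coords[i] - cloud.coords[j])
            if r > cutoff:
                continue
            e += k * cloud.partial_charges[i] * cloud.partial_charges[j] / (eps_r * r)
    return e


class TestLennardJones:
    def test_pair_at_minimum_gives_minus_epsilon(self):
        r = 3.5 * 2 ** (1 / 6)
        cloud = AtomCloud([[0, 0, 0], [r, 0, 0]], sigma=3.5, epsilon=0.2)
        assert lj_energy(cloud) == pytest.approx(-0.2, abs=1e-12)

    def test_pair_beyond_cutoff_is_zero(self):
        cloud = AtomCloud([[0, 0, 0], [11, 0, 0]])
        assert lj_energy(cloud, EnergyModelConfig(cutoff=10.0)) == 0.0

    def test_matches_brute_force_on_random_clouds(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 31))
            cloud = AtomCloud(
                separated_cloud(rng, n),
                sigma=rng.uniform(2.5, 4.0, size=n),
                epsilon=rng.uniform(0.05, 0.4, size=n),
            )
            assert lj_energy(cloud, NO_CUTOFF) == pytest.approx(
                brute_force_lj(cloud), abs=1e-10
            )
            assert lj_energy(cloud, EnergyModelConfig(cutoff=6.0)) == pytest.approx(
                brute_force_lj(cloud, cutoff=6.0), abs=1e-10
            )

    def test_zero_distance_names_atom_pair(self):
        cloud = AtomCloud([[0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError, match="X0.*X1"):
            lj_energy(cloud)

    def test_invariant_under_atom_reordering(self, rng):
        coords = separated_cloud(rng, 12, box=8.0)
        q = rng.normal(size=12)
        cloud = AtomCloud(coords, charges=q)
        perm = rng.permutation(12)
        shuffled = AtomCloud(coords[perm], charges=q[perm])
        assert lj_energy(cloud, NO_CUTOFF) == pytest.approx(
            lj_energy(shuffled, NO_CUTOFF), abs=1e-10
        )
        assert coulomb_energy(cloud, NO_CUTOFF) == pytest.approx(
            coulomb_energy(shuffled, NO_CUTOFF), abs=1e-10
        )


class TestCoulomb:
    def test_unit_charges_closed_form(self):
        r = COULOMB_CONSTANT / 100.0  # 3.320636 A
        cloud = AtomCloud([[0, 0, 0], [r, 0, 0]], charges=[1.0, -1.0])
        assert coulomb_energy(cloud) == pytest.approx(-100.0, abs=1e-9)

    def test_zero_charges_give_zero(self, rng):
        cloud = AtomCloud(rng.uniform(0, 5, size=(8, 3)))
        assert coulomb_energy(cloud, NO_CUTOFF) == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 31))
            cloud = AtomCloud(
                separated_cloud(rng, n, box=10.0), charges=rng.normal(size=n)
            )
            assert coulomb_energy(cloud, NO_CUTOFF) == pytest.approx(
                brute_force_coulomb(cloud), abs=1e-10
            )


class TestRigidMotionInvariance:
    def test_all_terms_invariant(self, rng):
        peptide = build_ideal_helix("MKDFE")
        ref = total_energy(peptide)
        for _ in range(3):
            rot = random_rotation(rng)
            shift = rng.uniform(-20, 20, size=3)
            moved = peptide.with_coords(peptide.coords @ rot.T + shift)
            out = total_energy(moved)
            assert out.lj == pytest.approx(ref.lj, abs=1e-8)
            assert out.coulomb == pytest.approx(ref.coulomb, abs=1e-8)
            assert out.solvation == pytest.approx(ref.solvation, abs=1e-8)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        cloud = AtomCloud([[0, 0, 0]], vdw=1.7)
        area = sasa(cloud, probe_radius=1.4)
        expected = 4 * np.pi * 3.1**2  # 120.76 A^2
        assert area.sum() == pytest.approx(expected, rel=0.02)

    def test_fully_caged_atom_is_buried(self):
        # icosahedral-ish cage of large spheres around a small one
        dirs = []
        phi = (1 + 5**0.5) / 2
        for a in (-1, 1):
            for b in (-phi, phi):
                dirs += [(0, a, b), (a, b, 0), (b, 0, a)]
        dirs = np.array(dirs, dtype=float)
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        coords = np.vstack([[0, 0, 0], dirs * 3.0])
        cloud = AtomCloud(coords, vdw=[1.7] + [2.5] * len(dirs))
        area = sasa(cloud, probe_radius=1.4)
        assert area[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_overlapping_spheres_match_grid_oracle(self):
        # analytic/grid reference: accessible fraction of sphere 1 of radius
        # R1 partially covered by sphere 2 of radius R2 at distance d
        r1, r2, d = 3.1, 2.9, 4.0
        cloud = AtomCloud([[0, 0, 0], [d, 0, 0]], vdw=[r1 - 1.4, r2 - 1.4])
        area = sasa(cloud, probe_radius=1.4, n_sphere_points=5000)
        # fine lat-long grid integration over sphere 1
        n_theta = 2000
        theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
        ring_area = 2 * np.pi * r1**2 * np.sin(theta) * (np.pi / n_theta)
        z = r1 * np.cos(theta)
        x = r1 * np.sin(theta)
        dist2 = (x - d) ** 2 + z**2  # rotational symmetry about the x-axis
        # fraction of each ring outside sphere 2 (rings are at constant angle
        # from the inter-center axis, so coverage is all-or-nothing per ring)
        pts_dist2 = (x * np.cos(0) - d) ** 2 + (x * np.sin(0)) ** 2 + z**2
        # grid over azimuth for partial rings
        n_phi = 720
        phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
        exposed = 0.0
        for t_i in range(n_theta):
            px = r1 * np.sin(theta[t_i]) * np.cos(phi)
            py = r1 * np.sin(theta[t_i]) * np.sin(phi)
            pz = np.full(n_phi, r1 * np.cos(theta[t_i]))
            outside = (px - d) ** 2 + py**2 + pz**2 >= r2**2
            exposed += ring_area[t_i] * outside.mean()
        assert area[0] == pytest.approx(exposed, rel=0.02)


class TestSolvation:
    def test_zero_parameters_give_zero(self, rng):
        cloud = AtomCloud(rng.uniform(0, 6, size=(5, 3)), solvation=0.0)
        assert solvation_energy(cloud) == 0.0

    def test_single_atom_equals_param_times_area(self):
        cloud = AtomCloud([[0, 0, 0]], solvation=0.016, vdw=1.7)
        expected = 0.016 * 4 * np.pi * 3.1**2
        assert solvation_energy(cloud) == pytest.approx(expected, rel=0.02)

    def test_burial_lowers_positive_param_solvation(self):
        # same pair, one conformation close (partly buried), one far apart
        exposed = AtomCloud([[0, 0, 0], [50, 0, 0]], solvation=0.016)
        buried = AtomCloud([[0, 0, 0], [2.0, 0, 0]], solvation=0.016)
        assert solvation_energy(buried) < solvation_energy(exposed)

    def test_unknown_model_lists_backends(self):
        cloud = AtomCloud([[0, 0, 0]])
        with pytest.raises(ValueError, match="sasa"):
            solvation_energy(cloud, SolvationConfig(model="pbl"))

    def test_registered_backend_is_dispatched(self):
        register_solvation_model("null", lambda peptide, config: 42.0)
        cloud = AtomCloud([[0, 0, 0]])
        assert solvation_energy(cloud, SolvationConfig(model="null")) == 42.0


class TestTotalEnergy:
    def test_breakdown_sums_exactly(self):
        peptide = build_ideal_helix("MKE")
        config = EnergyModelConfig()
        out = total_energy(peptide, config)
        assert out.total == out.lj + out.coulomb + out.solvation
        assert out.lj == pytest.approx(lj_energy(peptide, config), abs=1e-12)
        assert out.coulomb == pytest.approx(coulomb_energy(peptide, config), abs=1e-12)

    def test_neutral_nonpolar_pair_is_pure_lj(self):
        cloud = AtomCloud([[0, 0, 0], [4, 0, 0]], solvation=0.0)
        out = total_energy(cloud)
        assert out.total == pytest.approx(out.lj)
        assert out.coulomb == 0.0 and out.solvation == 0.0

    def test_native_breakdown_is_deterministic(self):
        peptide = build_ideal_helix("MATLEKLMKAFESLKSF")
        a = total_energy(peptide)
        b = total_energy(peptide)
        assert (a.lj, a.coulomb, a.solvation) == (b.lj, b.coulomb, b.solvation)


class TestDeltaE:
    def test_identity_and_arithmetic(self):
        assert delta_e(-480.0, -480.0) == 0.0
        assert delta_e(-500.0, -480.0) == -20.0  # stabilizing


class TestMinimize:
    def test_already_minimal_pair_unchanged(self):
        r = 3.5 * 2 ** (1 / 6)
        cloud = AtomCloud([[0, 0, 0], [r, 0, 0]], sigma=3.5, epsilon=0.2)
        res = minimize(cloud, max_steps=50, force_tol=1e-3,
                       backbone_fixed=False, full_output=True,
                       track_solvation=False)
        assert res.n_steps == 0
        assert np.array_equal(res.peptide.coords, cloud.coords)

    def test_compressed_pair_relaxes_to_lj_minimum(self):
        cloud = AtomCloud([[0, 0, 0], [0.9 * 3.5, 0, 0]], sigma=3.5, epsilon=0.2)
        res = minimize(cloud, max_steps=500, force_tol=1e-5,
                       backbone_fixed=False, full_output=True,
                       track_solvation=False)
        r = np.linalg.norm(res.peptide.coords[1] - res.peptide.coords[0])
        assert r == pytest.approx(3.5 * 2 ** (1 / 6), abs=1e-3)

    def test_energy_monotone_over_accepted_steps(self):
        from httscan import MutationSpec, apply_mutation

        peptide = apply_mutation(
            build_ideal_helix("MATLEKLM"), MutationSpec.parse("L4W")
        )
        res = minimize(peptide, max_steps=60, full_output=True,
                       track_solvation=False)
        assert res.n_steps > 0
        assert np.all(np.diff(res.energies) <= 0)
        assert res.energies[-1] <= res.energies[0]

    def test_total_energy_monotone_with_solvation_tracking(self):
        from httscan import MutationSpec, apply_mutation

        peptide = apply_mutation(
            build_ideal_helix("MKAF"), MutationSpec.parse("A3W")
        )
        res = minimize(peptide, max_steps=15, full_output=True,
                       track_solvation=True)
        assert np.all(np.diff(res.totals) <= 1e-12)

    def test_backbone_fixed_keeps_backbone(self):
        peptide = build_ideal_helix("MKF")
        res = minimize(peptide, max_steps=30, full_output=True,
                       track_solvation=False)
        mask = peptide.backbone_mask()
        assert np.array_equal(res.peptide.coords[mask], peptide.coords[mask])
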