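"""Energy terms vs brute-force oracles, forces, MD-input export."""

import math

import numpy as np
import pytest

import _oracles as orc
from ndbkit.michrom_model import (
    ChromosomeSystem,
    MiChroMParameters,
    confinement_radius_for,
    contact_kernel,
    contact_kernel_derivative,
    energy_bonded,
    energy_breakdown,
    energy_confinement,
    energy_ideal_chromosome,
    energy_loops,
    energy_type_to_type,
    export_md_inputs,
    fene_energy,
    forces,
    initial_conformation,
    parse_top,
    total_energy,
)
from ndbkit.ndb_io import LoopEntry, read_gro


@pytest.fixture
def params():
    return MiChroMParameters()


def random_config(n, rng, scale=1.2):
    """Loose chain configuration with bonds inside the FENE range."""
    steps = rng.normal(size=(n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    steps *= rng.uniform(0.8, scale, size=(n - 1, 1))
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])


class TestContactKernel:
    def test_half_at_rc(self, params):
        assert contact_kernel(params.contact_rc, params.contact_mu,
                              params.contact_rc) == pytest.approx(0.5)

    def test_monotone_limits(self, params):
        mu, rc = params.contact_mu, params.contact_rc
        f0, frc, ffar = (contact_kernel(r, mu, rc) for r in (0.0, rc, 10 * rc))
        assert f0 > frc > ffar
        assert f0 > 0.999 and ffar < 1e-3

    def test_nonpositive_derivative_on_grid(self, params):
        r = np.linspace(0, 6, 500)
        f = contact_kernel(r, params.contact_mu, params.contact_rc)
        assert np.all(np.diff(f) <= 0)
        num = np.gradient(f, r)
        ana = contact_kernel_derivative(r, params.contact_mu, params.contact_rc)
        assert np.all(ana <= 0)
        assert np.allclose(num[1:-1], ana[1:-1], atol=1e-3)

    def test_negative_distance_rejected(self, params):
        with pytest.raises(ValueError):
            contact_kernel(-0.1, params.contact_mu, params.contact_rc)


class TestBonded:
    def test_fene_zero_at_origin(self, params):
        assert fene_energy(0.0, params.fene_k, params.fene_r0) == 0.0

    def test_fene_diverges_near_r0(self, params):
        e = fene_energy(params.fene_r0 * (1 - 1e-6), params.fene_k,
                        params.fene_r0)
        assert e > 100.0

    def test_overstretch_names_the_bond(self, params):
        x = np.zeros((3, 3))
        x[1, 0] = 1.0
        x[2, 0] = 1.0 + params.fene_r0 + 0.1
        with pytest.raises(ValueError, match="bond 1-2"):
            energy_bonded(x, params)

    def test_five_bead_chain_matches_per_bond_closed_form(self, params, rng):
        x = random_config(5, rng)
        assert energy_bonded(x, params) == pytest.approx(
            orc.energy_bonded_bf(x, params), rel=1e-12)


class TestConfinement:
    def test_zero_inside(self, params):
        assert energy_confinement(np.zeros((4, 3)), params) == 0.0

    def test_closed_form_one_unit_outside(self, params):
        x = np.array([[params.confinement_radius + 1.0, 0.0, 0.0]])
        assert energy_confinement(x, params) == pytest.approx(
            params.confinement_k)

    def test_force_points_radially_inward(self, params):
        system = ChromosomeSystem(bead_types=[6], parameters=params)
        x = np.array([[params.confinement_radius + 0.5, 0.2, -0.1]])
        F = forces(system, x)
        # force anti-parallel to the position vector
        assert float(F[0] @ x[0]) < 0
        cosang = F[0] @ x[0] / (np.linalg.norm(F[0]) * np.linalg.norm(x[0]))
        assert cosang == pytest.approx(-1.0, abs=1e-10)


class TestIdealChromosome:
    def test_invariant_under_type_permutation(self, params, rng):
        x = random_config(15, rng)
        assert energy_ideal_chromosome(x, params) == energy_ideal_chromosome(
            x, params)  # type-independent by construction: no types passed

    def test_equal_separation_equal_distance_equal_contribution(self, params):
        # isolate two pairs: (0,3) and (5,8), same |i-j| and same r
        p = MiChroMParameters(ideal_d_min=3, ideal_d_max=3)
        x = np.zeros((9, 3))
        far = 100.0
        for i in range(9):
            x[i] = [i * far, 0, 0]
        x[3] = x[0] + [1.0, 0, 0]
        x[8] = x[5] + [1.0, 0, 0]
        e = energy_ideal_chromosome(x[[0, 1, 2, 3]], p)
        e2 = energy_ideal_chromosome(x[[5, 6, 7, 8]], p)
        assert e == pytest.approx(e2)

    def test_brute_force_oracle_20_beads(self, params, rng):
        x = random_config(20, rng)
        assert energy_ideal_chromosome(x, params) == pytest.approx(
            orc.energy_ideal_bf(x, params), rel=1e-12)


class TestTypeToType:
    def test_distant_pair_negligible(self, params):
        x = np.array([[0, 0, 0], [50, 0, 0], [100, 0, 0.0]])
        assert abs(energy_type_to_type(x, [0, 0, 0], params)) < 1e-6

    def test_homotypic_contact_is_attractive(self, params):
        x = np.array([[0, 0, 0], [100, 0, 0], [1.3, 0, 0.0]])
        e = energy_type_to_type(x, [0, 6, 0], params)  # A1...A1 in contact
        assert e < 0

    def test_brute_force_oracle_15_beads(self, params, rng):
        x = random_config(15, rng)
        types = rng.integers(0, 7, size=15)
        assert energy_type_to_type(x, types, params) == pytest.approx(
            orc.energy_type_bf(x, types, params), rel=1e-12)

    def test_unknown_type_index_rejected(self, params):
        with pytest.raises(ValueError, match="unknown"):
            energy_type_to_type(np.zeros((3, 3)), [0, 9, 0], params)

    def test_type_term_not_permutation_invariant(self, params, rng):
        """Distinguishing check: relabeling types changes the type term but
        never the ideal-chromosome term."""
        x = random_config(12, rng)
        types = np.array([0, 0, 0, 0, 2, 2, 2, 2, 0, 0, 2, 2])
        swapped = types[::-1].copy()
        e_ideal = energy_ideal_chromosome(x, params)
        assert energy_ideal_chromosome(x, params) == e_ideal
        assert energy_type_to_type(x, types, params) != pytest.approx(
            energy_type_to_type(x, swapped, params))


class TestLoops:
    def test_empty_loop_list(self, params):
        assert energy_loops(np.zeros((5, 3)), [], params) == 0.0

    def test_coincident_anchors_closed_form(self, params):
        x = np.zeros((4, 3))
        e = energy_loops(x, [LoopEntry(1, 3)], params)
        f0 = contact_kernel(0.0, params.contact_mu, params.contact_rc)
        assert e == pytest.approx(params.loop_chi * float(f0))

    def test_duplicates_deduplicated_with_warning(self, params, rng):
        x = random_config(8, rng)
        one = energy_loops(x, [LoopEntry(2, 6)], params)
        with pytest.warns(UserWarning, match="duplicate"):
            two = energy_loops(x, [LoopEntry(2, 6), LoopEntry(6, 2)], params)
        assert two == pytest.approx(one)

    def test_brute_force_oracle(self, params, rng):
        x = random_config(10, rng)
        loops = [LoopEntry(1, 5), LoopEntry(3, 9, "POLYCOMB")]
        assert energy_loops(x, loops, params) == pytest.approx(
            orc.energy_loops_bf(x, loops, params), rel=1e-12)


class TestTotalEnergy:
    def test_single_bead_at_origin(self, params):
        system = ChromosomeSystem(bead_types=[6], parameters=params)
        assert total_energy(system, np.zeros((1, 3))) == 0.0

    def test_additivity_of_terms(self, rng):
        system = ChromosomeSystem(
            bead_types=rng.integers(0, 6, 10),
            loops=[LoopEntry(1, 7)],
        )
        x = random_config(10, rng)
        bd = energy_breakdown(system, x)
        assert total_energy(system, x) == pytest.approx(sum(bd.values()))

    def test_isometry_invariance(self, rng):
        system = ChromosomeSystem(bead_types=rng.integers(0, 6, 12))
        x = random_config(12, rng)
        # random rotation about the confinement center
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        assert total_energy(system, x @ q.T) == pytest.approx(
            total_energy(system, x), rel=1e-10)


def test_forces_match_numeric_gradient(rng):
    system = ChromosomeSystem(
        bead_types=rng.integers(0, 6, 12), loops=[LoopEntry(2, 10)]
    )
    x = random_config(12, rng)
    F = forces(system, x)
    h = 1e-6
    for i, j in [(0, 0), (5, 1), (11, 2), (3, 0)]:
        xp, xm = x.copy(), x.copy()
        xp[i, j] += h
        xm[i, j] -= h
        num = -(total_energy(system, xp) - total_energy(system, xm)) / (2 * h)
        assert F[i, j] == pytest.approx(num, rel=1e-5, abs=1e-7)


class TestParameters:
    def test_asymmetric_type_matrix_rejected(self):
        m = np.zeros((7, 7))
        m[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            MiChroMParameters(type_matrix=m).validate()

    def test_d_min_below_three_rejected(self):
        with pytest.raises(ValueError, match="d_min"):
            MiChroMParameters(ideal_d_min=2).validate()

    def test_config_round_trip(self, tmp_path, params):
        path = params.save(tmp_path / "params.yaml")
        loaded = MiChroMParameters.load(path)
        assert loaded.fene_k == params.fene_k
        assert np.array_equal(loaded.type_matrix, params.type_matrix)
        assert loaded.ideal_gamma == params.ideal_gamma


class TestInitialConformation:
    def test_deterministic(self):
        a = initial_conformation(50, 5.0, seed=3)
        b = initial_conformation(50, 5.0, seed=3)
        assert np.array_equal(a, b)

    def test_inside_sphere_and_bond_range(self, params):
        x = initial_conformation(100, confinement_radius_for(100), seed=1)
        assert np.all(np.linalg.norm(x, axis=1) < confinement_radius_for(100))
        bonds = np.linalg.norm(np.diff(x, axis=0), axis=1)
        assert np.all(bonds < params.fene_r0)

    def test_cannot_fit_raises(self):
        with pytest.raises(ValueError, match="cannot fit"):
            initial_conformation(10_000, 2.0, seed=0)


class TestMdExport:
    @pytest.fixture
    def exported(self, tmp_path, rng):
        system = ChromosomeSystem(
            bead_types=np.array([0, 0, 2, 2, 6, 1, 1, 3]),
            loops=[LoopEntry(1, 6, "COHESIN"), LoopEntry(2, 8, "POLYCOMB")],
        )
        x = initial_conformation(8, system.parameters.confinement_radius, 4)
        files = export_md_inputs(system, x, tmp_path / "md")
        return system, x, files

    def test_table_b1_matches_confinement_closed_form(self, exported):
        system, _, files = exported
        p = system.parameters
        d, u = np.loadtxt(files["table_b1"]).T
        probe = p.confinement_radius + 1.0
        assert np.interp(probe, d, u) == pytest.approx(p.confinement_k,
                                                       rel=1e-5)

    def test_tables_reproduce_energy_terms_off_grid(self, exported):
        from scipy.interpolate import CubicSpline

        system, _, files = exported
        p = system.parameters
        r_probe = np.array([0.37111, 0.95313, 1.23457, 1.78, 2.41999])
        # bonded table = FENE + steric
        rb, ub = np.loadtxt(files["table_b0"]).T
        sp = CubicSpline(rb, ub)
        for r in r_probe[r_probe < p.fene_r0 * 0.99]:
            expect = orc.fene(r, p.fene_k, p.fene_r0) + orc.steric(
                r, p.steric_epsilon, p.steric_sigma, p.steric_ecut)
            assert float(sp(r)) == pytest.approx(expect, rel=1e-6, abs=1e-6)
        # contact-kernel tables
        for key in ("table_b2", "tablep"):
            rt, ft = np.loadtxt(files[key]).T
            spf = CubicSpline(rt, ft)
            for r in r_probe:
                assert float(spf(r)) == pytest.approx(
                    orc.kernel(r, p.contact_mu, p.contact_rc),
                    rel=1e-6, abs=1e-9)
        # type table: steric column + kernel column
        rt, ust, ft = np.loadtxt(files["table"]).T
        sps, spf = CubicSpline(rt, ust), CubicSpline(rt, ft)
        for r in r_probe:
            assert float(sps(r)) == pytest.approx(
                orc.steric(r, p.steric_epsilon, p.steric_sigma,
                           p.steric_ecut), rel=1e-6, abs=1e-6)
            assert float(spf(r)) == pytest.approx(
                orc.kernel(r, p.contact_mu, p.contact_rc), rel=1e-6, abs=1e-9)

    def test_gro_atom_count_and_types(self, exported):
        system, _, files = exported
        xyz, labels = read_gro(files["gro"])
        assert len(xyz) == system.n_beads
        assert labels == system.type_labels()

    def test_top_round_trip_recovers_loops(self, exported):
        system, _, files = exported
        top = parse_top(files["top"])
        assert top["loops"] == system.dedup_loops()
        assert np.array_equal(top["bead_types"], system.bead_types)
        assert top["parameters"]["loop_chi"] == system.parameters.loop_chi

    def test_outside_confinement_warns(self, tmp_path):
        system = ChromosomeSystem(bead_types=np.zeros(3, dtype=int))
        x = np.array([[0, 0, 0], [1, 0, 0],
                      [system.parameters.confinement_radius + 5, 0, 0.0]])
        with pytest.warns(UserWarning, match="outside"):
            export_md_inputs(system, x, tmp_path / "md2")
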