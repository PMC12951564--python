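import numpy as np
import pytest

from glycotraj import builder, electrostatics as es
from glycotraj.model import Atom, Frame, Topology, Trajectory


def _point_charges(charges, positions):
    atoms = [
        Atom(i, f"Q{i}", "C", i, "ION", "A", charge=q, mass=12.0)
        for i, q in enumerate(charges)
    ]
    return Topology(atoms=atoms), Frame(np.asarray(positions, float))


class TestGroupDipole:
    def test_rigid_water_model_value(self, chain6):
        """Fixed 3-site geometry/charges give the classic ~2.35 D dipole."""
        top, frame = builder.place_waters(chain6, 1, mode="shell", seed=0)
        idx = np.array([a.index for a in top.atoms if a.is_water])
        rec = es.group_dipole(frame, top, idx)
        assert 2.34 <= rec.mu_mag <= 2.35
        assert rec.net_charge == pytest.approx(0.0, abs=1e-12)

    def test_unit_conversion_constant(self):
        top, frame = _point_charges([1.0, -1.0], [[0.0, 0, 0], [1.0, 0, 0]])
        rec = es.group_dipole(frame, top, np.array([0, 1]))
        assert rec.mu_mag == pytest.approx(4.803205, abs=1e-6)
        assert rec.mu_vec[0] == pytest.approx(-4.803205, abs=1e-6)

    def test_zero_charges_warn_and_zero(self):
        top, frame = _point_charges([0.0, 0.0], [[0.0, 0, 0], [1.0, 0, 0]])
        with pytest.warns(UserWarning):
            rec = es.group_dipole(frame, top, np.array([0, 1]))
        assert rec.mu_mag == 0.0

    def test_origin_invariance_for_neutral_group(self, chain6, rng):
        top, frame = builder.place_waters(chain6, 1, mode="shell", seed=1)
        idx = np.array([a.index for a in top.atoms if a.is_water])
        ref = es.group_dipole(frame, top, idx).mu_vec
        for _ in range(10):
            shifted = Frame(frame.coordinates + rng.normal(scale=50.0, size=3))
            mu = es.group_dipole(shifted, top, idx).mu_vec
            assert np.abs(mu - ref).max() < 1e-10

    def test_aux_site_included_as_point_charge(self, chain6):
        top, frame = builder.place_waters(chain6, 1, mode="shell", seed=1, water_model="3-site+aux")
        widx = np.array([a.index for a in top.atoms if a.is_water])
        rec = es.group_dipole(frame, top, widx)
        no_aux = np.array([i for i in widx if not top.atoms[i].is_auxiliary])
        rec2 = es.group_dipole(frame, top, no_aux)
        assert rec.mu_mag != pytest.approx(rec2.mu_mag, abs=1e-3)


class TestAlignAxis:
    def _rod(self, direction, n=30, jitter=0.05):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 20, n)
        coords = np.outer(t, direction) + rng.normal(scale=jitter, size=(n, 3))
        atoms = [Atom(i, "C1", "C", i, "GLC", "A", mass=12.0) for i in range(n)]
        return Trajectory(topology=Topology(atoms=atoms), frames=[Frame(coords)])

    def test_z_rod_maps_to_x(self):
        traj = self._rod(np.array([0.0, 0, 1.0]))
        aligned, _ = es.align_axis(traj, "A")
        xyz = aligned.frames[0].coordinates
        assert np.ptp(xyz[:, 0]) > 19.0
        assert max(np.ptp(xyz[:, 1]), np.ptp(xyz[:, 2])) < 1.0

    def test_polarity_reducing_end_at_low_x(self):
        traj = self._rod(np.array([-1.0, 0, 0]))  # residue 1 at x=0, last at x=-20
        aligned, _ = es.align_axis(traj, "A")
        xyz = aligned.frames[0].coordinates
        assert xyz[0, 0] < xyz[-1, 0]

    def test_aligned_rod_near_identity(self):
        traj = self._rod(np.array([1.0, 0, 0]))
        aligned, recs = es.align_axis(traj, "A")
        rot = recs[0]["rotation"]
        assert np.abs(rot - np.eye(3)).max() < 0.05

    def test_whole_system_rotated_rigidly(self, chain12):
        top, frame = builder.place_waters(chain12, 5, mode="cavity", seed=3)
        traj = Trajectory(topology=top, frames=[frame])
        aligned, _ = es.align_axis(traj, "A")
        # internal distances preserved for every atom incl. waters
        d0 = np.linalg.norm(frame.coordinates[0] - frame.coordinates[-1])
        d1 = np.linalg.norm(aligned.frames[0].coordinates[0] - aligned.frames[0].coordinates[-1])
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestElectricField:
    def test_single_charge_at_10A(self):
        top, frame = _point_charges([1.0], [[0.0, 0, 0]])
        e = es.electric_field(np.array([10.0, 0, 0]), frame, top, np.array([0]))
        assert e[0] == pytest.approx(14.39964, abs=1e-4)
        assert abs(e[1]) < 1e-12 and abs(e[2]) < 1e-12

    def test_superposition_exact(self, rng):
        top, frame = _point_charges(
            rng.uniform(-1, 1, 6), rng.normal(scale=5, size=(6, 3))
        )
        pt = np.array([20.0, 3.0, -4.0])
        total = es.electric_field(pt, frame, top, np.arange(6))
        parts = es.electric_field(pt, frame, top, np.arange(3)) + es.electric_field(
            pt, frame, top, np.arange(3, 6)
        )
        assert np.abs(total - parts).max() < 1e-12

    def test_midpoint_symmetry(self):
        top, frame = _point_charges([1.0, 1.0], [[-5.0, 0, 0], [5.0, 0, 0]])
        e = es.electric_field(np.zeros(3), frame, top, np.array([0, 1]))
        assert np.abs(e).max() < 1e-12

    def test_inverse_square_decay_slope(self):
        top, frame = _point_charges([1.0], [[0.0, 0, 0]])
        r = np.linspace(2.0, 50.0, 40)
        mags = [
            np.linalg.norm(es.electric_field(np.array([ri, 0, 0]), frame, top, np.array([0])))
            for ri in r
        ]
        slope = np.polyfit(np.log(r), np.log(mags), 1)[0]
        assert slope == pytest.approx(-2.00, abs=0.01)

    def test_rotation_equivariance(self, rng):
        from tests.test_conformation import _random_rigid

        top, frame = _point_charges(rng.uniform(-1, 1, 5), rng.normal(scale=4, size=(5, 3)))
        pt = np.array([8.0, 1.0, 2.0])
        e0 = es.electric_field(pt, frame, top, np.arange(5))
        rot, _ = _random_rigid(rng)
        moved = Frame(frame.coordinates @ rot.T)
        e1 = es.electric_field(rot @ pt, moved, top, np.arange(5))
        assert np.abs(e1 - rot @ e0).max() < 1e-9

    def test_point_on_atom_rejected(self):
        top, frame = _point_charges([1.0], [[0.0, 0, 0]])
        with pytest.raises(ValueError, match="source atom"):
            es.electric_field(np.array([1e-5, 0, 0]), frame, top, np.array([0]))


class TestAxisPoints:
    def test_24_points_for_12mer(self, chain12):
        top, frame = chain12
        traj = Trajectory(topology=top, frames=[frame])
        aligned, _ = es.align_axis(traj, "A")
        pts = es.axis_points(aligned.frames[0], top, "A")
        assert pts.shape == (24, 3)
        assert np.all(np.diff(pts[:12, 0]) >= 0)  # ordered from the reducing end

    def test_equidistant_spacing(self):
        atoms = [Atom(i, "C1", "C", i, "GLC", "A", mass=12.0) for i in range(6)]
        top = Topology(atoms=atoms)
        frame = Frame(np.column_stack([np.linspace(0.0, 11.0, 6), np.zeros(6), np.zeros(6)]))
        pts = es.axis_points(frame, top, "A", n_blocks=1, points_per_block=12)
        assert np.allclose(np.diff(pts[:, 0]), 1.0)
        assert pts[0, 0] == 0.0 and pts[-1, 0] == 11.0

    def test_translation_equivariance(self, chain12):
        top, frame = chain12
        pts = es.axis_points(frame, top, "A")
        shifted = Frame(frame.coordinates + np.array([7.0, 0, 0]))
        pts2 = es.axis_points(shifted, top, "A")
        assert np.allclose(pts2[:, 0] - pts[:, 0], 7.0)

    def test_indivisible_residue_count_rejected(self, chain6):
        top, frame = chain6
        with pytest.raises(ValueError, match="divisible"):
            es.axis_points(frame, top, "A", n_blocks=5)


class TestFieldProfile:
    def test_matches_bruteforce_double_loop(self, chain12):
        top, frame = builder.place_waters(chain12, 5, mode="cavity", seed=4)
        traj = Trajectory(topology=top, frames=[frame])
        aligned, _ = es.align_axis(traj, "A")
        prof = es.field_profile(aligned, "A")
        src = np.array([a.index for a in top.atoms if a.chain_id == "A"])
        q = top.charges()[src]
        xyz = aligned.frames[0].coordinates[src]
        pts = es.axis_points(aligned.frames[0], top, "A")
        for p in range(24):
            e = np.zeros(3)
            for i in range(len(src)):  # independent double loop
                rv = pts[p] - xyz[i]
                r = np.sqrt((rv**2).sum())
                e += es.COULOMB_MV_CM * q[i] * rv / r**3
            assert np.linalg.norm(e) == pytest.approx(
                np.linalg.norm(prof.per_frame_E[0, p]), rel=1e-10
            )

    def test_single_frame_zero_ci(self, chain12):
        top, frame = chain12
        aligned, _ = es.align_axis(Trajectory(topology=top, frames=[frame]), "A")
        prof = es.field_profile(aligned, "A")
        assert np.all(prof.ci95 == 0.0)
        assert prof.point_index[0] == 1 and prof.point_index[-1] == 24

    def test_symmetric_charges_give_symmetric_profile(self):
        """Mirror-symmetric source arrangement -> profile symmetric about the middle."""
        n = 12
        atoms = []
        coords = []
        for i in range(n):
            atoms.append(Atom(2 * i, "C1", "C", i, "GLC", "A", charge=0.5, mass=12.0))
            atoms.append(Atom(2 * i + 1, "O2", "O", i, "GLC", "A", charge=-0.5, mass=16.0))
            x = i * 3.0
            coords.extend([[x, 2.0, 0.0], [x, -2.0, 0.0]])
        top = Topology(atoms=atoms)
        frame = Frame(np.array(coords))
        prof = es.field_profile(
            Trajectory(topology=top, frames=[frame]), "A",
        )
        mags = prof.mean_E_mag
        assert np.allclose(mags, mags[::-1], rtol=1e-6)


class TestWaterDipoleComponents:
    def test_isotropic_orientations_marginal(self, chain6):
        top, frame = builder.place_waters(chain6, 1000, mode="bulk", seed=10)
        wres = sorted({a.residue_index for a in top.atoms if a.is_water})
        traj = Trajectory(topology=top, frames=[frame])
        comps = es.water_dipole_components(traj, wres)
        mu = np.linalg.norm(comps[0], axis=1)
        assert np.allclose(mu, mu[0], atol=1e-9)  # rigid model: |mu| constant
        # uniform random orientation: E|mu_x| = mu/2, mean component ~ 0
        for ax in range(3):
            assert np.abs(comps[0][:, ax]).mean() == pytest.approx(mu[0] / 2, abs=0.08)
            assert comps[0][:, ax].mean() == pytest.approx(0.0, abs=0.15)

    def test_empty_water_set_rejected(self, chain6):
        top, frame = chain6
        with pytest.raises(ValueError):
            es.water_dipole_components(Trajectory(topology=top, frames=[frame]), [])
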