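import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycotraj import builder, conformation as conf
from glycotraj.builder import ChainSpec, EnsembleSpec
from glycotraj.model import Frame, Trajectory


def _random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.normal(scale=10.0, size=3)


def _atan2_dihedral_oracle(p1, p2, p3, p4):
    """Independent formulation: atan2(|b2| b1.(b2 x b3), (b1 x b2).(b2 x b3))."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    y = np.linalg.norm(b2) * np.dot(b1, np.cross(b2, b3))
    x = np.dot(np.cross(b1, b2), np.cross(b2, b3))
    return np.degrees(np.arctan2(y, x))


class TestDihedral:
    def test_cis_is_zero(self):
        assert conf.measure_dihedral([1, 1, 0], [0, 0, 0], [1, 0, 0], [2, 1, 0]) == pytest.approx(0.0, abs=1e-10)

    def test_trans_reported_as_minus_180(self):
        val = conf.measure_dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0])
        assert val == pytest.approx(-180.0, abs=1e-10)
        assert -180.0 <= val < 180.0

    def test_matches_atan2_oracle(self, rng):
        for _ in range(200):
            pts = rng.normal(scale=3.0, size=(4, 3))
            try:
                ours = conf.measure_dihedral(*pts)
            except ValueError:
                continue
            expected = _atan2_dihedral_oracle(*pts)
            expected = expected if expected < 180 else expected - 360
            assert ours == pytest.approx(expected, abs=1e-8)

    def test_quarter_turn_example(self):
        val = conf.measure_dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1])
        oracle = _atan2_dihedral_oracle(
            np.array([0.0, 1, 0]), np.array([0.0, 0, 0]), np.array([1.0, 0, 0]), np.array([1.0, 0, 1])
        )
        assert abs(val) == pytest.approx(90.0, abs=1e-10)
        assert val == pytest.approx(oracle, abs=1e-10)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            conf.measure_dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])
        with pytest.raises(ValueError):
            conf.measure_dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestCremerPople:
    def test_chair_signatures(self):
        j = np.arange(6)
        ring = builder.ideal_ring_coords(0.25 * (-1.0) ** j)
        assert conf.cremer_pople(ring).theta_deg == pytest.approx(0.0, abs=1e-9)
        flipped = builder.ideal_ring_coords(-0.25 * (-1.0) ** j)
        assert conf.cremer_pople(flipped).theta_deg == pytest.approx(180.0, abs=1e-9)

    def test_boat_at_90(self):
        j = np.arange(6)
        ring = builder.ideal_ring_coords(0.25 * np.cos(4 * np.pi * j / 6))
        assert conf.cremer_pople(ring).theta_deg == pytest.approx(90.0, abs=1e-9)

    def test_planar_hexagon_flagged(self):
        state = conf.cremer_pople(builder.ideal_ring_coords(np.zeros(6)))
        assert state.Q == pytest.approx(0.0, abs=1e-9)
        assert state.is_planar

    def test_rigid_transform_invariance(self, rng):
        j = np.arange(6)
        ring = builder.ideal_ring_coords(0.3 * np.cos(4 * np.pi * j / 6 + 0.7) + 0.1 * (-1.0) ** j)
        ref = conf.cremer_pople(ring)
        for _ in range(20):
            rot, trans = _random_rigid(rng)
            moved = conf.cremer_pople(ring @ rot.T + trans)
            assert moved.Q == pytest.approx(ref.Q, abs=1e-9)
            assert moved.theta_deg == pytest.approx(ref.theta_deg, abs=1e-7)
            assert moved.phi_deg == pytest.approx(ref.phi_deg, abs=1e-6)

    def test_mirror_ring_theta_sums_to_180(self, rng):
        for _ in range(10):
            z = rng.normal(scale=0.25, size=6)
            ring = builder.ideal_ring_coords(z)
            mirror = ring * np.array([1.0, 1.0, -1.0])
            a = conf.cremer_pople(ring)
            b = conf.cremer_pople(mirror)
            if a.is_planar:
                continue
            assert a.theta_deg + b.theta_deg == pytest.approx(180.0, abs=1e-7)


class TestSuperpose:
    def test_identical_frames_zero(self, chain6):
        _, frame = chain6
        _, _, rmsd = conf.superpose(frame, frame)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rotated_copy_recovered(self, chain6, rng):
        _, frame = chain6
        rot, trans = _random_rigid(rng)
        moved = Frame(frame.coordinates @ rot.T + trans)
        _, _, rmsd = conf.superpose(moved, frame)
        assert rmsd <= 1e-6

    def test_matches_scipy_align_vectors(self, rng):
        from scipy.spatial.transform import Rotation

        for _ in range(20):
            a = rng.normal(size=(12, 3))
            b = rng.normal(size=(12, 3))
            _, _, ours = conf.superpose(a, b)
            ac = a - a.mean(axis=0)
            bc = b - b.mean(axis=0)
            rot, _ = Rotation.align_vectors(bc, ac)
            ref = np.sqrt(((rot.apply(ac) - bc) ** 2).sum(axis=1).mean())
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_planar_set_matches_grid_search(self):
        """4-point planar toy: Kabsch equals a 0.1-deg rotational grid search."""
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        mob = ref.copy()
        mob[2] += np.array([0.3, -0.2, 0.0])
        _, _, ours = conf.superpose(mob, ref)
        mc = mob - mob.mean(axis=0)
        rc = ref - ref.mean(axis=0)
        best = np.inf
        for ang in np.arange(-30.0, 30.0, 0.1):
            t = np.radians(ang)
            rot = np.array(
                [[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]]
            )
            best = min(best, np.sqrt(((mc @ rot.T - rc) ** 2).sum(axis=1).mean()))
        assert ours <= best + 1e-12
        assert best - ours <= 1e-3

    def test_superposed_not_worse_than_raw(self, chain6, rng):
        _, frame = chain6
        noisy = Frame(frame.coordinates + rng.normal(scale=0.5, size=frame.coordinates.shape))
        _, _, fitted = conf.superpose(noisy, frame)
        raw = np.sqrt(((noisy.coordinates - frame.coordinates) ** 2).sum(axis=1).mean())
        assert fitted <= raw + 1e-12

    def test_too_few_atoms_rejected(self, chain6):
        _, frame = chain6
        with pytest.raises(ValueError):
            conf.superpose(frame, frame, selection=np.array([0, 1]))


class TestRmsdRmsf:
    def test_static_trajectory_all_zero(self, chain6):
        top, frame = chain6
        traj = Trajectory(topology=top, frames=[frame.copy() for _ in range(5)])
        assert np.allclose(conf.rmsd_series(traj), 0.0, atol=1e-12)

    def test_noise_rmsd_matches_direct_oracle(self, chain6, rng):
        top, frame = chain6
        frames = [
            Frame(frame.coordinates + rng.normal(scale=0.1, size=frame.coordinates.shape))
            for _ in range(50)
        ]
        traj = Trajectory(topology=top, frames=frames)
        sel = top.select(heavy=True)
        series = conf.rmsd_series(traj, selection=sel)
        # independent recomputation, frame by frame
        for k in (0, 10, 49):
            _, _, ref = conf.superpose(frames[k], frames[0], sel)
            assert series[k] == pytest.approx(ref, abs=1e-12)
        expected = 0.1 * np.sqrt(3.0)
        assert series[1:].mean() * np.sqrt(2) / 2 <= expected  # fitted rmsd below raw sigma*sqrt(3)*sqrt(2)

    def test_rmsf_isotropic_noise_closed_form(self):
        sigma = 0.1
        spec = EnsembleSpec(
            n_frames=2000, noise_sigma_A=sigma,
            state_mixture=[(ChainSpec(n_residues=6), 1.0)], seed=5,
        )
        traj, _ = builder.make_ensemble(spec)
        _, rmsf = conf.rmsf_per_residue(traj, "A")
        expected = sigma * np.sqrt(3.0)
        assert rmsf.mean() == pytest.approx(expected, rel=0.05)

    def test_rmsf_static_zero_and_single_frame_error(self, chain6):
        top, frame = chain6
        traj = Trajectory(topology=top, frames=[frame.copy(), frame.copy()])
        _, vals = conf.rmsf_per_residue(traj, "A")
        assert np.allclose(vals, 0.0, atol=1e-10)
        with pytest.raises(ValueError):
            conf.rmsf_per_residue(Trajectory(topology=top, frames=[frame]), "A")

    def test_wobbly_termini_exceed_core(self, rng):
        """Extra displacement on terminal residues shows up as terminal RMSF."""
        top, frame = builder.build_chain(ChainSpec(n_residues=6))
        term = np.array([a.index for a in top.atoms if a.residue_index in (0, 5)])
        frames = []
        for _ in range(200):
            xyz = frame.coordinates + rng.normal(scale=0.05, size=frame.coordinates.shape)
            xyz[term] += rng.normal(scale=0.3, size=(term.size, 3))
            frames.append(Frame(xyz))
        res, vals = conf.rmsf_per_residue(Trajectory(topology=top, frames=frames), "A")
        assert vals[0] > vals[2] and vals[-1] > vals[2]


class TestSizeDescriptors:
    def test_rg_two_equal_masses(self):
        from glycotraj.model import Atom, Topology

        top = Topology(atoms=[
            Atom(0, "C1", "C", 0, "GLC", "A", mass=12.0),
            Atom(1, "C2", "C", 0, "GLC", "A", mass=12.0),
        ])
        frame = Frame(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert conf.radius_of_gyration(frame, top, np.array([0, 1])) == pytest.approx(1.0)
        assert conf.radius_of_gyration(frame, top, np.array([0])) == pytest.approx(0.0)

    def test_rg_rigid_invariance(self, chain6, rng):
        top, frame = chain6
        sel = top.select(heavy=True)
        ref = conf.radius_of_gyration(frame, top, sel)
        rot, trans = _random_rigid(rng)
        moved = Frame(frame.coordinates @ rot.T + trans)
        assert conf.radius_of_gyration(moved, top, sel) == pytest.approx(ref, abs=1e-9)

    def test_end_to_end_matches_direct_distance(self, chain12):
        top, frame = chain12
        c1 = top.find_atom("A", 0, "C1").index
        c4 = top.find_atom("A", 11, "C4").index
        direct = np.linalg.norm(frame.coordinates[c1] - frame.coordinates[c4])
        assert conf.end_to_end(frame, top, "A") == pytest.approx(direct, abs=1e-12)

    def test_end_to_end_single_residue_error(self):
        top, frame = builder.build_ring(conf.PuckerState(Q=0.57, theta_deg=0.0, phi_deg=0.0))
        with pytest.raises(ValueError):
            conf.end_to_end(frame, top, "A")


class TestFes:
    def test_single_bin_and_flat_limit(self, rng):
        grid = conf.fes_2d(np.full(100, 10.0), np.full(100, 20.0), bins=36)
        assert np.nansum(grid.free_energy) == pytest.approx(0.0)
        assert grid.mask.sum() == 36 * 36 - 1
        phi = rng.uniform(-180, 180, 200000)
        psi = rng.uniform(-180, 180, 200000)
        grid = conf.fes_2d(phi, psi, bins=12)
        assert np.nanmax(grid.free_energy) < 0.15  # flat within sampling error

    def test_two_state_gap_recovered(self, rng):
        n = 20000
        labels = rng.uniform(size=n) < 0.7
        phi = np.where(labels, 105.0, -65.0) + rng.normal(scale=1.0, size=n)
        psi = np.where(labels, 115.0, -145.0) + rng.normal(scale=1.0, size=n)
        grid = conf.fes_2d(phi, psi, bins=36, temperature_K=298.0)
        kT = conf.KB_KCAL * 298.0
        expected_gap = kT * np.log(7.0 / 3.0)  # ~0.50 kcal/mol
        # gap between the two occupied basins (min F within each quadrant)
        fe = grid.free_energy
        centers = 0.5 * (grid.phi_edges[:-1] + grid.phi_edges[1:])
        major = np.nanmin(fe[np.ix_(centers > 0, centers > 0)])
        minor = np.nanmin(fe[np.ix_(centers < 0, centers < 0)])
        assert major == pytest.approx(0.0, abs=1e-12)
        assert minor - major == pytest.approx(expected_gap, abs=0.05)

    def test_min_unmasked_exactly_zero(self, rng):
        grid = conf.fes_2d(rng.normal(scale=30, size=5000), rng.normal(scale=30, size=5000))
        assert np.nanmin(grid.free_energy) == 0.0

    def test_bad_bins_rejected(self):
        with pytest.raises(ValueError):
            conf.fes_2d(np.array([0.0]), np.array([0.0]), bins=1)


@settings(max_examples=50, deadline=None)
@given(st.floats(-1000, 1000))
def test_wrap_angle_range(x):
    w = conf.wrap_angle(x)
    assert -180.0 <= w < 180.0
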