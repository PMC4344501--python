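"""Brownian dynamics: integrator statistics, torsion bookkeeping, I/O."""

import numpy as np
import pytest

from plectosim import _kernels
from plectosim.bd_engine import (
    NotEquilibratedError,
    RunProtocol,
    Trajectory,
    box_length_for_phi,
    detect_equilibration,
    frames_from_conformation,
    init_system,
    read_trajectory,
    run_bd,
    twist_angles_from_frames,
    unwrap_molecules,
    write_trajectory,
)
from plectosim.fixtures import planar_circle, twisted_circle
from plectosim.model_core import ForceField, RingTopologySpec, SystemState
from plectosim.topology import writhe


class TestInit:
    def test_box_length_formula(self):
        # 20 x 334 beads at 20% occupancy
        assert box_length_for_phi(20, 334, 0.20) == pytest.approx(25.96, abs=0.01)

    def test_dilute_is_boxless(self):
        state = init_system(RingTopologySpec(), m_rings=3, phi=0.0)
        assert not np.isfinite(state.box_length)
        assert state.n_rings == 3

    def test_planar_start_imposes_lk(self):
        state = init_system(RingTopologySpec(delta_lk=-7), m_rings=1, phi=0.0)
        ring = state.rings[0]
        tw = np.sum(ring.excess_twist) / (2 * np.pi)
        assert tw == pytest.approx(-7.0, abs=1e-9)
        assert writhe(ring.positions) == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_placement_raises(self):
        with pytest.raises(ValueError, match="compress_box"):
            init_system(RingTopologySpec(), m_rings=20, phi=0.20)

    def test_small_rings_fit_lattice(self):
        spec = RingTopologySpec(n_beads=16, n_bp=140)
        state = init_system(spec, m_rings=8, phi=0.01, seed=3)
        assert state.volume_fraction() == pytest.approx(0.01, rel=1e-3)


class TestIntegrator:
    def test_zero_forces_zero_noise_is_identity(self):
        # dt -> 0 limit approximated by vanishing noise: all couplings off
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        mn = np.zeros((3, 3))
        mn[:, 2] = 1
        s_pos, _, _ = _kernels.bd_run(
            pos.copy(), mn, 3, 1, -1.0, False, 0.0, 0.0, 0.0, 1.0, 0.0,
            -1, -1, 0.0, 2.0, 1e-12, 1.0, 1.0, 10, 10, 5,
        )
        np.testing.assert_allclose(s_pos[0], pos, atol=1e-5)

    def test_free_bead_diffusion_einstein(self):
        # <dr^2> = 6 D t with D = kT/gamma = 1 in reduced units
        n = 300
        pos = np.arange(n * 3, dtype=float).reshape(n, 3) * 7.0
        mn = np.zeros((n, 3))
        mn[:, 2] = 1
        s_pos, _, _ = _kernels.bd_run(
            pos.copy(), mn, n, 1, -1.0, False, 0.0, 0.0, 0.0, 1.0, 0.0,
            -1, -1, 0.0, 2.0, 5e-4, 1.0, 1.0, 2000, 2000, 7,
        )
        msd = np.mean(np.sum((s_pos[0] - pos) ** 2, axis=1))
        t = 5e-4 * 2000
        assert msd == pytest.approx(6.0 * t, rel=0.15)

    def test_dimer_bond_boltzmann(self):
        # harmonic bond at k = 800: near-Gaussian length fluctuations
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        mn = np.zeros((2, 3))
        mn[:, 2] = 1
        s_pos, _, _ = _kernels.bd_run(
            pos.copy(), mn, 2, 1, -1.0, False, 0.0, 0.0, 800.0, 1.0, 0.0,
            -1, -1, 0.0, 2.0, 1e-4, 1.0, 1.0, 150_000, 25, 8,
        )
        r = np.linalg.norm(s_pos[:, 1] - s_pos[:, 0], axis=1)
        sig = 1.0 / np.sqrt(800.0)
        assert r.mean() == pytest.approx(1.0 + 2 * sig**2, abs=3 * sig / np.sqrt(len(r) / 20))
        assert r.std() == pytest.approx(sig, rel=0.12)

    def test_instability_detected(self):
        pos = np.array([[0.0, 0, 0], [0.2, 0, 0], [0.4, 0, 0]])  # deep overlaps
        mn = np.zeros((3, 3))
        mn[:, 2] = 1
        with pytest.raises(ValueError, match="instability"):
            _kernels.bd_run(
                pos.copy(), mn, 3, 1, -1.0, False, 0.0, 1.0, 0.0, 1.0, 0.0,
                -1, -1, 0.0, 2.0, 5e-4, 1.0, 1.0, 10, 10, 5,
            )

    def test_seeded_runs_bitwise_identical(self, ff):
        state_a = SystemState([twisted_circle(32, -1)])
        state_b = SystemState([twisted_circle(32, -1)])
        proto = RunProtocol(n_steps=200, sample_every=50, seed=42)
        ta = run_bd(state_a, ff, proto)
        tb = run_bd(state_b, ff, proto)
        np.testing.assert_array_equal(ta.positions, tb.positions)
        np.testing.assert_array_equal(ta.phi, tb.phi)


class TestTorsion:
    def test_frames_roundtrip_uniform_twist(self):
        conf = twisted_circle(40, -2)
        mn = frames_from_conformation(conf)
        phi = twist_angles_from_frames(conf.positions, mn)
        np.testing.assert_allclose(phi, -2 * 2 * np.pi / 40, atol=1e-10)

    def test_lk_conserved_along_trajectory(self, ff):
        # White's theorem as a dynamical invariant: Tw + Wr = dLk throughout
        state = SystemState([twisted_circle(64, -2)])
        proto = RunProtocol(dt=5e-4, n_steps=3000, sample_every=500, seed=3)
        traj = run_bd(state, ff, proto)
        for f in range(traj.n_frames):
            st = traj.to_state(f)
            tw = np.sum(st.rings[0].excess_twist) / (2 * np.pi)
            wr = writhe(st.rings[0].positions)
            assert tw + wr == pytest.approx(-2.0, abs=0.05)

    def test_twist_force_matches_finite_differences(self, rng):
        from plectosim.model_core import RingConformation

        n = 10
        base = twisted_circle(n, -0.5)
        pos = np.ascontiguousarray(base.positions + 0.05 * rng.standard_normal((n, 3)))
        conf = RingConformation(pos, base.excess_twist.copy())
        mn = np.ascontiguousarray(frames_from_conformation(conf))
        k_twist = 31.7

        def energy(p, m):
            phi = np.zeros(n)
            _kernels.compute_phi(np.ascontiguousarray(p), np.ascontiguousarray(m), n, 1, True, phi)
            return 0.5 * k_twist * np.sum(phi**2)

        def transported(p_new):
            out = mn.copy()
            for k in range(n):
                a = pos[(k + 1) % n] - pos[k]
                b = p_new[(k + 1) % n] - p_new[k]
                a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
                kx = np.cross(a, b)
                s, c = np.linalg.norm(kx), a @ b
                v = mn[k] if s < 1e-14 else (
                    mn[k] * c + np.cross(kx / s, mn[k]) * s + kx / s * ((kx / s) @ mn[k]) * (1 - c)
                )
                v -= (v @ b) * b
                out[k] = v / np.linalg.norm(v)
            return out

        phi = np.zeros(n)
        _kernels.compute_phi(pos, mn, n, 1, True, phi)
        F = np.empty((n, 3))
        _kernels._bd_forces(
            pos, phi, n, 1, -1.0, True, 0.0, 0.0, 0.0, 1.0, k_twist, -1, -1, 0.0, 2.0, F
        )
        h = 1e-6
        for i in (0, 3, 7):
            for d in range(3):
                pp = pos.copy(); pp[i, d] += h
                pm = pos.copy(); pm[i, d] -= h
                fd = -(energy(pp, transported(pp)) - energy(pm, transported(pm))) / (2 * h)
                assert F[i, d] == pytest.approx(fd, abs=1e-5 * max(1.0, abs(fd)))


class TestCompression:
    def test_box_ratio_for_volume_quadrupling(self):
        # phi 0.05 -> 0.20 quarters the volume: edge ratio 4^(1/3)
        r = box_length_for_phi(20, 334, 0.05) / box_length_for_phi(20, 334, 0.20)
        assert r == pytest.approx(4 ** (1 / 3), rel=1e-12)

    def test_compress_to_target_is_exact(self):
        from plectosim.bd_engine import compress_box

        ff = ForceField(k_twist=0.0)
        spec = RingTopologySpec(n_beads=16, n_bp=140)
        state = init_system(spec, m_rings=8, phi=0.004, seed=2)
        compress_box(state, 0.02, ff, rate=0.01, relax_sweeps=6, seed=3)
        assert state.volume_fraction() == pytest.approx(0.02, rel=1e-3)
        # chain integrity and no core overlaps after the protocol
        for out in unwrap_molecules(state):
            bonds = np.linalg.norm(np.roll(out, -1, axis=0) - out, axis=1)
            assert np.all(np.abs(bonds - 1.0) < 0.01)

    def test_target_at_current_phi_is_noop(self):
        ff = ForceField(k_twist=0.0)
        spec = RingTopologySpec(n_beads=16, n_bp=140)
        state = init_system(spec, m_rings=8, phi=0.02, seed=2)
        before = state.all_positions().copy()
        from plectosim.bd_engine import compress_box

        compress_box(state, 0.02, ff, seed=3)
        np.testing.assert_allclose(state.all_positions(), before)


class TestEquilibration:
    def test_constant_series(self):
        assert detect_equilibration(np.ones((200, 3))) == 0

    def test_step_series_localised(self, rng):
        t_len, k = 400, 60
        series = np.where(np.arange(t_len)[:, None] < k, 9.0, 5.0) + 0.05 * rng.standard_normal((t_len, 2))
        t_eq = detect_equilibration(series)
        w = int(round(0.05 * t_len))
        assert k - w <= t_eq <= k + 2 * w

    def test_drifting_series_flagged(self):
        series = np.linspace(10, 5, 300)[:, None]
        with pytest.raises(NotEquilibratedError):
            detect_equilibration(series)


class TestUnwrapAndIO:
    def test_unwrap_identity_inside_box(self):
        conf = planar_circle(16)
        conf.positions += 20.0
        state = SystemState([conf], box_length=100.0)
        out = unwrap_molecules(state)
        np.testing.assert_allclose(out[0], conf.positions, atol=1e-12)

    def test_unwrap_straddling_face(self):
        conf = planar_circle(16)  # radius ~2.6, crosses x = 0 when centred there
        state = SystemState([conf], box_length=50.0)
        out = unwrap_molecules(state)
        bonds = np.linalg.norm(np.roll(out[0], -1, axis=0) - out[0], axis=1)
        assert np.all(bonds < 2.0)
        assert np.all(np.abs(bonds - 1.0) < 1e-9)

    def test_corrupted_flags_detected(self):
        conf = planar_circle(16)
        state = SystemState([conf], box_length=3.0)  # box smaller than the ring
        conf.positions[5] += np.array([40.0, 0, 0])  # inconsistent jump
        with pytest.raises(ValueError, match="image flags"):
            unwrap_molecules(state)

    def test_xyz_roundtrip_lossless(self, tmp_path, ff):
        state = SystemState([twisted_circle(24, -1)], box_length=30.0)
        proto = RunProtocol(n_steps=100, sample_every=25, seed=9)
        traj = run_bd(state, ff, proto)
        path = tmp_path / "run.xyz"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        np.testing.assert_allclose(back.positions, traj.positions, atol=1e-12)
        np.testing.assert_allclose(back.phi, traj.phi, atol=1e-12)
        np.testing.assert_array_equal(back.steps, traj.steps)
        assert back.metadata["seed"] == 9

    def test_empty_trajectory_roundtrip(self, tmp_path):
        traj = Trajectory(
            positions=np.empty((0, 0, 3)), phi=np.empty((0, 0)), box=np.empty(0),
            steps=np.empty(0, dtype=int), n_ring=0, m_rings=0,
        )
        path = tmp_path / "empty.xyz"
        write_trajectory(traj, path)
        assert read_trajectory(path).n_frames == 0

    def test_truncated_file_reports_frame(self, tmp_path, ff):
        state = SystemState([twisted_circle(24, -1)], box_length=30.0)
        traj = run_bd(state, ff, RunProtocol(n_steps=75, sample_every=25, seed=9))
        path = tmp_path / "trunc.xyz"
        write_trajectory(traj, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[: len(lines) - 10]) + "\n")
        with pytest.raises(ValueError, match="frame 2"):
            read_trajectory(path)
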