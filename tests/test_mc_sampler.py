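"""Equilibrium Metropolis sampler: analytic cross-checks and invariants."""

import numpy as np
import pytest

from plectosim import _kernels
from plectosim.fixtures import planar_circle, twisted_circle
from plectosim.mc_sampler import (
    fit_persistence_length,
    free_chain_cos_theta,
    free_chain_tangent_correlation,
    sample_ring,
    sample_system,
)
from plectosim.model_core import (
    ForceField,
    SystemState,
    energy_bend,
    persistence_length,
)


class TestFreeChainSampler:
    def test_cos_theta_mean_matches_langevin_function(self, rng):
        # <cos theta> = coth(kappa) - 1/kappa for the kappa(1-cos) junction
        kappa = 17.0
        c = free_chain_cos_theta(kappa, 200_000, rng)
        expected = 1.0 / np.tanh(kappa) - 1.0 / kappa
        assert c.mean() == pytest.approx(expected, abs=3 * c.std() / np.sqrt(len(c)))
        assert np.all(c <= 1.0) and np.all(c >= -1.0)

    def test_tangent_correlation_exponential(self):
        s, corr = free_chain_tangent_correlation(120, 17.0, n_chains=1500, max_s=25, seed=5)
        mean_cos = 1.0 / np.tanh(17.0) - 1.0 / 17.0
        np.testing.assert_allclose(corr, mean_cos**s, rtol=0.03)

    def test_persistence_length_recovered(self):
        s, corr = free_chain_tangent_correlation(200, 17.0, n_chains=3000, max_s=30, seed=6)
        lp = fit_persistence_length(s, corr, bond=1.0)
        assert lp == pytest.approx(persistence_length(17.0, 1.0), rel=0.05)

    def test_fit_rejects_non_decaying(self):
        with pytest.raises(ValueError):
            fit_persistence_length(np.arange(1, 5), np.ones(4) * 0.5 + np.arange(4) * 0.1)


class TestRingSampler:
    def test_seeded_runs_identical(self, ff):
        r1 = sample_ring(planar_circle(48), ff, n_sweeps=100, sample_every=20, seed=9)
        r2 = sample_ring(planar_circle(48), ff, n_sweeps=100, sample_every=20, seed=9)
        np.testing.assert_array_equal(r1.positions, r2.positions)
        assert not np.array_equal(
            r1.positions,
            sample_ring(planar_circle(48), ff, n_sweeps=100, sample_every=20, seed=10).positions,
        )

    def test_bond_lengths_preserved_by_crankshaft(self, ff):
        res = sample_ring(planar_circle(48), ff, n_sweeps=300, sample_every=100, seed=2)
        for s in range(res.n_samples):
            pos = res.positions[s]
            bonds = np.linalg.norm(np.roll(pos, -1, axis=0) - pos, axis=1)
            np.testing.assert_allclose(bonds, 1.0, atol=1e-9)

    def test_excluded_volume_respected(self, ff):
        res = sample_ring(planar_circle(48), ff, n_sweeps=500, sample_every=100, seed=3)
        pos = res.positions[-1]
        d = np.linalg.norm(pos[None] - pos[:, None], axis=-1)
        iu, ju = np.triu_indices(48, k=2)
        keep = ~((iu == 0) & (ju == 47))
        assert d[iu[keep], ju[keep]].min() > 0.6  # soft LJ core rarely below ~0.85

    def test_mean_bend_energy_matches_bd(self, ff):
        """Detailed-balance sanity: MC and BD sample the same Hamiltonian."""
        from plectosim.bd_engine import RunProtocol, run_bd

        ff0 = ForceField(k_twist=0.0)
        state = SystemState([planar_circle(40)])
        traj = run_bd(state, ff0, RunProtocol(dt=5e-4, n_steps=40_000, sample_every=200, seed=4))
        eb_bd = [energy_bend(traj.positions[f][:40], ff0) for f in range(20, traj.n_frames)]
        res = sample_ring(planar_circle(40), ff0, n_sweeps=4000, sample_every=10, seed=5)
        eb_mc = [energy_bend(p, ff0) for p in res.positions[80:]]
        se = np.hypot(
            np.std(eb_bd) / np.sqrt(len(eb_bd) / 5.0),
            np.std(eb_mc) / np.sqrt(len(eb_mc) / 5.0),
        )
        assert np.mean(eb_bd) == pytest.approx(np.mean(eb_mc), abs=2.5 * se)

    def test_writhe_tracking_matches_full_recompute(self, ff):
        conf = twisted_circle(64, -2)
        res = sample_ring(conf, ff, n_sweeps=600, sample_every=100, seed=6,
                          delta_lk=-2, wr_refresh=10_000)  # no refresh within run
        tracked = res.writhe[-1, 0]
        full = _kernels.writhe_ring(np.ascontiguousarray(res.positions[-1]))
        # rounding accumulates ~1e-11 per move; far below the 0.05-turn
        # bookkeeping tolerance
        assert tracked == pytest.approx(full, abs=1e-6)

    def test_supercoiled_ring_partitions_lk_into_writhe(self, ff):
        conf = twisted_circle(100, -4)
        res = sample_ring(conf, ff, n_sweeps=3000, sample_every=100, seed=7,
                          delta_lk=-4, d_max=0.8)
        wr_tail = res.writhe[-10:, 0]
        assert wr_tail.mean() < -0.5  # writhe takes up part of the deficit
        assert np.all(wr_tail < 0)


class TestMultiRing:
    def _stack(self, n_rings, n=24, box=16.0):
        rings = []
        for m in range(n_rings):
            c = planar_circle(n)
            c.positions = c.positions + np.array([0.0, 0.0, 2.5 * m])
            c.ring_id = m
            rings.append(c)
        return SystemState(rings, box_length=box)

    def test_cell_list_matches_full_scan(self, ff):
        ff0 = ForceField(k_twist=0.0)
        sa = self._stack(3)
        ra = sample_system(sa, ff0, n_sweeps=200, sample_every=40, seed=11, use_cell_list=True)
        sb = self._stack(3)
        rb = sample_system(sb, ff0, n_sweeps=200, sample_every=40, seed=11, use_cell_list=False)
        np.testing.assert_array_equal(ra.positions, rb.positions)

    def test_no_inter_ring_core_overlap(self, ff):
        ff0 = ForceField(k_twist=0.0)
        state = self._stack(3)
        res = sample_system(state, ff0, n_sweeps=400, sample_every=100, seed=12)
        pos = res.positions[-1]
        n = 24
        for a in range(3):
            for b in range(a + 1, 3):
                d = pos[a * n : (a + 1) * n, None, :] - pos[None, b * n : (b + 1) * n, :]
                d -= 16.0 * np.round(d / 16.0)
                assert np.linalg.norm(d, axis=-1).min() > 0.6
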