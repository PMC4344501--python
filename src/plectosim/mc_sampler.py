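"""Equilibrium Metropolis sampling of the same Hamiltonian as the BD engine.

Two samplers live here:

* a direct Boltzmann sampler for free (phantom) chains — junction bend
  angles are independent with density ~ exp(kappa cos theta) sin theta,
  so tangent chains can be drawn exactly; used for persistence-length
  calibration and as an analytic cross-check;
* a Metropolis crankshaft sampler for self-avoiding rings and open
  chains, optionally multi-molecule in a periodic box.  Supercoiling is
  handled through the torsionally equilibrated effective energy
  (2 pi^2 k_twist / n) (dLk - Wr)^2 with the writhe updated move by move,
  and every crankshaft is displacement-capped so that the hard excluded
  volume forbids strand passage (the sampler preserves topology).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model_core import ForceField, RingConformation, SystemState

__all__ = [
    "MCResult",
    "free_chain_cos_theta",
    "free_chain_tangent_correlation",
    "fit_persistence_length",
    "sample_ring",
    "sample_system",
]


# ---------------------------------------------------------------------------
# free-chain direct sampler

def free_chain_cos_theta(kappa: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw cos(theta) from the junction Boltzmann density ~ exp(kappa cos t).

    Inverse-CDF sampling on [-1, 1]; the mean is coth(kappa) - 1/kappa.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    u = rng.random(size)
    # F^-1(u) with F(c) = (e^{kappa c} - e^{-kappa}) / (e^{kappa} - e^{-kappa})
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa


def free_chain_tangent_correlation(
    n_beads: int,
    kappa: float,
    n_chains: int = 5000,
    max_s: int = 30,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Tangent-tangent correlation <t_i . t_{i+s}> of equilibrium free chains.

    Chains are built by successive rotations: each junction bends by an
    exactly-sampled polar angle with a uniform azimuth.  Correlations are
    pooled over all chains and all junction origins.  Returns
    (s = 1..max_s, C(s)).
    """
    rng = np.random.default_rng(seed)
    n_bonds = n_beads - 1
    t = np.zeros((n_chains, n_bonds, 3))
    cur = np.tile(np.array([0.0, 0.0, 1.0]), (n_chains, 1))
    t[:, 0] = cur
    for k in range(1, n_bonds):
        ct = free_chain_cos_theta(kappa, n_chains, rng)
        st = np.sqrt(np.clip(1.0 - ct * ct, 0.0, 1.0))
        psi = rng.uniform(0.0, 2.0 * np.pi, n_chains)
        # local frame perpendicular to the current tangent
        ref = np.where(np.abs(cur[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
        u1 = ref - np.einsum("ij,ij->i", ref, cur)[:, None] * cur
        u1 /= np.linalg.norm(u1, axis=1, keepdims=True)
        u2 = np.cross(cur, u1)
        cur = (
            ct[:, None] * cur
            + (st * np.cos(psi))[:, None] * u1
            + (st * np.sin(psi))[:, None] * u2
        )
        cur /= np.linalg.norm(cur, axis=1, keepdims=True)
        t[:, k] = cur
    s_vals = np.arange(1, max_s + 1)
    corr = np.empty(max_s)
    for idx, s in enumerate(s_vals):
        corr[idx] = np.einsum("cij,cij->", t[:, :-s], t[:, s:]) / (
            n_chains * (n_bonds - s)
        )
    return s_vals, corr


def fit_persistence_length(
    s: np.ndarray, corr: np.ndarray, bond: float = 1.0
) -> float:
    """Decay length of an exponential tangent correlation, via ln C(s) fit."""
    corr = np.asarray(corr, dtype=float)
    s = np.asarray(s, dtype=float)
    keep = corr > 0
    if keep.sum() < 2:
        raise ValueError("correlation not positive over the fit range")
    slope, _ = np.polyfit(s[keep], np.log(corr[keep]), 1)
    if slope >= 0:
        raise ValueError("tangent correlation does not decay")
    return float(-bond / slope)


# ---------------------------------------------------------------------------
# Metropolis crankshaft sampler

@dataclass
class MCResult:
    """Sampled coordinates (n_samples, n_beads_total, 3), per-ring writhe
    (only tracked for supercoiled runs), and the acceptance rate."""

    positions: np.ndarray
    writhe: np.ndarray
    acceptance: float
    n_ring: int
    m_rings: int

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    def ring_positions(self, sample: int) -> list[np.ndarray]:
        p = self.positions[sample]
        return [p[m * self.n_ring : (m + 1) * self.n_ring] for m in range(self.m_rings)]


def _run_kernel(
    pos, n, m, box, closed, ff, delta_lk, ep_sites, n_sweeps, sample_every,
    d_max, max_arc, angle_cap, p_translate, trans_step, wr_refresh, seed,
    ep_eps=None, bias=None, use_cell_list=True,
):
    k_twist = ff.k_twist if (delta_lk is not None and closed) else 0.0
    dlk = float(delta_lk) if delta_lk is not None else 0.0
    wr = np.zeros(m)
    if k_twist > 0.0:
        for mm in range(m):
            wr[mm] = _kernels.writhe_ring(pos[mm * n : (mm + 1) * n])
    ep_i, ep_j = ep_sites if ep_sites is not None else (-1, -1)
    if ep_eps is None:
        ep_eps = ff.ep_eps if ep_sites else 0.0
    bias_k, bias_d0 = bias if bias is not None else (0.0, 0.0)
    samples, wr_s, n_acc, n_tri = _kernels.mc_run(
        pos, n, m, box, closed,
        ff.eps_bend, ff.eps_rep, k_twist, dlk, wr,
        ep_i, ep_j, ep_eps, ff.ep_rcut, bias_k, bias_d0,
        n_sweeps, sample_every, d_max, max_arc, angle_cap,
        p_translate, trans_step, wr_refresh, 1 if use_cell_list else 0,
        seed % 2**31,
    )
    acc = n_acc / max(n_tri, 1)
    return MCResult(samples, wr_s, acc, n, m)


def sample_ring(
    conf: RingConformation | np.ndarray,
    ff: ForceField = ForceField(),
    n_sweeps: int = 1000,
    sample_every: int = 10,
    seed: int = 0,
    delta_lk: float | None = None,
    ep_sites: tuple[int, int] | None = None,
    closed: bool = True,
    box: float | None = None,
    d_max: float | None = None,
    max_arc: int | None = None,
    angle_cap: float | None = None,
    wr_refresh: int = 200,
    ep_eps: float | None = None,
    bias: tuple[float, float] | None = None,
) -> MCResult:
    """Metropolis sampling of a single molecule (dilute unless ``box`` given).

    ``delta_lk`` switches on the writhe-coupled torsional energy (a nicked
    / torsionally relaxed molecule is ``delta_lk=None``).  The input
    conformation is updated in place to the final sampled state.

    By default a dilute torsionally relaxed ring uses unrestricted
    crankshaft angles (fast mixing; the knotted fraction of such rings is
    negligible), while supercoiled or boxed molecules use
    displacement-capped moves that preserve topology, and smaller arcs to
    keep the per-move writhe update affordable.
    """
    pos = conf.positions if isinstance(conf, RingConformation) else np.asarray(conf)
    pos = np.ascontiguousarray(pos, dtype=np.float64)
    n = pos.shape[0]
    unrestricted = delta_lk is None and box is None
    if d_max is None:
        d_max = 1.0e9 if unrestricted else 0.45
    if angle_cap is None:
        angle_cap = np.pi if unrestricted else 1.5
    if max_arc is None:
        max_arc = max(3, n // 2 if delta_lk is None else n // 16)
    res = _run_kernel(
        pos, n, 1, box if box is not None else -1.0, closed, ff, delta_lk,
        ep_sites, n_sweeps, sample_every, d_max, max_arc, angle_cap,
        0.0, 0.0, wr_refresh, seed, ep_eps=ep_eps, bias=bias,
    )
    if isinstance(conf, RingConformation):
        conf.positions = pos
    return res


def sample_system(
    state: SystemState,
    ff: ForceField = ForceField(),
    n_sweeps: int = 1000,
    sample_every: int = 10,
    seed: int = 0,
    delta_lk: float | None = None,
    ep_sites: tuple[int, int] | None = None,
    closed: bool = True,
    d_max: float = 0.45,
    max_arc: int | None = None,
    angle_cap: float = 1.5,
    p_translate: float = 0.05,
    trans_step: float = 0.4,
    wr_refresh: int = 200,
    use_cell_list: bool = True,
) -> MCResult:
    """Metropolis sampling of an M-ring system in its periodic box.

    Crankshaft moves plus rigid molecule translations, all displacement-
    capped so that molecules can neither knot nor thread each other; the
    state is advanced in place.  ``sample_every = 0`` runs relaxation only.
    """
    n = state.rings[0].n_beads
    m = state.n_rings
    pos = np.ascontiguousarray(state.all_positions(), dtype=np.float64)
    box = state.box_length if np.isfinite(state.box_length) else -1.0
    if max_arc is None:
        max_arc = max(3, n // 4 if delta_lk is None else n // 16)
    res = _run_kernel(
        pos, n, m, box, closed, ff, delta_lk, ep_sites, n_sweeps,
        sample_every, d_max, max_arc, angle_cap, p_translate, trans_step,
        wr_refresh, seed, use_cell_list=use_cell_list,
    )
    for k, r in enumerate(state.rings):
        r.positions = pos[k * n : (k + 1) * n].copy()
    return res
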