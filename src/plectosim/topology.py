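"""Twist, writhe, linking number and supercoiling density of closed rings.

For a torsionally constrained closed DNA molecule White's theorem
partitions the (conserved) linking number into axial twist and spatial
writhe, Lk = Tw + Wr.  Twist is bookkept from the per-junction
excess-twist angles; writhe is evaluated by the exact closed-form solid
angle of every segment pair (the method of Klenin & Langowski), which for
a polygonal curve equals the Gauss double integral exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import RingConformation, RingTopologySpec

__all__ = ["TopologyRecord", "writhe", "twist", "supercoiling_density", "topology_record"]


@dataclass(frozen=True)
class TopologyRecord:
    """Per-conformation topology summary, all in turns (wr dimensionless)."""

    tw: float
    wr: float
    lk: float
    sigma: float


def _segment_pair_solid_angles(p1, p2, p3, p4):
    """Signed solid angle Omega/4pi of segment pairs (p1->p2), (p3->p4).

    Vectorized over leading axes.  Degenerate pairs (coplanar with a shared
    line, zero-length normals) contribute zero.
    """
    r13 = p3 - p1
    r14 = p4 - p1
    r23 = p3 - p2
    r24 = p4 - p2
    r12 = p2 - p1
    r34 = p4 - p3

    n1 = np.cross(r13, r14)
    n2 = np.cross(r14, r24)
    n3 = np.cross(r24, r23)
    n4 = np.cross(r23, r13)

    def _unit(v):
        nrm = np.linalg.norm(v, axis=-1, keepdims=True)
        ok = nrm[..., 0] > 1e-14
        out = np.where(nrm > 1e-14, v / np.where(nrm > 1e-14, nrm, 1.0), 0.0)
        return out, ok

    n1, ok1 = _unit(n1)
    n2, ok2 = _unit(n2)
    n3, ok3 = _unit(n3)
    n4, ok4 = _unit(n4)
    valid = ok1 & ok2 & ok3 & ok4

    def _asin_dot(a, b):
        return np.arcsin(np.clip(np.einsum("...i,...i->...", a, b), -1.0, 1.0))

    omega = (
        _asin_dot(n1, n2) + _asin_dot(n2, n3) + _asin_dot(n3, n4) + _asin_dot(n4, n1)
    )
    sign = np.sign(np.einsum("...i,...i->...", np.cross(r34, r12), r13))
    return np.where(valid, omega * sign / (4.0 * np.pi), 0.0)


def writhe(positions: np.ndarray) -> float:
    """Writhe of a closed polygonal curve (unwrapped coordinates).

    Sums the exact per-pair solid angles over all non-adjacent segment
    pairs; adjacent pairs contribute zero in the Gauss integral and are
    skipped.  A planar curve returns 0 to machine precision.
    """
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    if pos.ndim != 2 or pos.shape[1] != 3 or n < 3:
        raise ValueError("positions must be (n>=3, 3)")
    nxt = np.roll(pos, -1, axis=0)
    seg_len = np.linalg.norm(nxt - pos, axis=1)
    if np.any(seg_len == 0.0):
        raise ValueError("zero-length segment in ring")

    i, j = np.triu_indices(n, k=2)
    # segments 0 and n-1 are adjacent through ring closure
    keep = ~((i == 0) & (j == n - 1))
    i, j = i[keep], j[keep]
    om = _segment_pair_solid_angles(pos[i], nxt[i], pos[j], nxt[j])
    return float(2.0 * np.sum(om))


def twist(conf: RingConformation) -> float:
    """Excess twist in turns: Tw = sum(phi_i) / 2 pi."""
    return float(np.sum(conf.excess_twist) / (2.0 * np.pi))


def supercoiling_density(
    delta_lk: float, n_bp: float, helical_repeat: float = 10.5
) -> float:
    """sigma = delta_lk / (n_bp / helical_repeat).

    A 3 kb ring at 10.5 bp/turn has Lk0 ~ 285.7, so delta_lk = -7 and -14
    give sigma ~ -0.025 and -0.05.
    """
    if n_bp <= 0:
        raise ValueError("n_bp must be positive")
    return float(delta_lk / (n_bp / helical_repeat))


def topology_record(conf: RingConformation, spec: RingTopologySpec) -> TopologyRecord:
    """Tw, Wr, Lk = Tw + Wr and sigma for one ring conformation."""
    tw = twist(conf)
    wr = writhe(conf.positions)
    lk = tw + wr
    return TopologyRecord(tw=tw, wr=wr, lk=lk, sigma=lk / spec.lk0)
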