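"""Local intra-molecular thickness via a tangent probe sphere.

At a chain point the local thickness is the diameter of the largest
sphere that can be laid tangentially against the chain there, at *any*
azimuthal direction around the local tangent, without intersecting the
rest of the chain (short portions around the point of tangency are
ignored to remove the trivial obstruction by local curvature).  Where two
chain portions touch, the thickness collapses to one bead diameter; in
open regions it is capped at a configurable maximum probe size.

For a probe sphere of radius rho placed at r_i + (rho + sigma/2) u the
non-intersection condition against an obstructing bead at separation d is
|d|^2 >= 2 (rho + sigma/2) (u . d), which yields the largest admissible
radius per azimuth in closed form; the thickness is twice the minimum
over azimuths plus one bead diameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["ThicknessParams", "local_thickness", "ring_thickness", "thickness_ensemble"]


@dataclass(frozen=True)
class ThicknessParams:
    exclusion_halfwidth: int = 10   # beads ignored around the tangency point
    n_azimuth: int = 36             # probe directions around the tangent
    max_radius: float = 15.0        # probe cap, sigma_LJ
    include_other_rings: bool = True
    sigma: float = 1.0              # bead diameter

    def __post_init__(self) -> None:
        if self.exclusion_halfwidth < 2:
            raise ValueError("exclusion_halfwidth must be >= 2")
        if self.n_azimuth < 8:
            raise ValueError("n_azimuth must be >= 8")
        if self.max_radius <= 0 or self.sigma <= 0:
            raise ValueError("max_radius and sigma must be positive")


def _tangent(pos: np.ndarray, i: int, closed: bool) -> np.ndarray:
    n = pos.shape[0]
    if closed:
        t = pos[(i + 1) % n] - pos[(i - 1) % n]
    else:
        if i == 0 or i == n - 1:
            raise ValueError("tangent undefined at open-chain endpoints")
        t = pos[i + 1] - pos[i - 1]
    nrm = np.linalg.norm(t)
    if nrm < 1e-12:
        raise ValueError("coincident neighbours: tangent undefined")
    return t / nrm


def _azimuth_frame(t: np.ndarray, n_az: int) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(t @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u1 = ref - (ref @ t) * t
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(t, u1)
    ang = 2.0 * np.pi * np.arange(n_az) / n_az
    return np.cos(ang)[:, None] * u1 + np.sin(ang)[:, None] * u2


def _obstructions(
    conf_set: Sequence[np.ndarray],
    ring_id: int,
    bead_i: int,
    params: ThicknessParams,
    closed: bool,
) -> np.ndarray:
    own = np.asarray(conf_set[ring_id], dtype=float)
    n = own.shape[0]
    idx = np.arange(n)
    if closed:
        sep = np.minimum((idx - bead_i) % n, (bead_i - idx) % n)
    else:
        sep = np.abs(idx - bead_i)
    keep = own[sep > params.exclusion_halfwidth]
    others = [
        np.asarray(conf_set[k], dtype=float)
        for k in range(len(conf_set))
        if k != ring_id and params.include_other_rings
    ]
    return np.vstack([keep] + others) if others else keep


def local_thickness(
    conf_set: Sequence[np.ndarray],
    ring_id: int,
    bead_i: int,
    params: ThicknessParams = ThicknessParams(),
    closed: bool = True,
) -> float:
    """Thickness t_i = 2 min_u rho(u) + sigma at bead ``bead_i``.

    ``conf_set`` is a list of unwrapped (n, 3) coordinate arrays, one per
    ring; ``ring_id`` selects the probed chain.  The result lies in
    [sigma, 2 max_radius + sigma].
    """
    pos = np.asarray(conf_set[ring_id], dtype=float)
    t = _tangent(pos, bead_i, closed)
    dirs = _azimuth_frame(t, params.n_azimuth)
    obst = _obstructions(conf_set, ring_id, bead_i, params, closed)
    half = 0.5 * params.sigma
    if obst.shape[0] == 0:
        return 2.0 * params.max_radius + params.sigma
    d = obst - pos[bead_i]
    d2 = np.einsum("ij,ij->i", d, d)
    proj = dirs @ d.T  # (n_az, n_obst)
    with np.errstate(divide="ignore"):
        bound = np.where(proj > 1e-12, d2[None, :] / (2.0 * proj), np.inf)
    rho = np.min(bound, axis=1) - half  # largest admissible radius per azimuth
    rho = np.clip(rho, 0.0, params.max_radius)
    return float(2.0 * np.min(rho) + params.sigma)


def ring_thickness(
    conf_set: Sequence[np.ndarray],
    ring_id: int,
    params: ThicknessParams = ThicknessParams(),
    closed: bool = True,
    bead_stride: int = 1,
) -> np.ndarray:
    """Thickness at every ``bead_stride``-th bead of one ring."""
    n = np.asarray(conf_set[ring_id]).shape[0]
    beads = range(0, n, bead_stride) if closed else range(1, n - 1, bead_stride)
    return np.array(
        [local_thickness(conf_set, ring_id, i, params, closed) for i in beads]
    )


def thickness_ensemble(
    frames: Iterable[Sequence[np.ndarray]],
    params: ThicknessParams = ThicknessParams(),
    bead_stride: int = 1,
) -> np.ndarray:
    """Pool per-bead thickness values over frames of unwrapped ring sets."""
    pooled: list[np.ndarray] = []
    for conf_set in frames:
        for rid in range(len(conf_set)):
            pooled.append(ring_thickness(conf_set, rid, params, bead_stride=bead_stride))
    if not pooled:
        return np.empty(0)
    return np.concatenate(pooled)
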