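"""Deterministic conformation generators with known topology and shape.

These fixtures let every analysis stage (writhe, shape, thickness,
contacts) be validated without running any simulation: planar and
uniformly twisted circles, interwound plectonemes of known writhe,
ellipsoid-shell point clouds, and parallel-strand probes.
"""

from __future__ import annotations

import numpy as np

from .model_core import RingConformation

__all__ = [
    "planar_circle",
    "twisted_circle",
    "plectoneme",
    "ellipsoid_shell",
    "parallel_strands",
]


def planar_circle(n: int, radius: float | None = None) -> RingConformation:
    """Regular n-gon in the xy plane with zero excess twist.

    Default radius gives unit bond length: R = 1 / (2 sin(pi/n)).
    """
    if n < 3:
        raise ValueError("need at least 3 beads")
    if radius is None:
        radius = 1.0 / (2.0 * np.sin(np.pi / n))
    ang = 2.0 * np.pi * np.arange(n) / n
    pos = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)])
    return RingConformation(pos, np.zeros(n))


def twisted_circle(n: int, delta_lk: float, radius: float | None = None) -> RingConformation:
    """Planar circle carrying uniform excess twist summing to delta_lk turns.

    The planar axis has Wr = 0, so Lk = Tw = delta_lk by construction.
    """
    conf = planar_circle(n, radius)
    conf.excess_twist = np.full(n, 2.0 * np.pi * delta_lk / n)
    return conf


def plectoneme(
    n: int,
    n_turns: float,
    superhelix_radius: float = 1.5,
    pitch: float = 6.0,
    handedness: str = "right",
) -> RingConformation:
    """Closed interwound superhelix capped by semicircular apical loops.

    Two strands wind around a common straight axis at the given superhelix
    radius and pitch (axial rise per strand winding), joined at both ends
    by semicircular apical loops — the idealised shape a supercoiled ring
    collapses into.  The writhe of this geometry is 2 W sin(gamma) with W
    strand windings and pitch angle sin(gamma) = pitch / winding length,
    so the winding count is chosen to make |Wr| ~ ``n_turns``.
    Right-handed interwinding yields negative writhe (the geometry of
    negatively supercoiled DNA): n_turns = 5, right-handed gives Wr ~ -5.

    Raises if the two strands would pass closer than ~0.8 bead diameters.
    """
    if n < 12:
        raise ValueError("need at least 12 beads for a capped plectoneme")
    if n_turns <= 0 or superhelix_radius <= 0 or pitch <= 0:
        raise ValueError("n_turns, superhelix_radius and pitch must be positive")
    sign = 1.0 if handedness == "right" else -1.0
    r = superhelix_radius
    sin_gamma = pitch / np.hypot(2.0 * np.pi * r, pitch)
    windings = n_turns / (2.0 * sin_gamma)
    height = windings * pitch
    # arc lengths: each helical strand, and two semicircular caps of radius r
    len_strand = np.hypot(2.0 * np.pi * windings * r, height)
    len_cap = np.pi * r
    total = 2.0 * len_strand + 2.0 * len_cap
    m_cap = max(3, int(round(n * len_cap / total)))
    m_strand = (n - 2 * m_cap) // 2
    if m_strand < 4:
        raise ValueError("too few beads for the requested geometry")
    n_extra = n - 2 * m_cap - 2 * m_strand  # absorb rounding into one strand

    def helix(m, phase, down=False):
        t = np.linspace(0.0, 1.0, m, endpoint=False)
        if down:
            t = 1.0 - t
        ang = sign * 2.0 * np.pi * windings * t + phase
        return np.column_stack([r * np.cos(ang), r * np.sin(ang), height * t])

    def cap(m, ang0, z, up=True):
        # semicircle joining diametrically opposite points (ang0, ang0+pi)
        s = np.linspace(0.0, np.pi, m, endpoint=False)[1:]  # skip shared endpoint
        u = np.array([np.cos(ang0), np.sin(ang0), 0.0])
        w = np.array([0.0, 0.0, 1.0 if up else -1.0])
        return z + np.outer(r * np.cos(s), u) + np.outer(r * np.sin(s), w)

    strand_a = helix(m_strand + n_extra, 0.0)
    ang_top = sign * 2.0 * np.pi * windings
    top = cap(m_cap + 1, ang_top, np.array([0.0, 0.0, height]), up=True)
    strand_b = helix(m_strand, np.pi, down=True)
    bottom = cap(m_cap + 1, np.pi, np.zeros(3), up=False)
    pos = np.vstack([strand_a, top, strand_b, bottom])
    assert pos.shape[0] == n

    # self-avoidance check between chain portions that are not local
    # neighbours along the contour (window scales with bead spacing)
    bond = np.linalg.norm(np.roll(pos, -1, axis=0) - pos, axis=1).mean()
    skip = max(2, int(np.ceil(2.5 / bond)))
    d = np.linalg.norm(pos[None, :, :] - pos[:, None, :], axis=-1)
    iu, ju = np.triu_indices(n, k=skip + 1)
    far = (ju - iu) <= n - skip - 1
    if np.min(d[iu[far], ju[far]]) < 0.9:
        raise ValueError("self-intersecting plectoneme parameters")
    return RingConformation(pos, np.zeros(n))


def ellipsoid_shell(
    a: float, b: float, c: float, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """n points on an ellipsoid shell with semiaxes a >= b >= c.

    Uniform points on the unit sphere are scaled by diag(a, b, c), which
    realises exactly the hollow-shell moment convention used by the shape
    solver: <x^2> = a^2/3 etc., so I_a = (m/3)(b^2 + c^2) and the
    inertial-ellipsoid round trip recovers (a, b, c) up to sampling
    noise.  Deterministic for a fixed seed.
    """
    if not (a >= b >= c > 0):
        raise ValueError("semiaxes must satisfy a >= b >= c > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u * np.array([a, b, c])


def parallel_strands(d: float, length: int, spacing: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Two straight bead rows along x at centre-centre distance d.

    The close-apposition probe fixture: at d = 1 bead diameter the local
    thickness at interior beads equals exactly one diameter.
    """
    if d < 1.0:
        raise ValueError("strand distance below one bead diameter")
    if length < 3:
        raise ValueError("need at least 3 beads per strand")
    x = spacing * np.arange(length, dtype=float)
    s1 = np.column_stack([x, np.zeros(length), np.zeros(length)])
    s2 = np.column_stack([x, np.full(length, d), np.zeros(length)])
    return s1, s2
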