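"""Characteristic inertial ellipsoids and scale-free shape descriptors.

A momentary chain conformation, taken as a rigid set of equal-mass beads,
is summarised by the ellipsoid that has the same mass and the same three
principal moments of inertia, with the mass spread over the ellipsoid
surface (hollow-shell convention: I_a = m/3 (b^2 + c^2) and cyclic).
From the ordered semiaxes a >= b >= c two dimensionless descriptors are
computed:

    asphericity  A = [(a-b)^2 + (a-c)^2 + (b-c)^2] / [2 (a+b+c)^2]
    prolateness  P = (2a-b-c)(2b-a-c)(2c-a-b) /
                     [2 (a^2+b^2+c^2-ab-ac-bc)^(3/2)]

A is 0 for a sphere and approaches 1 for a thin rod; P is +1 for
perfectly prolate (a > b = c) and -1 for perfectly oblate (a = b > c)
ellipsoids.  Both depend only on axis ratios, so the shell-vs-solid
moment convention cancels.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .model_core import EllipsoidAxes

__all__ = [
    "ShapeRecord",
    "inertial_ellipsoid",
    "asphericity",
    "prolateness",
    "asphericity_2d",
    "frequency_density",
    "shape_record",
]


@dataclass(frozen=True)
class ShapeRecord:
    axes: EllipsoidAxes
    asphericity: float
    prolateness: float


def inertial_ellipsoid(points: np.ndarray, mass: float = 1.0) -> EllipsoidAxes:
    """Semiaxes of the surface-mass ellipsoid matching the principal moments.

    The principal moments of inertia I1 <= I2 <= I3 of the equal-mass point
    set about its centroid are matched by a hollow ellipsoidal shell via
    I_a = (m/3)(b^2 + c^2) (cyclic), inverted as a^2 = 3(I_b + I_c - I_a)/(2m).
    Nearly planar or collinear sets give c ~ 0; a non-physical (negative)
    squared semiaxis from numerical noise is clamped to zero with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("points must be (n>=3, 3)")
    x = pts - pts.mean(axis=0)
    n = pts.shape[0]
    m_bead = mass / n
    # inertia tensor of the discrete mass distribution
    r2 = np.einsum("ij,ij->i", x, x)
    inertia = m_bead * (np.sum(r2) * np.eye(3) - x.T @ x)
    moments = np.sort(np.linalg.eigvalsh(inertia))  # I1 <= I2 <= I3
    i1, i2, i3 = moments
    sq = 1.5 / mass * np.array([i2 + i3 - i1, i1 + i3 - i2, i1 + i2 - i3])
    if np.any(sq < 0):
        if np.any(sq < -1e-9 * max(1.0, float(moments[2]))):
            warnings.warn("non-physical moment triple: semiaxis clamped to 0", RuntimeWarning)
        sq = np.clip(sq, 0.0, None)
    a, b, c = np.sqrt(sq)  # smallest moment -> largest semiaxis
    return EllipsoidAxes(a=float(a), b=float(b), c=float(c))


def asphericity(axes: EllipsoidAxes) -> float:
    """A(a,b,c) = [(a-b)^2 + (a-c)^2 + (b-c)^2] / [2(a+b+c)^2], in [0, 1]."""
    a, b, c = axes.a, axes.b, axes.c
    s = a + b + c
    if s <= 0:
        raise ValueError("axes must not all be zero")
    return float(((a - b) ** 2 + (a - c) ** 2 + (b - c) ** 2) / (2.0 * s * s))


def prolateness(axes: EllipsoidAxes) -> float:
    """P(a,b,c) in [-1, 1]; 0 by convention for a perfect sphere (0/0 case)."""
    a, b, c = axes.a, axes.b, axes.c
    q = a * a + b * b + c * c - a * b - a * c - b * c
    if q <= 1e-24 * max(a, 1.0) ** 2:
        return 0.0
    num = (2 * a - b - c) * (2 * b - a - c) * (2 * c - a - b)
    return float(np.clip(num / (2.0 * q**1.5), -1.0, 1.0))


def asphericity_2d(points: np.ndarray) -> float:
    """Planar asphericity A = (a - b)^2 / (a + b)^2 of traced 2D point sets.

    a >= b are the principal values (eigenvalues) of the 2D radius-of-
    gyration tensor.  0 for an isotropic trace, 1 for collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("points must be (n>=3, 2)")
    x = pts - pts.mean(axis=0)
    gyr = x.T @ x / pts.shape[0]
    lam2, lam1 = np.sort(np.linalg.eigvalsh(gyr))  # lam1 >= lam2
    if lam1 <= 0:
        raise ValueError("all points identical: gyration tensor is zero")
    return float((lam1 - lam2) ** 2 / (lam1 + lam2) ** 2)


def frequency_density(
    values: np.ndarray, bins: int | str | np.ndarray = "fd"
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram normalised to unit integral (frequency density profile).

    Returns (bin_centers, density).  Default binning is Freedman-Diaconis
    ('fd'); pass an int or explicit edges to override.  Degenerate inputs
    (a single value, or zero spread) fall back to a single narrow bin.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("no values to bin")
    if np.ptp(v) == 0.0:
        width = max(abs(v[0]) * 1e-6, 1e-12)
        edges = np.array([v[0] - width / 2, v[0] + width / 2])
        dens = np.array([1.0 / width])
        return np.array([v[0]]), dens
    dens, edges = np.histogram(v, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dens


def shape_record(points: np.ndarray) -> ShapeRecord:
    """Axes + asphericity + prolateness of one conformation."""
    axes = inertial_ellipsoid(points)
    return ShapeRecord(axes=axes, asphericity=asphericity(axes), prolateness=prolateness(axes))
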