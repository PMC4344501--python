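"""Reduced units, data model and energy terms of the coarse-grained DNA force field.

A circular DNA molecule is modelled as a closed chain of beads of diameter
one Lennard-Jones length unit (sigma_LJ = 3 nm, the screened effective
diameter of B-DNA).  The Hamiltonian has four terms:

* purely repulsive cut Lennard-Jones excluded volume (r_cut = 1 sigma_LJ),
* harmonic stretching of consecutive bonds,
* bending energy  eps_b * (1 - cos theta)  per junction, with
  eps_b = 17 eps_0 calibrated to a 50 nm persistence length,
* harmonic torsion  (k_twist/2) * phi**2  per junction, where phi is the
  excess-twist angle read off material frames attached to the mid-points
  of consecutive bonds.

Energies are in eps_0 = 1 kT, lengths in sigma_LJ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ReducedUnits",
    "RingTopologySpec",
    "ForceField",
    "RingConformation",
    "SystemState",
    "EllipsoidAxes",
    "energy_repulsive",
    "energy_bend",
    "energy_bond",
    "energy_twist",
    "persistence_length",
    "bond_vectors",
    "junction_angles",
]

#: energy cap (eps_0) applied per pair when beads nearly overlap
_OVERLAP_CAP = 1.0e8


@dataclass(frozen=True)
class ReducedUnits:
    """Mapping between reduced simulation units and physical units."""

    length_unit_nm: float = 3.0          # nm per sigma_LJ
    energy_unit_J: float = 4.0e-21       # J per eps_0 (1 kT)
    bp_per_bead: float = 3000.0 / 334.0  # ~8.98 bp represented by one bead

    def __post_init__(self) -> None:
        if self.length_unit_nm <= 0 or self.energy_unit_J <= 0 or self.bp_per_bead <= 0:
            raise ValueError("reduced-unit scales must be positive")


@dataclass(frozen=True)
class RingTopologySpec:
    """Size and linking deficit of one circular molecule.

    The supercoiling density is sigma = delta_lk / (n_bp / helical_repeat);
    delta_lk = -7 and -14 on a 3 kb ring give sigma ~ -0.025 and -0.05.
    """

    n_beads: int = 334
    delta_lk: float = 0.0
    n_bp: float = 3000.0
    helical_repeat: float = 10.5

    def __post_init__(self) -> None:
        if self.n_beads < 3:
            raise ValueError("a ring needs at least 3 beads")
        if self.n_bp <= 0 or self.helical_repeat <= 0:
            raise ValueError("n_bp and helical_repeat must be positive")

    @property
    def lk0(self) -> float:
        """Relaxed linking number n_bp / helical_repeat."""
        return self.n_bp / self.helical_repeat

    @property
    def sigma(self) -> float:
        return self.delta_lk / self.lk0


@dataclass(frozen=True)
class ForceField:
    """All energy parameters, in reduced units (eps_0, sigma_LJ)."""

    eps_rep: float = 1.0        # repulsive LJ scale
    r_cut_rep: float = 1.0      # purely repulsive truncation
    k_bond: float = 800.0       # harmonic bond stiffness, eps_0/sigma^2
    r0_bond: float = 1.0        # equilibrium bond length
    eps_bend: float = 17.0      # bending stiffness, eps_0
    k_twist: float = 31.7       # per-junction twist stiffness, eps_0/rad^2
    ep_eps: float = 8.0         # enhancer-promoter well depth
    ep_rcut: float = 2.0        # enhancer-promoter cutoff

    def __post_init__(self) -> None:
        for name in ("eps_rep", "k_bond", "eps_bend", "k_twist", "ep_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.r_cut_rep <= 0 or self.ep_rcut <= 0 or self.r0_bond <= 0:
            raise ValueError("cutoffs and bond length must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ForceField":
        return cls(**d)


@dataclass
class RingConformation:
    """One circular molecule: bead positions plus per-junction excess twist.

    ``positions`` are contiguous (unwrapped) coordinates in sigma_LJ;
    ``excess_twist`` holds the signed excess-twist angle (radians) of each
    of the n junctions of the closed ring, so that
    Tw = sum(excess_twist) / 2 pi   in turns.
    """

    positions: np.ndarray
    excess_twist: np.ndarray | None = None
    ring_id: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if self.n_beads < 3:
            raise ValueError("a ring needs at least 3 beads")
        if self.excess_twist is None:
            self.excess_twist = np.zeros(self.n_beads)
        else:
            self.excess_twist = np.asarray(self.excess_twist, dtype=float)
            if self.excess_twist.shape != (self.n_beads,):
                raise ValueError("excess_twist must have one angle per junction")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "RingConformation":
        return RingConformation(
            self.positions.copy(), self.excess_twist.copy(), self.ring_id
        )


@dataclass
class SystemState:
    """M rings in a cubic periodic box (box_length = inf means dilute)."""

    rings: list
    box_length: float = np.inf
    step: int = 0

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    @property
    def n_beads_total(self) -> int:
        return sum(r.n_beads for r in self.rings)

    def volume_fraction(self) -> float:
        """Bead-sphere volume fraction phi of the periodic box."""
        if not np.isfinite(self.box_length):
            return 0.0
        v_beads = self.n_beads_total * (np.pi / 6.0)
        return v_beads / self.box_length**3

    def all_positions(self) -> np.ndarray:
        return np.concatenate([r.positions for r in self.rings], axis=0)

    def wrapped_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates folded into [0, L) plus integer image flags.

        ``unwrapped = wrapped + image_flags * box_length`` exactly.
        """
        pos = self.all_positions()
        if not np.isfinite(self.box_length):
            return pos.copy(), np.zeros(pos.shape, dtype=np.int64)
        flags = np.floor(pos / self.box_length).astype(np.int64)
        return pos - flags * self.box_length, flags

    def copy(self) -> "SystemState":
        return SystemState([r.copy() for r in self.rings], self.box_length, self.step)


@dataclass(frozen=True)
class EllipsoidAxes:
    """Semiaxes of a characteristic inertial ellipsoid, ordered a >= b >= c."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b >= self.c >= 0.0):
            raise ValueError("semiaxes must satisfy a >= b >= c >= 0")
        if self.a <= 0:
            raise ValueError("largest semiaxis must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])


# ---------------------------------------------------------------------------
# geometry helpers

def bond_vectors(positions: np.ndarray, closed: bool = True) -> np.ndarray:
    """Consecutive bond vectors; for a closed ring the last bond closes it."""
    positions = np.asarray(positions, dtype=float)
    if closed:
        return np.roll(positions, -1, axis=0) - positions
    return positions[1:] - positions[:-1]


def junction_angles(positions: np.ndarray, closed: bool = True) -> np.ndarray:
    """Angle theta_i between consecutive bond vectors at every junction."""
    e = bond_vectors(positions, closed=closed)
    norms = np.linalg.norm(e, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-length bond: junction angle undefined")
    t = e / norms[:, None]
    if closed:
        cos_t = np.einsum("ij,ij->i", t, np.roll(t, -1, axis=0))
    else:
        cos_t = np.einsum("ij,ij->i", t[:-1], t[1:])
    return np.arccos(np.clip(cos_t, -1.0, 1.0))


# ---------------------------------------------------------------------------
# energy terms

def _min_image(d: np.ndarray, box: float | None) -> np.ndarray:
    if box is not None and np.isfinite(box):
        d = d - box * np.round(d / box)
    return d


def energy_repulsive(
    positions: np.ndarray,
    box: float | None,
    ff: ForceField,
    closed: bool = True,
) -> float:
    """Excluded-volume energy of one chain: cut LJ, repulsive part only.

    U = sum over non-bonded pairs of 4 eps [(sigma/r)^12 - (sigma/r)^6]
    for r < r_cut = 1 sigma_LJ (where the LJ potential crosses zero, so the
    truncation is continuous).  Pair distances use the minimum-image
    convention when ``box`` is finite.  Nearly overlapping beads have their
    pair energy capped and raise a warning rather than overflowing.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n < 2:
        return 0.0
    d = _min_image(positions[None, :, :] - positions[:, None, :], box)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    iu, ju = np.triu_indices(n, k=1)
    sep = ju - iu
    bonded = sep == 1
    if closed:
        bonded |= sep == n - 1
    mask = ~bonded
    r2p = r2[iu[mask], ju[mask]]
    return _pair_lj_sum(r2p, ff.eps_rep, ff.r_cut_rep)


def _pair_lj_sum(r2: np.ndarray, eps: float, rcut: float) -> float:
    inside = r2 < rcut * rcut
    r2 = r2[inside]
    if r2.size == 0:
        return 0.0
    with np.errstate(divide="ignore", over="ignore"):
        inv6 = 1.0 / r2**3
        u = 4.0 * eps * (inv6 * inv6 - inv6)
    if np.any(~np.isfinite(u)) or np.any(u > _OVERLAP_CAP):
        warnings.warn("near-overlapping beads: repulsive energy capped", RuntimeWarning)
        u = np.minimum(np.nan_to_num(u, nan=_OVERLAP_CAP, posinf=_OVERLAP_CAP), _OVERLAP_CAP)
    return float(np.sum(u))


def energy_bond(positions: np.ndarray, ff: ForceField, closed: bool = True) -> float:
    """Harmonic stretching energy  sum (k_bond/2) (r_i - r0)^2."""
    r = np.linalg.norm(bond_vectors(positions, closed=closed), axis=1)
    return float(0.5 * ff.k_bond * np.sum((r - ff.r0_bond) ** 2))


def energy_bend(positions: np.ndarray, ff: ForceField, closed: bool = True) -> float:
    """Bending energy  sum eps_b (1 - cos theta_i) over junctions.

    With this form the equilibrium tangent correlation per junction is
    <cos theta> = coth(kappa) - 1/kappa, giving a persistence length of
    ~17 beads = 50 nm at kappa = 17.
    """
    theta = junction_angles(positions, closed=closed)
    return float(ff.eps_bend * np.sum(1.0 - np.cos(theta)))


def energy_twist(conf: RingConformation, ff: ForceField) -> float:
    """Torsional energy  sum (k_twist/2) phi_i^2 over the ring's junctions."""
    phi = np.asarray(conf.excess_twist, dtype=float)
    return float(0.5 * ff.k_twist * np.sum(phi * phi))


def persistence_length(
    eps_bend: float, bond: float = 1.0, units: ReducedUnits | None = None
) -> float:
    """Persistence length of the kappa (1 - cos theta) chain.

    The junction Boltzmann factor exp(kappa cos theta) gives
    <cos theta> = coth kappa - 1/kappa, hence an exponential tangent
    correlation with decay length  L_p = -b / ln(<cos theta>).

    Parameters
    ----------
    eps_bend : bending stiffness kappa in eps_0 (must exceed 1 so that
        <cos theta> > 0 and the decay length is defined).
    bond : bead spacing b. In sigma_LJ if ``units`` is None, in nm otherwise
        irrelevant — the result is returned in the same unit as ``bond``
        unless ``units`` is given, in which case ``bond`` is interpreted in
        sigma_LJ and the result converted to nm.
    """
    kappa = float(eps_bend)
    if kappa <= 0:
        raise ValueError("bending stiffness must be positive")
    mean_cos = 1.0 / np.tanh(kappa) - 1.0 / kappa
    if mean_cos <= 0:
        raise ValueError("chain too flexible: tangent correlation not positive")
    lp = -bond / np.log(mean_cos)
    if units is not None:
        lp *= units.length_unit_nm
    return float(lp)
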