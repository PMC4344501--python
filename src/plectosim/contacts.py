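"""Enhancer-promoter attraction and contact-fraction statistics.

Two beads on the same molecule, half the ring apart (167 beads on a
334-bead ring), are given a mutual affinity: a full Lennard-Jones well of
depth 8 kT truncated and shifted to vanish at two bead diameters.  A pair
is "in contact" when its surface-to-surface distance is below one bead
diameter, i.e. centre-centre distance < 2 sigma_LJ for unit beads.  The
observable is the fraction of sampled frames spent in contact, with a
block-averaged standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import ForceField

__all__ = ["EPSpec", "ep_energy", "contact_fraction", "ep_distances", "make_linear_control"]


@dataclass(frozen=True)
class EPSpec:
    enhancer_bead: int = 0
    promoter_bead: int = 167
    eps: float = 8.0            # well depth, eps_0
    rcut: float = 2.0           # sigma_LJ; potential shifted to 0 here
    contact_dist: float = 2.0   # centre-centre contact threshold, sigma_LJ

    def __post_init__(self) -> None:
        if self.eps < 0 or self.rcut <= 0:
            raise ValueError("eps must be >= 0 and rcut > 0")
        if self.contact_dist > self.rcut + 1e-12:
            raise ValueError("contact_dist must not exceed rcut")

    def separation(self, n_beads: int) -> int:
        """Genomic separation along the ring, in beads."""
        d = abs(self.promoter_bead - self.enhancer_bead) % n_beads
        return min(d, n_beads - d)


def ep_energy(r: float | np.ndarray, spec: EPSpec = EPSpec()) -> float | np.ndarray:
    """Truncated-and-shifted attractive LJ between the site pair.

    U(r) = 4 eps [(1/r)^12 - (1/r)^6] - U_LJ(rcut) for r < rcut, else 0;
    the shift keeps the potential continuous (no impulsive force) at rcut.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    inv6 = 1.0 / r**6
    u = 4.0 * spec.eps * (inv6 * inv6 - inv6)
    rc6 = 1.0 / spec.rcut**6
    shift = 4.0 * spec.eps * (rc6 * rc6 - rc6)
    out = np.where(r < spec.rcut, u - shift, 0.0)
    return float(out) if out.ndim == 0 else out


def ep_distances(frames, spec: EPSpec = EPSpec()) -> np.ndarray:
    """Centre-centre enhancer-promoter distance per frame and molecule.

    ``frames`` iterates over lists of unwrapped (n, 3) ring coordinate
    arrays (one list per frame).  Returns shape (n_frames, n_rings).
    """
    rows = []
    for conf_set in frames:
        rows.append(
            [
                float(np.linalg.norm(pos[spec.enhancer_bead] - pos[spec.promoter_bead]))
                for pos in (np.asarray(p, dtype=float) for p in conf_set)
            ]
        )
    return np.array(rows)


def contact_fraction(
    distances: np.ndarray, spec: EPSpec = EPSpec(), n_blocks: int = 10
) -> tuple[float, float]:
    """Fraction of frames in contact, with block-averaged standard error.

    ``distances`` is (n_frames,) or (n_frames, n_molecules); the fraction
    is pooled over molecules, and the error is estimated from ``n_blocks``
    contiguous time blocks (robust to serial correlation up to the block
    length).
    """
    d = np.atleast_2d(np.asarray(distances, dtype=float).T).T  # (n_frames, n_mol)
    if d.shape[0] == 0:
        raise ValueError("no frames")
    hits = (d < spec.contact_dist).mean(axis=1)
    frac = float(hits.mean())
    nb = min(n_blocks, d.shape[0])
    blocks = np.array_split(hits, nb)
    bm = np.array([b.mean() for b in blocks])
    se = float(bm.std(ddof=1) / np.sqrt(nb)) if nb > 1 else float("nan")
    return frac, se


def umbrella_contact_fraction(
    conf,
    ff: ForceField,
    spec: EPSpec,
    delta_lk: float | None = None,
    d0_windows: np.ndarray | None = None,
    bias_k: float = 1.0,
    n_sweeps: int = 1200,
    n_equil: int = 300,
    sample_every: int = 3,
    seed: int = 0,
    n_bootstrap: int = 16,
    **mc_kwargs,
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Equilibrium contact fraction via umbrella sampling along the pair distance.

    The spontaneous juxtaposition of two sites half a ring apart is a rare
    event, so the free-energy profile of the site-pair separation d is
    obtained from harmonically restrained windows (WHAM-stitched), and the
    contact fraction under the attractive site potential follows by exact
    reweighting:

        f = sum_{d < d_c} P(d) e^{-U_ep(d)} / sum_d P(d) e^{-U_ep(d)}

    where P(d) is the unbiased separation density of the molecule *without*
    the attraction.  Windows walk inward from the largest d0; each
    continues from the previous window's final conformation.

    For systems with a slow orthogonal coordinate (the writhe of a
    supercoiled ring), pass several *legs*: ``conf`` a list of starting
    conformations and ``d0_windows`` a matching list of window sequences,
    each leg walking from its own initial basin; all window histograms
    are stitched jointly.

    Returns (fraction, bootstrap standard error, (bin_centers, P)).
    """
    from .mc_sampler import sample_ring

    if d0_windows is None:
        d0_windows = np.arange(20.0, 1.0, -2.0)
    if isinstance(conf, (list, tuple)):
        legs = list(zip(conf, d0_windows))
    else:
        legs = [(conf, d0_windows)]
    rng = np.random.default_rng(seed)
    d_top = max(float(np.max(w)) for _, w in legs)
    edges = np.arange(0.85, d_top + 6.0, 0.25)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = []
    biases = []
    for leg_conf, windows in legs:
        work = leg_conf.copy() if hasattr(leg_conf, "copy") else np.array(leg_conf)
        for d0 in np.atleast_1d(windows):
            # stronger springs at tight separations keep the window on target
            k_w = bias_k if d0 >= 5.0 else bias_k * 4.0
            res = sample_ring(
                work, ff,
                n_sweeps=n_equil + n_sweeps,
                sample_every=sample_every,
                seed=int(rng.integers(2**31)),
                delta_lk=delta_lk,
                ep_sites=(spec.enhancer_bead, spec.promoter_bead),
                ep_eps=0.0,
                bias=(k_w, float(d0)),
                **mc_kwargs,
            )
            keep = res.positions[n_equil // sample_every :]
            d = np.linalg.norm(
                keep[:, spec.enhancer_bead] - keep[:, spec.promoter_bead], axis=1
            )
            counts.append(np.histogram(d, bins=edges)[0].astype(float))
            biases.append(0.5 * k_w * (centers - d0) ** 2)
    counts = np.array(counts)
    biases = np.array(biases)

    def _wham_fraction(cnt):
        p = _wham(cnt, biases)
        boltz = np.exp(-np.minimum(ep_energy(centers, spec), 50.0))
        num = float(np.sum(p * boltz * (centers < spec.contact_dist)))
        den = float(np.sum(p * boltz))
        return num / den if den > 0 else 0.0

    frac = _wham_fraction(counts)
    boots = []
    n_frames = counts.sum(axis=1)
    for _ in range(n_bootstrap):
        resampled = np.array(
            [
                rng.multinomial(int(n_frames[w]), counts[w] / n_frames[w])
                if n_frames[w] > 0
                else counts[w]
                for w in range(counts.shape[0])
            ],
            dtype=float,
        )
        boots.append(_wham_fraction(resampled))
    se = float(np.std(boots, ddof=1)) if n_bootstrap > 1 else float("nan")
    return frac, se, (centers, _wham(counts, biases))


def _wham(counts: np.ndarray, biases: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Weighted-histogram stitching of umbrella windows (1-D, kT = 1)."""
    n_w = counts.shape[0]
    n_frames = counts.sum(axis=1)
    f = np.zeros(n_w)
    total = counts.sum(axis=0)
    p = np.where(total > 0, total, 0.0)
    p = p / p.sum()
    expb = np.exp(-biases)  # (n_w, n_bins)
    for _ in range(n_iter):
        denom = (n_frames[:, None] * np.exp(f)[:, None] * expb).sum(axis=0)
        p = np.where(denom > 0, total / np.where(denom > 0, denom, 1.0), 0.0)
        s = p.sum()
        if s <= 0:
            break
        p /= s
        f = -np.log(np.maximum((expb * p[None, :]).sum(axis=1), 1e-300))
    return p


def make_linear_control(
    spec: EPSpec, n_beads: int, ff: ForceField | None = None
) -> tuple[np.ndarray, ForceField, EPSpec]:
    """Open-chain control with the same genomic separation and affinity.

    Returns straight-line initial coordinates (n_beads beads, n_beads - 1
    bonds, no closure), a force field with the torsion term switched off
    (a linear molecule is torsionally unconstrained), and the unchanged
    site specification.
    """
    ff = ff if ff is not None else ForceField()
    pos = np.column_stack(
        [np.arange(n_beads, dtype=float), np.zeros(n_beads), np.zeros(n_beads)]
    )
    ff_linear = ForceField(**{**ff.to_dict(), "k_twist": 0.0})
    return pos, ff_linear, spec
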