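"""Brownian-dynamics propagation of multi-ring systems under PBC.

The integrator is overdamped Euler-Maruyama at kT = 1 with friction
gamma = 1 per bead.  Torsion is carried by a unit material normal per
bond: after every position update the normals are parallel-transported
onto the new tangents (which conserves the linking number — writhe
changes are absorbed as opposite twist), forces on positions include the
holonomy gradient of the twist energy, and the frame angles themselves
undergo torsional Langevin rotation.  Crowding is produced by slowly
shrinking the periodic box while rescaling molecule centroids.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model_core import ForceField, RingConformation, RingTopologySpec, SystemState

__all__ = [
    "RunProtocol",
    "Trajectory",
    "NotEquilibratedError",
    "box_length_for_phi",
    "init_system",
    "run_bd",
    "step",
    "compress_box",
    "detect_equilibration",
    "unwrap_molecules",
    "radius_of_gyration",
    "write_trajectory",
    "read_trajectory",
    "frames_from_conformation",
    "twist_angles_from_frames",
]


class NotEquilibratedError(RuntimeError):
    """Raised when a radius-of-gyration series shows no usable plateau."""


@dataclass(frozen=True)
class RunProtocol:
    """Integration and sampling parameters of one BD run (reduced units)."""

    dt: float = 5.0e-4
    gamma: float = 1.0
    gamma_t: float = 1.0
    n_steps: int = 10_000
    sample_every: int = 1000
    target_phi: float = 0.0
    compression_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt > 1e-3:
            raise ValueError("dt must be in (0, 1e-3] for stability at k_bond = 800")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if not (0.0 <= self.target_phi <= 0.3):
            raise ValueError("target_phi must be in [0, 0.3]")


@dataclass
class Trajectory:
    """Sampled frames of one run: unwrapped positions + twist angles.

    ``positions`` has shape (n_frames, m_rings * n_ring, 3); ``phi`` the
    per-junction excess-twist angles, ``box`` and ``steps`` one entry per
    frame.  ``metadata`` carries protocol, force field and seed so a run
    can be replayed.
    """

    positions: np.ndarray
    phi: np.ndarray
    box: np.ndarray
    steps: np.ndarray
    n_ring: int
    m_rings: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def ring_positions(self, frame: int) -> list[np.ndarray]:
        """Per-ring unwrapped coordinate arrays of one frame."""
        p = self.positions[frame]
        return [p[m * self.n_ring : (m + 1) * self.n_ring] for m in range(self.m_rings)]

    def to_state(self, frame: int) -> SystemState:
        rings = [
            RingConformation(
                pos.copy(),
                self.phi[frame][m * self.n_ring : (m + 1) * self.n_ring].copy(),
                ring_id=m,
            )
            for m, pos in enumerate(self.ring_positions(frame))
        ]
        return SystemState(rings, float(self.box[frame]), int(self.steps[frame]))


def config_hash(obj) -> str:
    """Short deterministic hash of a JSON-serialisable config object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# system construction

def box_length_for_phi(m_rings: int, n_beads: int, phi: float) -> float:
    """Cubic box edge giving bead-volume fraction phi: L = (M n pi/6 / phi)^(1/3)."""
    if phi <= 0:
        return float("inf")
    return (m_rings * n_beads * (np.pi / 6.0) / phi) ** (1.0 / 3.0)


def init_system(
    spec: RingTopologySpec,
    m_rings: int = 20,
    phi: float = 0.0,
    seed: int = 0,
    stacked: bool = False,
) -> SystemState:
    """Planar circles on a cubic lattice, with Lk imposed by construction.

    Each ring starts as a regular planar polygon (Wr = 0) carrying uniform
    excess twist summing to ``spec.delta_lk`` turns, so Lk = Tw = delta_lk
    exactly.  ``phi = 0`` means the dilute limit (no box).  For phi > 0
    the box edge follows from the bead volume fraction; if the planar
    circles cannot be placed in that box without overlap the requested
    occupancy must instead be reached through :func:`compress_box` from a
    dilute start, and a ValueError explains so.

    ``stacked=True`` places the circles coaxially, 3 sigma apart along the
    stack axis (parallel planes cannot overlap) — the compact dilute start
    used before box compression.
    """
    from .fixtures import twisted_circle

    if not (0.0 <= phi <= 0.3):
        raise ValueError("phi must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    n = spec.n_beads
    diameter = 1.0 / np.sin(np.pi / n) + 1.0
    rings = []
    if phi <= 0.0:
        spacing = 3.0 if stacked else diameter + 10.0
        for m in range(m_rings):
            conf = twisted_circle(n, spec.delta_lk)
            conf.positions = conf.positions + np.array([0.0, 0.0, m * spacing])
            conf.ring_id = m
            rings.append(conf)
        return SystemState(rings, box_length=np.inf)

    box = box_length_for_phi(m_rings, n, phi)
    per_side = int(np.ceil(m_rings ** (1.0 / 3.0)))
    spacing = box / per_side
    if spacing < diameter:
        raise ValueError(
            f"phi={phi:g} too high to place {m_rings} planar {n}-bead circles "
            f"without overlap (need spacing {diameter:.1f}, have {spacing:.1f}); "
            "initialise dilute and use compress_box to reach this occupancy"
        )
    sites = [
        (ix, iy, iz)
        for ix in range(per_side)
        for iy in range(per_side)
        for iz in range(per_side)
    ][:m_rings]
    for m, (ix, iy, iz) in enumerate(sites):
        conf = twisted_circle(n, spec.delta_lk)
        ang = rng.uniform(0.0, np.pi, 2)
        rx = _rotation_matrix([1.0, 0.0, 0.0], ang[0]) @ _rotation_matrix(
            [0.0, 0.0, 1.0], ang[1]
        )
        conf.positions = conf.positions @ rx.T + (np.array([ix, iy, iz]) + 0.5) * spacing
        conf.ring_id = m
        rings.append(conf)
    return SystemState(rings, box_length=box)


def _rotation_matrix(axis, angle) -> np.ndarray:
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * (kx @ kx)


# ---------------------------------------------------------------------------
# material frames <-> twist angles

def frames_from_conformation(conf: RingConformation) -> np.ndarray:
    """Edge material normals realising the stored excess-twist angles.

    The normal of edge 0 is an arbitrary unit vector perpendicular to the
    first tangent; each subsequent normal is the parallel transport of the
    previous one rotated by the stored junction angle about the new
    tangent.
    """
    pos = conf.positions
    n = conf.n_beads
    e = np.roll(pos, -1, axis=0) - pos
    t = e / np.linalg.norm(e, axis=1, keepdims=True)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(t[0] @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    m0 = ref - (ref @ t[0]) * t[0]
    m0 /= np.linalg.norm(m0)
    mnorm = np.empty((n, 3))
    mnorm[0] = m0
    for k in range(1, n):
        transported = _transport_py(t[k - 1], t[k], mnorm[k - 1])
        phi = conf.excess_twist[k]
        mnorm[k] = _rotate_py(transported, t[k], phi)
        mnorm[k] -= (mnorm[k] @ t[k]) * t[k]
        mnorm[k] /= np.linalg.norm(mnorm[k])
    return mnorm


def twist_angles_from_frames(pos: np.ndarray, mnorm: np.ndarray) -> np.ndarray:
    """Per-junction excess-twist angles of one closed ring."""
    n = pos.shape[0]
    phi = np.zeros(n)
    _kernels.compute_phi(
        np.ascontiguousarray(pos, dtype=np.float64),
        np.ascontiguousarray(mnorm, dtype=np.float64),
        n, 1, True, phi,
    )
    return phi


def _transport_py(a, b, v):
    k = np.cross(a, b)
    s = np.linalg.norm(k)
    c = float(a @ b)
    if s < 1e-12:
        return v if c > 0 else -v
    k = k / s
    return v * c + np.cross(k, v) * s + k * (k @ v) * (1 - c)


def _rotate_py(v, axis, angle):
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)


# ---------------------------------------------------------------------------
# propagation

def _flatten(state: SystemState) -> tuple[np.ndarray, np.ndarray, int, int]:
    n = state.rings[0].n_beads
    for r in state.rings:
        if r.n_beads != n:
            raise ValueError("all rings must have equal length")
    pos = np.ascontiguousarray(state.all_positions(), dtype=np.float64)
    mnorm = np.vstack([frames_from_conformation(r) for r in state.rings])
    return pos, np.ascontiguousarray(mnorm), n, state.n_rings


def run_bd(
    state: SystemState,
    ff: ForceField,
    proto: RunProtocol,
    closed: bool = True,
    ep_sites: tuple[int, int] | None = None,
) -> Trajectory:
    """Propagate ``state`` in place for ``proto.n_steps`` and sample frames."""
    pos, mnorm, n, m = _flatten(state)
    box = state.box_length if np.isfinite(state.box_length) else -1.0
    ep_i, ep_j = ep_sites if ep_sites is not None else (-1, -1)
    s_pos, s_phi, s_en = _kernels.bd_run(
        pos, mnorm, n, m, box, closed,
        ff.eps_bend, ff.eps_rep, ff.k_bond, ff.r0_bond, ff.k_twist,
        ep_i, ep_j, ff.ep_eps if ep_sites else 0.0, ff.ep_rcut,
        proto.dt, proto.gamma, proto.gamma_t,
        proto.n_steps, proto.sample_every, proto.seed % 2**31,
    )
    # write the final state back
    phi_final = np.zeros(n * m)
    if ff.k_twist > 0 and closed:
        _kernels.compute_phi(pos, mnorm, n, m, closed, phi_final)
    for k, r in enumerate(state.rings):
        r.positions = pos[k * n : (k + 1) * n].copy()
        r.excess_twist = phi_final[k * n : (k + 1) * n].copy()
    state.step += proto.n_steps
    meta = {
        "protocol": {k: getattr(proto, k) for k in proto.__dataclass_fields__},
        "force_field": ff.to_dict(),
        "seed": proto.seed,
    }
    meta["config_hash"] = config_hash(meta)
    nf = s_pos.shape[0]
    steps = state.step - proto.n_steps + proto.sample_every * (1 + np.arange(nf))
    return Trajectory(
        positions=s_pos,
        phi=s_phi,
        box=np.full(nf, state.box_length),
        steps=steps,
        n_ring=n,
        m_rings=m,
        metadata=meta,
    )


def step(state: SystemState, ff: ForceField, proto: RunProtocol, closed: bool = True) -> SystemState:
    """Advance the system by a single BD step (convenience wrapper)."""
    one = RunProtocol(
        dt=proto.dt, gamma=proto.gamma, gamma_t=proto.gamma_t,
        n_steps=1, sample_every=1, seed=proto.seed,
    )
    run_bd(state, ff, one, closed=closed)
    return state


def radius_of_gyration(positions: np.ndarray) -> float:
    x = positions - positions.mean(axis=0)
    return float(np.sqrt(np.einsum("ij,ij->", x, x) / positions.shape[0]))


def compress_box(
    state: SystemState,
    target_phi: float,
    ff: ForceField,
    rate: float = 0.005,
    relax_sweeps: int = 20,
    seed: int = 0,
    method: str = "mc",
    proto: RunProtocol | None = None,
    delta_lk: float | None = None,
) -> SystemState:
    """Shrink the periodic box to the target occupancy, relaxing in between.

    Every interval the edge is multiplied by (1 - rate) and molecule
    centroids are rescaled (internal coordinates untouched), followed by a
    relaxation stint — Metropolis sweeps by default, or BD when
    ``method='bd'``.  The final edge is set exactly for ``target_phi``.
    Raises if a shrink step produces core overlaps (< 0.5 sigma).
    """
    from .mc_sampler import sample_system

    if target_phi <= 0:
        raise ValueError("target_phi must be positive")
    n_tot = state.n_beads_total
    target_box = (n_tot * (np.pi / 6.0) / target_phi) ** (1.0 / 3.0)
    if not np.isfinite(state.box_length):
        # enclose the current configuration in a generous starting box
        allpos = state.all_positions()
        state.box_length = float(np.ptp(allpos, axis=0).max() + 4.0)
    if state.box_length <= target_box:
        state.box_length = max(state.box_length, target_box)
        return state

    interval = 0
    while state.box_length > target_box:
        new_box = max(state.box_length * (1.0 - rate), target_box)
        scale = new_box / state.box_length
        for r in state.rings:
            centroid = r.positions.mean(axis=0)
            r.positions = r.positions + centroid * (scale - 1.0)
        state.box_length = new_box
        _check_core_overlaps(state)
        # below ~2% occupancy the relaxation between shrinks can be shorter
        eff_relax = (
            max(4, relax_sweeps // 3)
            if state.volume_fraction() < 0.02
            else relax_sweeps
        )
        if method == "bd":
            p = proto or RunProtocol()
            relax = RunProtocol(
                dt=p.dt, gamma=p.gamma, gamma_t=p.gamma_t,
                n_steps=relax_sweeps * 100, sample_every=relax_sweeps * 100,
                seed=(seed + interval) % 2**31,
            )
            run_bd(state, ff, relax)
        else:
            sample_system(
                state, ff, n_sweeps=eff_relax, sample_every=0,
                seed=(seed + interval) % 2**31, delta_lk=delta_lk, d_max=0.8,
            )
        interval += 1
    if abs(state.volume_fraction() - target_phi) > 1e-3 * target_phi:
        raise RuntimeError("compression did not reach the target occupancy")
    return state


def _check_core_overlaps(state: SystemState) -> None:
    pos = state.all_positions()
    box = state.box_length
    n = state.rings[0].n_beads
    d = pos[None, :, :] - pos[:, None, :]
    if np.isfinite(box):
        d -= box * np.round(d / box)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    iu, ju = np.triu_indices(pos.shape[0], k=1)
    same = (iu // n) == (ju // n)
    sep = ju - iu
    bonded = same & ((sep == 1) | (sep == n - 1))
    r2min = r2[iu[~bonded], ju[~bonded]].min()
    if r2min < 0.25:
        raise RuntimeError("compression produced core overlaps (< 0.5 sigma)")


# ---------------------------------------------------------------------------
# equilibration detection

def detect_equilibration(rg_series: np.ndarray, window_frac: float = 0.05) -> int:
    """First frame index after which molecule Rg series have plateaued.

    For each molecule the running tail mean (from candidate index t to the
    end) must agree with the final-half mean within one standard error of
    that tail mean.  The error is estimated from batch means of the final
    half, which accounts for the serial correlation Rg series always
    carry.  Candidates advance on a grid of ``window_frac`` of the series
    length.  Raises :class:`NotEquilibratedError` when the earliest
    acceptable index lies beyond a quarter of the series — a drifting,
    non-plateauing signal.
    """
    rg = np.atleast_2d(np.asarray(rg_series, dtype=float).T).T  # (T, M)
    t_len = rg.shape[0]
    if t_len < 4:
        raise ValueError("series too short")
    w = max(1, int(round(window_frac * t_len)))
    half = rg[t_len // 2 :]
    mu_f = half.mean(axis=0)
    n_batch = min(8, max(2, half.shape[0] // 2))
    bm = np.array([b.mean(axis=0) for b in np.array_split(half, n_batch, axis=0)])
    # effective sd including autocorrelation, from the batch-mean spread
    sd_eff = bm.std(axis=0, ddof=1) * np.sqrt(half.shape[0] / n_batch)
    for t in range(0, t_len - w + 1, w):
        tail = rg[t:]
        se = sd_eff / np.sqrt(tail.shape[0])
        if np.all(np.abs(tail.mean(axis=0) - mu_f) <= se + 1e-12):
            if t > t_len // 4:
                raise NotEquilibratedError(
                    f"plateau starts only at index {t} of {t_len}: series not equilibrated"
                )
            return t
    raise NotEquilibratedError("no Rg plateau found: series not equilibrated")


def unwrap_molecules(state: SystemState) -> list[np.ndarray]:
    """Contiguous (unwrapped) coordinates of every ring, validated.

    Reconstructs ``wrapped + image_flags * L`` and checks that every bond
    is shorter than 2 sigma — longer bonds mean corrupted image flags.
    """
    wrapped, flags = state.wrapped_positions()
    pos = wrapped + flags * (state.box_length if np.isfinite(state.box_length) else 0.0)
    out = []
    start = 0
    for r in state.rings:
        n = r.n_beads
        p = pos[start : start + n]
        bonds = np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)
        if np.any(bonds >= 2.0):
            raise ValueError(
                f"ring {r.ring_id}: bond of {bonds.max():.2f} sigma after unwrap "
                "— corrupted image flags"
            )
        out.append(p)
        start += n
    return out


# ---------------------------------------------------------------------------
# extended-XYZ trajectory I/O

def write_trajectory(traj: Trajectory, path) -> None:
    """Extended-XYZ dialect: wrapped coordinates, image flags, twist angles.

    Comment line per frame: Lattice, step, n_ring, m_rings; frame 0 also
    carries the JSON metadata.  The round trip is lossless (%.17g).
    """
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            pos = traj.positions[f]
            box = traj.box[f]
            if np.isfinite(box):
                flags = np.floor(pos / box).astype(np.int64)
                wrapped = pos - flags * box
                lat = f'Lattice="{box:.17g} 0 0 0 {box:.17g} 0 0 0 {box:.17g}" '
            else:
                flags = np.zeros(pos.shape, dtype=np.int64)
                wrapped = pos
                lat = ""
            comment = (
                f"{lat}Properties=species:S:1:pos:R:3:ring:I:1:image:I:3:phi:R:1 "
                f"step={int(traj.steps[f])} n_ring={traj.n_ring} m_rings={traj.m_rings}"
            )
            if f == 0 and traj.metadata:
                comment += " metadata=" + json.dumps(traj.metadata, sort_keys=True).replace(" ", "")
            fh.write(f"{pos.shape[0]}\n{comment}\n")
            for b in range(pos.shape[0]):
                ring = b // traj.n_ring
                fh.write(
                    "C %.17g %.17g %.17g %d %d %d %d %.17g\n"
                    % (
                        wrapped[b, 0], wrapped[b, 1], wrapped[b, 2],
                        ring, flags[b, 0], flags[b, 1], flags[b, 2],
                        traj.phi[f, b],
                    )
                )


def read_trajectory(path) -> Trajectory:
    """Parse the extended-XYZ dialect written by :func:`write_trajectory`."""
    frames_pos, frames_phi, boxes, steps = [], [], [], []
    n_ring = m_rings = None
    metadata: dict = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i])
        except ValueError as exc:
            raise ValueError(f"frame {frame_no}: malformed atom count") from exc
        if i + 1 >= len(lines) or i + 1 + nat > len(lines):
            raise ValueError(f"frame {frame_no}: truncated file")
        comment = lines[i + 1]
        box = np.inf
        if 'Lattice="' in comment:
            lat = comment.split('Lattice="', 1)[1].split('"', 1)[0].split()
            box = float(lat[0])
        fields = dict(
            tok.split("=", 1) for tok in comment.split() if "=" in tok and not tok.startswith("Lattice")
        )
        step_no = int(fields.get("step", frame_no))
        n_ring = int(fields.get("n_ring", nat))
        m_rings = int(fields.get("m_rings", 1))
        if "metadata" in fields:
            metadata = json.loads(fields["metadata"])
        pos = np.empty((nat, 3))
        phi = np.empty(nat)
        for b in range(nat):
            parts = lines[i + 2 + b].split()
            if len(parts) != 9:
                raise ValueError(f"frame {frame_no}: malformed atom line {b}")
            x, y, z = (float(v) for v in parts[1:4])
            ix, iy, iz = (int(v) for v in parts[5:8])
            if np.isfinite(box):
                pos[b] = np.array([x, y, z]) + np.array([ix, iy, iz]) * box
            else:
                pos[b] = (x, y, z)
            phi[b] = float(parts[8])
        frames_pos.append(pos)
        frames_phi.append(phi)
        boxes.append(box)
        steps.append(step_no)
        i += 2 + nat
        frame_no += 1
    if not frames_pos:
        return Trajectory(
            positions=np.empty((0, 0, 3)), phi=np.empty((0, 0)), box=np.empty(0),
            steps=np.empty(0, dtype=int), n_ring=0, m_rings=0, metadata=metadata,
        )
    return Trajectory(
        positions=np.array(frames_pos),
        phi=np.array(frames_phi),
        box=np.array(boxes),
        steps=np.array(steps),
        n_ring=n_ring,
        m_rings=m_rings,
        metadata=metadata,
    )
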