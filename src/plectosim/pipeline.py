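"""Config-driven orchestration of the simulation-and-analysis grid.

A *condition* is one cell of the study grid (supercoiling level x volume
occupancy).  ``run_condition`` builds the system, reaches the target
occupancy by box compression, equilibrates (monitoring per-molecule radii
of gyration, with the run required to exceed eight times the detected
equilibration time), samples with the Metropolis sampler (or BD), and
writes per-frame per-molecule metric tables plus frequency-density
profiles as CSV.  Every artifact is stamped with the config hash and
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bd_engine import (
    NotEquilibratedError,
    RunProtocol,
    Trajectory,
    compress_box,
    config_hash,
    detect_equilibration,
    init_system,
    radius_of_gyration,
    run_bd,
    write_trajectory,
)
from .contacts import EPSpec
from .mc_sampler import sample_system
from .model_core import ForceField, RingTopologySpec
from .shape import frequency_density, shape_record
from .thickness import ThicknessParams, ring_thickness
from .topology import writhe

__all__ = ["Condition", "run_condition", "expand_grid", "analyze_frames", "report"]


@dataclass(frozen=True)
class Condition:
    """One cell of the study grid, with desk-scale sampling defaults.

    The full-scale profile of the study (20 molecules of 334 beads,
    occupancies up to 20%, millions of sampled configurations) is
    expressed by the same dataclass with larger numbers; the defaults
    here are sized for a single CPU.
    """

    name: str = "dilute-nicked"
    n_beads: int = 334
    m_rings: int = 2
    delta_lk: float = 0.0
    phi: float = 0.0
    nicked: bool = True          # torsionally relaxed (no twist coupling)
    n_sweeps: int = 2000
    equil_sweeps: int = 500
    sample_every: int = 10
    seed: int = 0
    engine: str = "mc"           # "mc" or "bd"
    analyses: tuple = ("shape", "topology")
    thickness_stride: int = 8
    ep: bool = False

    def topology_spec(self) -> RingTopologySpec:
        n_bp = self.n_beads * (3000.0 / 334.0)
        return RingTopologySpec(
            n_beads=self.n_beads, delta_lk=self.delta_lk, n_bp=n_bp
        )


def expand_grid(
    delta_lks=(0.0, -7.0, -14.0), phis=(0.0, 0.05, 0.10, 0.20), **overrides
) -> list[Condition]:
    """The study grid: supercoiling levels x volume occupancies."""
    conds = []
    for dlk in delta_lks:
        for phi in phis:
            conds.append(
                Condition(
                    name=f"dlk{int(dlk)}_phi{int(round(phi * 100))}",
                    delta_lk=dlk,
                    nicked=(dlk == 0.0),
                    phi=phi,
                    **overrides,
                )
            )
    return conds


def prepare_crowded_state(
    cond: Condition,
    ff: ForceField,
    rate: float = 0.005,
    relax_sweeps: int = 12,
    pre_sweeps: int = 400,
):
    """Crumple, place and compress molecules to the target occupancy.

    Each ring is first equilibrated in isolation (planar circles are far
    from the dilute coil and would collide with their periodic images
    under compression), the coils are placed on a cubic lattice with
    clearance, and the box is then shrunk a fraction ``rate`` per
    interval with Metropolis relaxation in between — the slow-reduction
    protocol that produces self-crowding without strand passage.
    """
    from .mc_sampler import sample_ring

    spec = cond.topology_spec()
    dlk = None if cond.nicked else cond.delta_lk
    rng = np.random.default_rng(cond.seed)
    state = init_system(spec, cond.m_rings, phi=0.0, seed=cond.seed)
    extent = 0.0
    for m, ring in enumerate(state.rings):
        center = ring.positions.mean(axis=0)
        ring.positions -= center
        sample_ring(
            ring, ff, n_sweeps=pre_sweeps, sample_every=0,
            seed=int(rng.integers(2**31)), delta_lk=dlk,
        )
        ring.positions -= ring.positions.mean(axis=0)
        extent = max(extent, float(np.ptp(ring.positions, axis=0).max()))
    per_side = int(np.ceil(cond.m_rings ** (1.0 / 3.0)))
    spacing = extent + 2.0
    sites = [
        (ix, iy, iz)
        for ix in range(per_side)
        for iy in range(per_side)
        for iz in range(per_side)
    ][: cond.m_rings]
    for ring, site in zip(state.rings, sites):
        ring.positions += (np.array(site, dtype=float) + 0.5) * spacing
    state.box_length = per_side * spacing
    if cond.phi > 0:
        compress_box(
            state, cond.phi, ff, rate=rate, relax_sweeps=relax_sweeps,
            seed=cond.seed + 1, delta_lk=dlk,
        )
    return state


def analyze_frames(
    frames,
    cond: Condition,
    analyses=None,
    box: float = -1.0,
) -> pd.DataFrame:
    """Per-frame, per-molecule metric records from unwrapped ring sets."""
    analyses = analyses if analyses is not None else cond.analyses
    spec = cond.topology_spec()
    ep = EPSpec(0, cond.n_beads // 2) if cond.ep else None
    rows = []
    for f, conf_set in enumerate(frames):
        for rid, pos in enumerate(conf_set):
            row = {"frame": f, "ring_id": rid, "rg": radius_of_gyration(pos)}
            if "shape" in analyses:
                rec = shape_record(pos)
                row.update(
                    a=rec.axes.a, b=rec.axes.b, c=rec.axes.c,
                    asphericity=rec.asphericity, prolateness=rec.prolateness,
                )
            if "topology" in analyses:
                wr = writhe(pos)
                row.update(wr=wr, sigma_wr=wr / spec.lk0)
            if "thickness" in analyses:
                t = ring_thickness(
                    conf_set, rid, ThicknessParams(), bead_stride=cond.thickness_stride
                )
                row.update(thickness_mean=float(t.mean()), thickness_min=float(t.min()))
            if ep is not None:
                d = float(np.linalg.norm(pos[ep.enhancer_bead] - pos[ep.promoter_bead]))
                row.update(ep_distance=d, in_contact=int(d < ep.contact_dist))
            rows.append(row)
    return pd.DataFrame(rows)


def run_condition(cond: Condition, outdir: str | Path | None = None):
    """Simulate -> equilibrate -> sample -> analyze one grid condition.

    Returns (metric table, sampled frames).  With ``outdir`` set, writes
    ``metrics_<name>.csv``, density profiles and an extended-XYZ
    trajectory, all stamped with the config hash.
    """
    ff = ForceField()
    spec = cond.topology_spec()
    chash = config_hash(asdict(cond))
    dlk = None if cond.nicked else cond.delta_lk
    ep_sites = (0, cond.n_beads // 2) if cond.ep else None

    if cond.phi > 0:
        state = prepare_crowded_state(cond, ff)
    else:
        state = init_system(spec, cond.m_rings, phi=0.0, seed=cond.seed)

    if cond.n_sweeps <= 0:
        table = pd.DataFrame(
            columns=["frame", "ring_id", "rg", "asphericity", "prolateness", "wr"]
        )
        frames = []
    elif cond.engine == "bd":
        proto = RunProtocol(
            n_steps=cond.n_sweeps, sample_every=cond.sample_every, seed=cond.seed + 2
        )
        traj = run_bd(state, ff, proto)
        frames = [traj.ring_positions(f) for f in range(traj.n_frames)]
        frames = _equilibrated_tail(frames)
        table = analyze_frames(frames, cond)
    else:
        res = sample_system(
            state, ff,
            n_sweeps=cond.equil_sweeps + cond.n_sweeps,
            sample_every=cond.sample_every,
            seed=cond.seed + 2,
            delta_lk=dlk,
            ep_sites=ep_sites,
            d_max=0.8,
        )
        frames = [res.ring_positions(s) for s in range(res.n_samples)]
        frames = _equilibrated_tail(frames)
        table = analyze_frames(frames, cond)

    table.attrs["config_hash"] = chash
    table.attrs["seed"] = cond.seed
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / f"metrics_{cond.name}.csv"
        with open(path, "w") as fh:
            fh.write(f"# config_hash={chash} seed={cond.seed}\n")
            table.to_csv(fh, index=False)
        for col in ("asphericity", "prolateness", "wr"):
            if col in table.columns and len(table):
                centers, dens = frequency_density(table[col].to_numpy())
                pd.DataFrame({"bin_center": centers, "density": dens}).to_csv(
                    outdir / f"profile_{cond.name}_{col}.csv", index=False
                )
        if frames:
            _write_frames(frames, state.box_length, cond, chash,
                          outdir / f"traj_{cond.name}.xyz")
        with open(outdir / f"config_{cond.name}.json", "w") as fh:
            json.dump({**asdict(cond), "config_hash": chash}, fh, indent=1)
    return table, frames


def _equilibrated_tail(frames):
    """Drop the pre-plateau part of the sampled frames (Rg plateau rule).

    The run must exceed eight times the detected equilibration index,
    otherwise a NotEquilibratedError propagates.
    """
    if len(frames) < 8:
        return frames
    rg = np.array([[radius_of_gyration(p) for p in fs] for fs in frames])
    t_eq = detect_equilibration(rg)
    if len(frames) < 8 * max(t_eq, 1):
        raise NotEquilibratedError(
            f"run of {len(frames)} frames is shorter than 8 x t_eq = {8 * t_eq}"
        )
    return frames[t_eq:]


def _write_frames(frames, box, cond, chash, path):
    pos = np.array([np.concatenate(fs, axis=0) for fs in frames])
    nf = pos.shape[0]
    traj = Trajectory(
        positions=pos,
        phi=np.zeros(pos.shape[:2]),
        box=np.full(nf, box),
        steps=np.arange(nf) * cond.sample_every,
        n_ring=cond.n_beads,
        m_rings=cond.m_rings,
        metadata={"condition": asdict(cond), "config_hash": chash},
    )
    write_trajectory(traj, path)


def report(tables: dict[str, pd.DataFrame] | list) -> pd.DataFrame:
    """Per-condition summary: mean +- SE of the headline observables.

    Accepts {condition_name: metric table}.  Single-frame tables get NaN
    standard errors (flagged, not fabricated).
    """
    if not isinstance(tables, dict):
        tables = {f"condition_{i}": t for i, t in enumerate(tables)}
    if not tables:
        raise ValueError("no metric tables")
    rows = []
    for name, t in tables.items():
        row = {"condition": name, "n_records": len(t)}
        for col in ("asphericity", "prolateness", "wr", "rg",
                    "thickness_mean", "in_contact"):
            if col in t.columns and len(t):
                v = t[col].to_numpy(dtype=float)
                n_frames = t["frame"].nunique() if "frame" in t.columns else len(v)
                row[f"{col}_mean"] = float(np.mean(np.abs(v) if col == "wr" else v))
                row[f"{col}_se"] = (
                    float(np.std(v, ddof=1) / np.sqrt(n_frames))
                    if n_frames > 1
                    else float("nan")
                )
        rows.append(row)
    return pd.DataFrame(rows)
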