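"""Pore geometry and flexibility: pore-radius profiles, RMSF, cavity
water counts and RMSD monitoring.

The pore-radius profiler re-implements the classic largest-inscribed-
sphere construction: at each z along the pore axis, find the sphere
centre (x, y free, z fixed) maximising

    r(c) = min over atoms ( |c - atom| - vdW )

by a seeded simulated-annealing random walk in the xy plane, warm-started
from the previous z's centre. Trajectory profiles aggregate per-snapshot
profiles to mean ± SD, the presentation used for ensembles of simulation
snapshots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    AlignmentError,
    ContractError,
    FrameSeries,
    PoreflowError,
    SelectionSpec,
    Structure,
    kabsch,
)


class SeedPointError(PoreflowError):
    """The profiler's starting point lies inside an atom."""


@dataclass
class ProbeParams:
    """Simulated-annealing settings for the sphere maximisation."""

    mc_steps: int = 500
    step_size: float = 0.1   # Å, initial xy step
    seed: int = 0
    cooling: float = 0.99    # geometric step-size decay per move
    z_step: float = 0.25     # Å (used when callers build a default z grid)


@dataclass
class PoreRadiusProfile:
    z_grid: np.ndarray
    radius_mean: np.ndarray
    radius_sd: np.ndarray | None = None
    per_structure_radii: np.ndarray | None = None  # (n_snapshots, n_z)


@dataclass
class RMSFProfile:
    ids: np.ndarray            # atom or residue ids
    rmsf: np.ndarray           # nm
    sd: np.ndarray | None = None  # nm, across replicas
    per_residue: bool = False


@dataclass
class CavityRegion:
    """Axial slice of the pore between the gate plane and the SF bottom."""

    z_range: tuple[float, float]
    radius: float = 8.0

    def __post_init__(self):
        if self.z_range[1] <= self.z_range[0]:
            raise ContractError("cavity z_range must be non-empty")
        if self.radius <= 0:
            raise ContractError("cavity radius must be positive")


# ---------------------------------------------------------------------------
# Pore radius
# ---------------------------------------------------------------------------


def _max_sphere_radius(
    xy0: np.ndarray,
    z: float,
    coords: np.ndarray,
    vdw: np.ndarray,
    probe: ProbeParams,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """Annealed random search for the largest sphere centred at height z."""

    def f(xy):
        d = np.sqrt(
            (coords[:, 0] - xy[0]) ** 2
            + (coords[:, 1] - xy[1]) ** 2
            + (coords[:, 2] - z) ** 2
        )
        return float(np.min(d - vdw))

    best = np.asarray(xy0, float).copy()
    best_r = f(best)
    start_r = best_r
    step = probe.step_size
    cur, cur_r = best.copy(), best_r
    for _ in range(probe.mc_steps):
        cand = cur + rng.standard_normal(2) * step
        r = f(cand)
        if r > cur_r:
            cur, cur_r = cand, r
            if r > best_r:
                best, best_r = cand, r
        step *= probe.cooling
    return best_r, best, start_r


def pore_radius_profile(
    structure: Structure,
    z_grid: np.ndarray,
    probe: ProbeParams | None = None,
    positions: np.ndarray | None = None,
) -> PoreRadiusProfile:
    """Largest-inscribed-sphere radius at each z of a single structure.

    The walk starts on the axis at the first grid point and warm-starts
    each subsequent z from the previous optimum. Radii are clamped at 0.
    Raises :class:`SeedPointError` when the starting point is inside an
    atom (negative clearance with no recovery within the first moves).
    """
    probe = probe or ProbeParams()
    coords = structure.positions if positions is None else positions
    vdw = structure.atoms["vdw_radius"].to_numpy()
    z_grid = np.asarray(z_grid, float)
    rng = np.random.default_rng(probe.seed)
    radii = np.empty(len(z_grid))
    center = np.zeros(2)
    for k, z in enumerate(z_grid):
        r, center, start_r = _max_sphere_radius(center, z, coords, vdw, probe,
                                                rng)
        if k == 0 and start_r <= 0:
            raise SeedPointError(
                f"profile start point (0, 0, {z:.2f}) lies inside an atom "
                f"(clearance {start_r:.2f} Å)"
            )
        radii[k] = max(r, 0.0)
    return PoreRadiusProfile(z_grid=z_grid, radius_mean=radii)


def trajectory_pore_profile(
    frames: FrameSeries,
    z_grid: np.ndarray,
    probe: ProbeParams | None = None,
    stride: int = 1,
    selection: SelectionSpec | None = None,
) -> PoreRadiusProfile:
    """Per-snapshot pore profiles aggregated to mean ± SD per z."""
    probe = probe or ProbeParams()
    if stride < 1:
        raise ContractError("stride must be >= 1")
    idx = (
        selection.resolve(frames.structure)
        if selection is not None
        else np.arange(frames.n_atoms)
    )
    sub = Structure(
        atoms=frames.structure.atoms.iloc[idx].reset_index(drop=True),
        positions=frames.positions[0, idx],
    )
    per = []
    for f in range(0, frames.n_frames, stride):
        try:
            p = pore_radius_profile(
                sub, z_grid, probe, positions=frames.positions[f, idx]
            )
        except SeedPointError as exc:
            raise SeedPointError(f"frame {f}: {exc}") from exc
        per.append(p.radius_mean)
    per = np.vstack(per)
    return PoreRadiusProfile(
        z_grid=np.asarray(z_grid, float),
        radius_mean=per.mean(axis=0),
        radius_sd=per.std(axis=0, ddof=1) if len(per) > 1 else np.zeros(per.shape[1]),
        per_structure_radii=per,
    )


# ---------------------------------------------------------------------------
# RMSF / RMSD
# ---------------------------------------------------------------------------


def rmsf_profile(
    frames: FrameSeries | list[FrameSeries],
    sel: SelectionSpec,
    per_residue: bool = False,
) -> RMSFProfile:
    """Per-atom RMSF sqrt(<|x - <x>|^2>) over frames, in nm.

    Frames are assumed already superposed on the pore-domain backbone
    (the alignment stage); no additional fitting is applied here. With a
    list of replicas the per-replica RMSF values are averaged and their
    SD (n-1) reported. ``per_residue`` averages atom RMSF within residues.
    """
    replicas = frames if isinstance(frames, list) else [frames]
    rep_vals = []
    ids = None
    for rep in replicas:
        if rep.n_frames < 2:
            raise ContractError("RMSF is undefined for a single frame")
        idx = sel.resolve(rep.structure)
        if len(idx) == 0:
            raise ContractError(f"selection {sel.expression!r} is empty")
        x = rep.positions[:, idx, :]
        mean = x.mean(axis=0)
        rmsf_a = np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0)) / 10.0
        atoms = rep.structure.atoms.iloc[idx]
        if per_residue:
            resids = atoms["residue_id"].to_numpy()
            uniq = np.unique(resids)
            vals = np.array([rmsf_a[resids == r].mean() for r in uniq])
            cur_ids = uniq
        else:
            vals = rmsf_a
            cur_ids = atoms["atom_id"].to_numpy()
        if ids is None:
            ids = cur_ids
        rep_vals.append(vals)
    arr = np.vstack(rep_vals)
    return RMSFProfile(
        ids=ids,
        rmsf=arr.mean(axis=0),
        sd=arr.std(axis=0, ddof=1) if len(replicas) > 1 else None,
        per_residue=per_residue,
    )


def rmsd_series(
    frames: FrameSeries,
    sel: SelectionSpec,
    reference_frame: int = 0,
    superpose: bool = True,
) -> np.ndarray:
    """RMSD per frame vs. the reference, in nm.

    ``superpose`` (default) applies the least-squares rigid fit before
    measuring, the convention for conformational-drift monitoring;
    ``superpose=False`` measures raw coordinate deviations.
    """
    idx = sel.resolve(frames.structure)
    if len(idx) == 0:
        raise ContractError(f"selection {sel.expression!r} is empty")
    ref = frames.positions[reference_frame, idx]
    out = np.empty(frames.n_frames)
    for f in range(frames.n_frames):
        P = frames.positions[f, idx]
        if superpose:
            R, t = kabsch(P, ref)
            P = P @ R.T + t
        out[f] = np.sqrt(np.mean(np.sum((P - ref) ** 2, axis=1))) / 10.0
    return out


# ---------------------------------------------------------------------------
# Cavity water
# ---------------------------------------------------------------------------


def cavity_water_count(
    frames: FrameSeries,
    water_sel: SelectionSpec,
    region: CavityRegion,
) -> tuple[np.ndarray, float, float]:
    """Water oxygens inside the cavity cylinder, per frame.

    Returns (per-frame counts, mean, SD). Counts waters with z in the
    region's range and lateral distance from the axis <= its radius.
    """
    if frames.alignment is None:
        raise AlignmentError("cavity count requires aligned frames")
    idx = water_sel.resolve(frames.structure)
    if len(idx) == 0:
        raise ContractError(f"water selection {water_sel.expression!r} is empty")
    z_lo, z_hi = region.z_range
    box_z = frames.box[:, 2]
    if np.all((z_lo > box_z / 2) | (z_hi < -box_z / 2)):
        warnings.warn("cavity region lies entirely outside the box; counts are 0")
    pos = frames.positions[:, idx, :]
    in_z = (pos[:, :, 2] >= z_lo) & (pos[:, :, 2] <= z_hi)
    in_r = pos[:, :, 0] ** 2 + pos[:, :, 1] ** 2 <= region.radius**2
    counts = np.sum(in_z & in_r, axis=1).astype(float)
    sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return counts, float(counts.mean()), sd
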