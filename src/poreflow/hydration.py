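"""First-hydration-shell census of permeating ions.

Counts the oxygens coordinating a cation — water oxygens versus protein
backbone-carbonyl oxygens — within a fixed first-shell radius (3.4 Å for
K+, 3.1 Å for Na+, the minima of the respective radius-of-gyration
profiles), using minimum-image distances under the frame's orthorhombic
box. Profiled along the pore axis this shows where ions shed their
hydration water in exchange for carbonyl coordination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AlignmentError,
    ContractError,
    FrameSeries,
    SelectionSpec,
    Structure,
)

#: first-shell radii, Å (radius-of-gyration-profile minima)
SHELL_RADIUS_K = 3.4
SHELL_RADIUS_NA = 3.1


@dataclass
class HydrationParams:
    """Census configuration.

    By default the carbonyl selection covers backbone O atoms of protein
    residues; restrict it to the SF residues with e.g.
    ``name O and resid 360:365`` for filter-scoped profiles.
    """

    shell_radius: float = SHELL_RADIUS_K
    water_oxygen_sel: SelectionSpec = field(
        default_factory=lambda: SelectionSpec("name OW")
    )
    carbonyl_oxygen_sel: SelectionSpec = field(
        default_factory=lambda: SelectionSpec("name O and protein")
    )
    z_edges: np.ndarray = field(
        default_factory=lambda: np.arange(-20.0, 20.5, 1.0)
    )

    def __post_init__(self):
        if self.shell_radius <= 0:
            raise ContractError("shell_radius must be positive")
        self.z_edges = np.asarray(self.z_edges, float)


@dataclass
class HydrationProfile:
    z_centers: np.ndarray
    mean_water: np.ndarray
    mean_carbonyl: np.ndarray
    sd_water: np.ndarray | None
    sd_carbonyl: np.ndarray | None
    n_observations: np.ndarray
    mask: np.ndarray  # True where too few observations

    @property
    def mean_total(self) -> np.ndarray:
        return self.mean_water + self.mean_carbonyl


def _min_image_dist2(points: np.ndarray, center: np.ndarray,
                     box: np.ndarray) -> np.ndarray:
    d = points - center
    d -= box * np.round(d / box)
    return np.einsum("ij,ij->i", d, d)


def first_shell_census(
    structure_or_frame,
    ion_position: np.ndarray,
    params: HydrationParams,
    box: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> tuple[int, int]:
    """Count (water, carbonyl) oxygens within the first shell of one ion.

    Accepts a :class:`Structure` (uses its own coordinates and box) or any
    structure plus explicit per-frame ``positions`` and ``box``. Distances
    are minimum-image; ties at exactly the shell radius count as inside.
    """
    structure: Structure = structure_or_frame
    pos = structure.positions if positions is None else positions
    b = structure.box if box is None else box
    if b is None:
        raise ContractError("census needs a box for minimum-image distances")
    b = np.asarray(b, float)
    ion = np.asarray(ion_position, float)
    r2 = params.shell_radius**2 * (1 + 1e-12)  # ties count as inside

    iw = params.water_oxygen_sel.resolve(structure)
    ic = params.carbonyl_oxygen_sel.resolve(structure)
    n_w = int(np.sum(_min_image_dist2(pos[iw], ion, b) <= r2)) if len(iw) else 0
    n_c = int(np.sum(_min_image_dist2(pos[ic], ion, b) <= r2)) if len(ic) else 0
    return n_w, n_c


def hydration_profile(
    frames: FrameSeries | list[FrameSeries],
    ion_sel: SelectionSpec,
    params: HydrationParams,
    min_observations: int = 50,
) -> HydrationProfile:
    """Per-z-bin mean first-shell composition of the selected ions.

    The census is evaluated for every selected ion in every frame and
    accumulated into z bins by the ion's axial position. With a list of
    replicas, per-replica means are averaged bin-wise and the SD (n-1)
    across replicas is reported. Bins with fewer than ``min_observations``
    ion visits (per replica) are masked.
    """
    replicas = frames if isinstance(frames, list) else [frames]
    edges = params.z_edges
    nb = len(edges) - 1
    rep_w, rep_c, rep_n = [], [], []
    for rep in replicas:
        if rep.alignment is None:
            raise AlignmentError("hydration profile requires aligned frames")
        idx = ion_sel.resolve(rep.structure)
        if len(idx) == 0:
            raise ContractError(f"ion selection {ion_sel.expression!r} is empty")
        iw = params.water_oxygen_sel.resolve(rep.structure)
        ic = params.carbonyl_oxygen_sel.resolve(rep.structure)
        sum_w = np.zeros(nb)
        sum_c = np.zeros(nb)
        n_obs = np.zeros(nb)
        r2 = params.shell_radius**2 * (1 + 1e-12)
        for f in range(rep.n_frames):
            pos = rep.positions[f]
            b = rep.box[f]
            for i in idx:
                zbin = np.searchsorted(edges, pos[i, 2], side="right") - 1
                if zbin < 0 or zbin >= nb:
                    continue
                nw = int(np.sum(_min_image_dist2(pos[iw], pos[i], b) <= r2)) \
                    if len(iw) else 0
                nc = int(np.sum(_min_image_dist2(pos[ic], pos[i], b) <= r2)) \
                    if len(ic) else 0
                sum_w[zbin] += nw
                sum_c[zbin] += nc
                n_obs[zbin] += 1
        rep_n.append(n_obs)
        with np.errstate(invalid="ignore", divide="ignore"):
            rep_w.append(np.where(n_obs > 0, sum_w / np.maximum(n_obs, 1), np.nan))
            rep_c.append(np.where(n_obs > 0, sum_c / np.maximum(n_obs, 1), np.nan))

    w = np.vstack(rep_w)
    c = np.vstack(rep_c)
    n = np.vstack(rep_n)
    mask = np.all(n < min_observations, axis=0)
    if np.all(mask):
        warnings.warn("no z bin reached the minimum observation count; "
                      "profile fully masked")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_w = np.nanmean(w, axis=0)
        mean_c = np.nanmean(c, axis=0)
        sd_w = np.nanstd(w, axis=0, ddof=1) if len(replicas) > 1 else None
        sd_c = np.nanstd(c, axis=0, ddof=1) if len(replicas) > 1 else None
    mean_w = np.where(mask, np.nan, mean_w)
    mean_c = np.where(mask, np.nan, mean_c)
    return HydrationProfile(
        z_centers=(edges[:-1] + edges[1:]) / 2,
        mean_water=mean_w,
        mean_carbonyl=mean_c,
        sd_water=sd_w,
        sd_carbonyl=sd_c,
        n_observations=n.sum(axis=0),
        mask=mask,
    )


def bulk_coordination_number(
    structures: list[Structure],
    params: HydrationParams | None = None,
) -> float:
    """Mean total first-shell oxygen count over independent bulk snapshots.

    Each structure must contain one cation (resname K or NA) whose
    position anchors the census; in bulk water this is the ion's
    coordination number.
    """
    params = params or HydrationParams()
    ion_sel = SelectionSpec("resname K or resname NA")
    totals = []
    for s in structures:
        ion_idx = ion_sel.resolve(s)
        if len(ion_idx) != 1:
            raise ContractError("each snapshot must contain exactly one cation")
        nw, nc = first_shell_census(s, s.positions[ion_idx[0]], params)
        totals.append(nw + nc)
    return float(np.mean(totals))
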