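"""Ion occupancy histograms and Boltzmann-inversion free-energy profiles.

Steady-state ion density along the pore axis, referenced to the bulk
concentration, Boltzmann-inverts into a free-energy profile

    dG(z) = -RT ln( C(z) / C_bulk )        [kcal/mol]

so that enriched binding sites appear as negative dG. Occupancy can be
binned in 1D (z, laterally integrated within r_max) or 2D (z, r) with
cylindrical-shell volume normalisation; zero-count bins are capped at a
finite value and flagged rather than left infinite. Replicate runs are
averaged on the dG profiles (not pooled counts), with an SD per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    R_KCAL,
    AlignmentError,
    ContractError,
    FrameSeries,
    PoreflowError,
    SelectionSpec,
)


class DegenerateProfileError(PoreflowError):
    """Profile lacks the structure (two minima) a barrier measurement needs."""


@dataclass
class OccupancyGrid:
    """Binned ion counts accumulated over frames.

    ``counts`` has shape (n_z,) for 1D grids or (n_z, n_r) for 2D grids;
    2D bin volumes are cylindrical shells pi (r_out^2 - r_in^2) dz.
    ``normalized_density`` is in ions per 0.001 Å^3 per frame interval
    (the frame cadence is recorded as ``frame_stride_time``).
    """

    z_edges: np.ndarray
    counts: np.ndarray
    n_frames: int
    r_edges: np.ndarray | None = None
    r_max: float | None = None
    frame_stride_time: float = 50.0  # ps

    def __post_init__(self):
        self.z_edges = np.asarray(self.z_edges, float)
        self.counts = np.asarray(self.counts, float)
        if np.any(self.counts < 0):
            raise ContractError("counts must be non-negative")

    @property
    def z_centers(self) -> np.ndarray:
        return (self.z_edges[:-1] + self.z_edges[1:]) / 2

    @property
    def bin_volumes(self) -> np.ndarray:
        """Å^3 per bin; (n_z,) in 1D, (n_z, n_r) in 2D."""
        dz = np.diff(self.z_edges)
        if self.r_edges is None:
            area = np.pi * (self.r_max**2 if self.r_max else 1.0)
            return dz * area
        shell = np.pi * (self.r_edges[1:] ** 2 - self.r_edges[:-1] ** 2)
        return dz[:, None] * shell[None, :]

    @property
    def normalized_density(self) -> np.ndarray:
        """Ions per 0.001 Å^3 per frame interval."""
        return self.counts / self.n_frames / (self.bin_volumes / 0.001)

    def integrate_radially(self) -> "OccupancyGrid":
        """Collapse a 2D (z, r) grid to the volume-weighted 1D profile."""
        if self.r_edges is None:
            return self
        return OccupancyGrid(
            z_edges=self.z_edges,
            counts=self.counts.sum(axis=1),
            n_frames=self.n_frames,
            r_max=float(self.r_edges[-1]),
            frame_stride_time=self.frame_stride_time,
        )


@dataclass
class EnergeticsParams:
    """Thermodynamic context for the Boltzmann inversion.

    ``bulk_slab`` lists (z_lo, z_hi) ranges defining the bulk reference
    concentration C_out; it must be disjoint from the pore region.
    R = 8.314 J/(mol K); temperature defaults to 300 K (303.15 K is the
    other protocol temperature in use).
    """

    temperature: float = 300.0
    bulk_slab: list = field(default_factory=lambda: [(-20.0, -15.0), (15.0, 20.0)])
    zero_count_cap: float = 8.0  # kcal/mol

    def __post_init__(self):
        if self.temperature <= 0:
            raise ContractError("temperature must be positive")

    @property
    def rt_kcal(self) -> float:
        return R_KCAL * self.temperature


@dataclass
class FreeEnergyProfile:
    z_centers: np.ndarray
    delta_g: np.ndarray          # kcal/mol
    sd: np.ndarray | None        # kcal/mol across replicas
    capped_mask: np.ndarray      # True where counts were zero (capped)
    rt_kcal: float


def occupancy_histogram(
    frames: FrameSeries,
    ion_sel: SelectionSpec,
    z_edges: np.ndarray,
    r_edges: np.ndarray | None = None,
    r_max: float = 10.0,
) -> OccupancyGrid:
    """Accumulate selected-ion positions into z (or z, r) bins over frames.

    Frames must be pore-aligned. In 1D mode, only ions within the lateral
    ``r_max`` cylinder are counted, and the bin volume is pi r_max^2 dz.
    """
    if frames.alignment is None:
        raise AlignmentError("occupancy requires pore-aligned frames")
    idx = ion_sel.resolve(frames.structure)
    if len(idx) == 0:
        raise ContractError(f"ion selection {ion_sel.expression!r} is empty")
    z_edges = np.asarray(z_edges, float)
    z = frames.positions[:, idx, 2].ravel()
    r = np.sqrt(
        frames.positions[:, idx, 0] ** 2 + frames.positions[:, idx, 1] ** 2
    ).ravel()
    stride = (
        float(np.median(np.diff(frames.times))) if frames.n_frames > 1 else 50.0
    )
    if r_edges is None:
        sel = r <= r_max
        counts, _ = np.histogram(z[sel], bins=z_edges)
        return OccupancyGrid(
            z_edges=z_edges, counts=counts.astype(float),
            n_frames=frames.n_frames, r_max=r_max, frame_stride_time=stride,
        )
    r_edges = np.asarray(r_edges, float)
    counts, _, _ = np.histogram2d(z, r, bins=[z_edges, r_edges])
    return OccupancyGrid(
        z_edges=z_edges, counts=counts, n_frames=frames.n_frames,
        r_edges=r_edges, frame_stride_time=stride,
    )


def _profile_from_grid(grid: OccupancyGrid, params: EnergeticsParams):
    g1 = grid.integrate_radially()
    centers = g1.z_centers
    vol = g1.bin_volumes
    density = g1.counts / vol  # per-frame factor cancels in the ratio

    in_bulk = np.zeros(len(centers), dtype=bool)
    for lo, hi in params.bulk_slab:
        in_bulk |= (centers >= lo) & (centers <= hi)
    if not np.any(in_bulk):
        raise ContractError("bulk slab contains no bins")
    bulk_counts = g1.counts[in_bulk].sum()
    if bulk_counts < 100:
        raise ContractError(
            f"bulk slab holds only {bulk_counts:.0f} counts (need >= 100) — "
            "reference concentration is unreliable"
        )
    c_bulk = bulk_counts / vol[in_bulk].sum()
    rt = params.rt_kcal
    with np.errstate(divide="ignore"):
        dg = -rt * np.log(density / c_bulk)
    capped = g1.counts == 0
    dg[capped] = params.zero_count_cap
    return centers, dg, capped


def free_energy_profile(
    grids: OccupancyGrid | list[OccupancyGrid],
    params: EnergeticsParams,
) -> FreeEnergyProfile:
    """Boltzmann-invert occupancy into dG(z) = -RT ln(C/C_bulk).

    A list of grids is treated as independent replicas: profiles are
    computed per replica and averaged bin-wise with an SD (n-1). Bins with
    zero counts in a replica are set to ``zero_count_cap`` and flagged.
    """
    if isinstance(grids, OccupancyGrid):
        grids = [grids]
    if not grids:
        raise ContractError("no occupancy grids given")
    profiles, caps = [], []
    centers = None
    for g in grids:
        c, dg, capped = _profile_from_grid(g, params)
        if centers is None:
            centers = c
        elif not np.allclose(centers, c):
            raise ContractError("replica grids have mismatched z bins")
        profiles.append(dg)
        caps.append(capped)
    profs = np.vstack(profiles)
    mean = profs.mean(axis=0)
    sd = profs.std(axis=0, ddof=1) if len(grids) > 1 else None
    return FreeEnergyProfile(
        z_centers=centers,
        delta_g=mean,
        sd=sd,
        capped_mask=np.any(np.vstack(caps), axis=0),
        rt_kcal=params.rt_kcal,
    )


def barrier_height(profile: FreeEnergyProfile,
                   z_window: tuple[float, float]) -> float:
    """Barrier between the two deepest minima inside ``z_window``.

    The binned profile is smoothed with a 3-bin moving average, local
    minima are located on the smoothed curve, and the height returned is
    max(profile between the two deepest minima) minus the shallower of
    the two. Raises :class:`DegenerateProfileError` for profiles with
    fewer than two minima (e.g. monotone profiles).
    """
    lo, hi = z_window
    sel = (profile.z_centers >= lo) & (profile.z_centers <= hi)
    z = profile.z_centers[sel]
    g = profile.delta_g[sel]
    if len(g) < 5:
        raise DegenerateProfileError("window contains too few bins")
    sm = np.convolve(g, np.ones(3) / 3, mode="same")
    sm[0], sm[-1] = g[0], g[-1]  # do not let edge padding invent minima
    interior = np.arange(1, len(sm) - 1)
    is_min = (sm[interior] <= sm[interior - 1]) & (sm[interior] <= sm[interior + 1])
    # collapse flat runs to a single representative
    minima = []
    for i in interior[is_min]:
        if minima and i - minima[-1] == 1 and np.isclose(sm[i], sm[minima[-1]]):
            continue
        minima.append(i)
    if len(minima) < 2:
        raise DegenerateProfileError(
            f"found {len(minima)} local minima in window {z_window}; need >= 2"
        )
    minima = sorted(minima, key=lambda i: sm[i])[:2]
    i0, i1 = sorted(minima)
    peak = float(np.max(sm[i0 : i1 + 1]))
    shallower = float(max(sm[i0], sm[i1]))
    return peak - shallower
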