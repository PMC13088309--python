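"""Synthetic generators with known ground truth.

Every downstream analysis stage is testable offline because this module
produces inputs with the statistical structure those analyses assume:

* a Brownian (overdamped Langevin) model-pore ion simulator with an
  imposed potential of mean force U(z), an optional uniform applied field,
  and periodic boundaries along z — the known-PMF / known-flux oracle for
  the permeation and energetics stages;
* constructed solvation fixtures (exact shell contents) and an
  RDF-structured bulk solvation sampler for the hydration census;
* ring-of-atoms cylinder / hourglass pores for the pore-radius profiler;
* a continuous-time two-state (closed/open) channel-gating simulator with
  Gaussian recording noise for the amplitude-histogram stage.

All generators take an integer seed and use numpy's PCG64 generator;
fixed seed means bit-identical output. Generated trajectories embed their
:class:`GroundTruth` so tests are self-describing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    R_KCAL,
    EV_TO_KCAL,
    ContractError,
    FrameSeries,
    PoreflowError,
    Structure,
    build_structure,
)
from .ephys import CurrentTrace, bessel_lowpass


class StepSizeError(PoreflowError):
    """Langevin integration became unstable; carries the offending step."""

    def __init__(self, message: str, step: int):
        super().__init__(message)
        self.step = step


# ---------------------------------------------------------------------------
# Imposed PMF
# ---------------------------------------------------------------------------


@dataclass
class Pmf:
    """Piecewise-linear U(z) in kcal/mol on z in [-L/2, +L/2], periodic.

    The first and last knot values must agree so the profile is continuous
    across the periodic boundary.
    """

    z_knots: np.ndarray
    u_knots: np.ndarray

    def __post_init__(self):
        self.z_knots = np.asarray(self.z_knots, float)
        self.u_knots = np.asarray(self.u_knots, float)
        if len(self.z_knots) != len(self.u_knots) or len(self.z_knots) < 2:
            raise ContractError("PMF needs matching z/u knot arrays (>= 2 knots)")
        if not np.all(np.diff(self.z_knots) > 0):
            raise ContractError("PMF z knots must be strictly increasing")
        if abs(self.u_knots[0] - self.u_knots[-1]) > 1e-9:
            raise ContractError("PMF must be periodic-continuous: U(-L/2) == U(+L/2)")

    @property
    def length(self) -> float:
        return float(self.z_knots[-1] - self.z_knots[0])

    def u(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, float)
        zw = self.z_knots[0] + np.mod(z - self.z_knots[0], self.length)
        return np.interp(zw, self.z_knots, self.u_knots)

    def force(self, z: np.ndarray) -> np.ndarray:
        """-dU/dz, kcal/mol/Å (piecewise constant)."""
        z = np.asarray(z, float)
        zw = self.z_knots[0] + np.mod(z - self.z_knots[0], self.length)
        seg = np.clip(np.searchsorted(self.z_knots, zw, side="right") - 1, 0,
                      len(self.z_knots) - 2)
        slopes = np.diff(self.u_knots) / np.diff(self.z_knots)
        return -slopes[seg]

    @property
    def is_flat(self) -> bool:
        return float(self.u_knots.max() - self.u_knots.min()) < 1e-12

    @classmethod
    def flat(cls, box_length: float = 40.0) -> "Pmf":
        h = box_length / 2
        return cls(np.array([-h, h]), np.zeros(2))

    @classmethod
    def double_well(
        cls,
        box_length: float = 40.0,
        well_depth: float = 3.0,
        barrier_top: float = 1.0,
        well_z: float = 8.0,
        well_width: float = 2.0,
        barrier_width: float = 2.5,
        n_knots: int = 321,
    ) -> "Pmf":
        """Smooth symmetric double well: Gaussian wells of depth
        ``-well_depth`` at ±well_z separated by a central Gaussian peak at
        ``+barrier_top``, decaying to flat bulk (U = 0) toward the box
        edges. The barrier seen from a well is ``barrier_top + well_depth``.

        The two component amplitudes are solved so the profile takes the
        requested values at the well centres and at z = 0 despite the
        small Gaussian overlap.
        """
        h = box_length / 2
        z = np.linspace(-h, h, n_knots)

        def wells(x):
            return (np.exp(-((x - well_z) ** 2) / (2 * well_width**2))
                    + np.exp(-((x + well_z) ** 2) / (2 * well_width**2)))

        def bar(x):
            return np.exp(-(x**2) / (2 * barrier_width**2))

        # solve -a wells + b bar = (-well_depth at well_z, +barrier_top at 0)
        A = np.array([[-wells(np.array([well_z]))[0], bar(np.array([well_z]))[0]],
                      [-wells(np.array([0.0]))[0], bar(np.array([0.0]))[0]]])
        a, b = np.linalg.solve(A, np.array([-well_depth, barrier_top]))
        u = -a * wells(z) + b * bar(z)
        u -= u[0]  # enforce exact periodic continuity at the (flat) edges
        return cls(z, u)

    @classmethod
    def sinusoid(cls, box_length: float = 40.0, amplitude: float = 1.0,
                 n_knots: int = 81) -> "Pmf":
        h = box_length / 2
        z = np.linspace(-h, h, n_knots)
        return cls(z, amplitude * np.cos(2 * np.pi * (z + h) / box_length) - amplitude)


# ---------------------------------------------------------------------------
# Model pore + ground truth
# ---------------------------------------------------------------------------


@dataclass
class PoreModel:
    """Physical parameters of the model pore.

    Defaults are the package's standard study conditions: a bulk K+
    diffusion coefficient (0.2 Å²/ps ≈ 2.0e-5 cm²/s), 300 K, a 40 Å
    periodic cell along the pore axis and eight permeant cations (a
    high-salt-like ion count chosen for crossing statistics).
    """

    pmf: Pmf = field(default_factory=Pmf.flat)
    radial_spring: float = 1.0          # kcal/mol/Å², inside |z| < pore_half_length
    diffusion_coefficient: float = 0.2  # Å²/ps
    ion_charge: float = 1.0             # e
    box_length: float = 40.0            # L_z, Å
    box_xy: float = 20.0                # lateral box edge, Å
    applied_field: float = 0.0          # E, V/nm, along z
    temperature: float = 300.0          # K
    n_ions: int = 8
    pore_half_length: float = 10.0      # Å; radial confinement active inside

    def __post_init__(self):
        if self.diffusion_coefficient <= 0:
            raise ContractError("diffusion_coefficient must be > 0")
        if self.temperature <= 0:
            raise ContractError("temperature must be > 0")
        if abs(self.pmf.length - self.box_length) > 1e-6:
            raise ContractError(
                f"PMF spans {self.pmf.length} Å but box_length is {self.box_length} Å"
            )

    @property
    def kT(self) -> float:
        return R_KCAL * self.temperature

    @property
    def field_force(self) -> float:
        """Force qE on one ion in kcal/mol/Å (E given in V/nm)."""
        return self.ion_charge * (self.applied_field * 0.1) * EV_TO_KCAL

    @property
    def drift_velocity(self) -> float:
        """Field-driven drift v = D q E / kT in Å/ps (flat-PMF closed form)."""
        return self.diffusion_coefficient * self.field_force / self.kT

    @property
    def voltage_mv(self) -> float:
        """V = E L_z of the applied-field protocol, in mV."""
        return self.applied_field * (self.box_length / 10.0) * 1000.0


@dataclass
class GroundTruth:
    """Generator parameters stored alongside every synthetic trajectory."""

    pmf_z: list
    pmf_u: list
    diffusion_coefficient: float
    temperature: float
    applied_field: float
    ion_charge: float
    box_length: float
    n_ions: int
    rng_seed: int
    dt: float
    n_steps: int
    theoretical_mean_flux: float | None  # net permeation events / µs (all ions)

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


def theoretical_flux_events_per_us(model: PoreModel) -> float | None:
    """Closed-form net crossing rate for the whole system, events/µs.

    Exact for a flat PMF under a uniform field (v/L_z per ion); zero at
    zero field in equilibrium; ``None`` when no closed form applies.
    """
    if model.pmf.is_flat:
        return model.n_ions * model.drift_velocity / model.box_length * 1e6
    if model.applied_field == 0.0:
        return 0.0
    return None


# ---------------------------------------------------------------------------
# Overdamped Langevin simulator
# ---------------------------------------------------------------------------


def _boltzmann_initial_z(pmf: Pmf, kT: float, n: int, rng) -> np.ndarray:
    h = pmf.length / 2
    zg = np.linspace(-h, h, 4001)
    w = np.exp(-(pmf.u(zg) - pmf.u(zg).min()) / kT)
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, zg)


def simulate_langevin_pore(
    model: PoreModel,
    n_steps: int,
    dt: float,
    seed: int,
    save_stride: int = 10,
    n_water: int = 0,
) -> tuple[FrameSeries, GroundTruth]:
    """Brownian dynamics of ions in the model pore.

    Per-ion update (overdamped, Euler–Maruyama)::

        z <- z + (D/kT) F(z) dt + sqrt(2 D dt) eta,   F = -dU/dz + qE

    with periodic wrapping in z. Laterally, ions feel a harmonic
    confinement toward the axis while inside the pore (|z| <
    ``pore_half_length``) and diffuse freely outside, reflected at the box
    walls. Optional non-interacting pseudo-water (ideal-gas oxygen sites,
    re-sampled each saved frame) supports cavity-count tests; hydration-shell
    physics is deliberately *not* simulated here.

    Raises :class:`StepSizeError` if any single-step displacement exceeds
    5 Å, and :class:`ContractError` when dt violates the drift bound
    max|F| dt D / kT < 0.2 Å.
    """
    if n_steps < 1 or dt <= 0:
        raise ContractError("n_steps >= 1 and dt > 0 required")
    kT = model.kT
    D = model.diffusion_coefficient
    mobility = D / kT

    # stability contract on the axial deterministic drift
    slopes = np.diff(model.pmf.u_knots) / np.diff(model.pmf.z_knots)
    f_max = float(np.max(np.abs(slopes))) + abs(model.field_force)
    if f_max * dt * mobility >= 0.2:
        raise ContractError(
            f"time step too large: max|F| dt D/kT = {f_max * dt * mobility:.3f} Å "
            ">= 0.2 Å; reduce dt"
        )
    # the lateral harmonic confinement must also relax stably
    if model.radial_spring * dt * mobility >= 0.5:
        raise ContractError("time step too large for the radial spring; reduce dt")

    rng = np.random.default_rng(seed)
    n = model.n_ions
    half_l = model.box_length / 2
    half_xy = model.box_xy / 2
    sigma = math.sqrt(2 * D * dt)

    # force lookup on a fine periodic grid (piecewise-constant segments)
    ngrid = 8192
    zg = -half_l + (np.arange(ngrid) + 0.5) * (model.box_length / ngrid)
    f_grid = model.pmf.force(zg) + model.field_force
    inv_dz = ngrid / model.box_length

    z = _boltzmann_initial_z(model.pmf, kT, n, rng)
    xy = (rng.random((n, 2)) - 0.5) * model.box_xy * 0.5

    n_saved = n_steps // save_stride + 1
    n_atoms = n + n_water
    positions = np.empty((n_saved, n_atoms, 3))
    times = np.empty(n_saved)

    def snapshot(k: int, step: int):
        positions[k, :n, 0] = xy[:, 0]
        positions[k, :n, 1] = xy[:, 1]
        positions[k, :n, 2] = z
        if n_water:
            positions[k, n:, 0] = (rng.random(n_water) - 0.5) * model.box_xy
            positions[k, n:, 1] = (rng.random(n_water) - 0.5) * model.box_xy
            positions[k, n:, 2] = (rng.random(n_water) - 0.5) * model.box_length
        times[k] = step * dt

    snapshot(0, 0)
    saved = 1
    chunk = 10000
    step = 0
    while step < n_steps:
        m = min(chunk, n_steps - step)
        noise = rng.standard_normal((m, n, 3)) * sigma
        for j in range(m):
            idx = ((z + half_l) * inv_dz).astype(np.intp) % ngrid
            dz = mobility * f_grid[idx] * dt + noise[j, :, 2]
            if np.any(np.abs(dz) > 5.0):
                k = int(np.argmax(np.abs(dz)))
                raise StepSizeError(
                    f"unstable step at step {step + j + 1}: ion {k} moved "
                    f"{dz[k]:.2f} Å in one step", step=step + j + 1,
                )
            z = z + dz
            z = (z + half_l) % model.box_length - half_l
            inside = np.abs(z) < model.pore_half_length
            f_xy = np.where(inside[:, None], -model.radial_spring * xy, 0.0)
            xy = xy + mobility * f_xy * dt + noise[j, :, :2]
            # reflecting walls at +/- box_xy/2
            xy = np.where(xy > half_xy, model.box_xy - xy, xy)
            xy = np.where(xy < -half_xy, -model.box_xy - xy, xy)
            if (step + j + 1) % save_stride == 0:
                snapshot(saved, step + j + 1)
                saved += 1
        step += m

    names = ["K"] * n + ["OW"] * n_water
    resnames = ["K"] * n + ["SOL"] * n_water
    resids = list(range(1, n_atoms + 1))
    charges = np.concatenate([np.full(n, model.ion_charge), np.zeros(n_water)])
    structure = build_structure(
        names, resnames, resids, positions[0], charges=charges,
        box=np.array([model.box_xy, model.box_xy, model.box_length]),
    )
    box = np.tile(
        np.array([model.box_xy, model.box_xy, model.box_length]), (saved, 1)
    )
    gt = GroundTruth(
        pmf_z=model.pmf.z_knots.tolist(),
        pmf_u=model.pmf.u_knots.tolist(),
        diffusion_coefficient=D,
        temperature=model.temperature,
        applied_field=model.applied_field,
        ion_charge=model.ion_charge,
        box_length=model.box_length,
        n_ions=n,
        rng_seed=seed,
        dt=dt,
        n_steps=n_steps,
        theoretical_mean_flux=theoretical_flux_events_per_us(model),
    )
    from .core import PoreAlignment, SelectionSpec

    frames = FrameSeries(
        structure=structure,
        times=times[:saved],
        positions=positions[:saved],
        box=box,
        # the model pore is constructed axis-aligned and centred by design
        alignment=PoreAlignment(
            rotation=np.eye(3), translation=np.zeros(3),
            sf_selection=SelectionSpec("resname K"), z_orientation=+1,
        ),
        ground_truth=gt,
    )
    return frames, gt


# ---------------------------------------------------------------------------
# Solvation fixtures (hydration census oracles)
# ---------------------------------------------------------------------------


def _uniform_in_sphere_shell(rng, n: int, r_lo: float, r_hi: float) -> np.ndarray:
    """n points with distance drawn uniformly (in distance) from (r_lo, r_hi)."""
    r = rng.uniform(r_lo, r_hi, n)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * r[:, None]


def make_solvation_fixture(
    n_water_shell: int,
    n_carbonyl_shell: int,
    n_background: int,
    r_shell: float,
    seed: int,
    box: float = 30.0,
) -> Structure:
    """One cation at the origin with an exactly known first shell.

    ``n_water_shell`` water oxygens (name OW) and ``n_carbonyl_shell``
    backbone-carbonyl-tagged oxygens (name O, protein residue) are placed
    uniformly at distances in (0.6 r_shell, r_shell); ``n_background`` of
    each type are placed uniformly *outside* 1.5 r_shell (so a background-only
    fixture contributes exactly zero to the census inside r_shell).
    """
    if min(n_water_shell, n_carbonyl_shell, n_background) < 0:
        raise ContractError("counts must be >= 0")
    if box < 4 * r_shell:
        raise ContractError("box too small for the background exclusion zone")
    rng = np.random.default_rng(seed)

    shell_w = _uniform_in_sphere_shell(rng, n_water_shell, 0.6 * r_shell, r_shell)
    shell_c = _uniform_in_sphere_shell(rng, n_carbonyl_shell, 0.6 * r_shell, r_shell)

    def background(n):
        pts = []
        while len(pts) < n:
            cand = (rng.random((max(8, 2 * (n - len(pts))), 3)) - 0.5) * box
            keep = np.linalg.norm(cand, axis=1) > 1.5 * r_shell
            pts.extend(cand[keep][: n - len(pts)])
        return np.array(pts).reshape(n, 3)

    bg_w = background(n_background)
    bg_c = background(n_background)

    pos = np.vstack([np.zeros((1, 3)), shell_w, bg_w, shell_c, bg_c])
    nw = n_water_shell + n_background
    nc = n_carbonyl_shell + n_background
    names = ["K"] + ["OW"] * nw + ["O"] * nc
    resnames = ["K"] + ["SOL"] * nw + ["GLY"] * nc
    resids = list(range(1, 2 + nw + nc))
    charges = np.zeros(1 + nw + nc)
    charges[0] = 1.0
    return build_structure(names, resnames, resids, pos, charges=charges,
                          box=np.array([box, box, box]))


def make_uniform_solvent_box(
    density: float, box: float, seed: int, ion_at_origin: bool = True,
) -> Structure:
    """Ideal-gas water oxygens at the given number density (Å^-3).

    The census expectation inside a shell of radius r is the analytic
    sphere volume rho (4/3) pi r^3 — the oracle for uniform-background tests.
    """
    rng = np.random.default_rng(seed)
    n = rng.poisson(density * box**3)
    pos_w = (rng.random((n, 3)) - 0.5) * box
    if ion_at_origin:
        pos = np.vstack([np.zeros((1, 3)), pos_w])
        names = ["K"] + ["OW"] * n
        resnames = ["K"] + ["SOL"] * n
    else:
        pos = pos_w
        names = ["OW"] * n
        resnames = ["SOL"] * n
    resids = list(range(1, len(names) + 1))
    return build_structure(names, resnames, resids, pos,
                          box=np.array([box, box, box]))


@dataclass
class SolvationRdf:
    """Parametric cation-oxygen radial distribution function g(r).

    Models the structured first solvation shell of K+ in water: an
    excluded core, a Gaussian first peak near 2.8 Å (height ~2.7,
    width 0.30 Å) and a shallow first minimum near 3.7 Å — standard
    neutron-diffraction / simulation magnitudes for K+–water oxygen.
    """

    r_core: float = 2.40
    peak_r: float = 2.80
    peak_height: float = 2.70
    peak_width: float = 0.30
    dip_r: float = 3.70
    dip_depth: float = 0.30
    dip_width: float = 0.40

    def g(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, float)
        out = (
            1.0
            + (self.peak_height - 1.0)
            * np.exp(-((r - self.peak_r) ** 2) / (2 * self.peak_width**2))
            - self.dip_depth
            * np.exp(-((r - self.dip_r) ** 2) / (2 * self.dip_width**2))
        )
        return np.where(r < self.r_core, 0.0, out)

    def expected_coordination(self, r_cut: float, density: float) -> float:
        """rho * integral_0^r_cut g(r) 4 pi r^2 dr (the analytic census)."""
        r = np.linspace(0, r_cut, 2001)
        return float(density * np.trapezoid(self.g(r) * 4 * np.pi * r**2, r))


def make_bulk_solvation(
    n_frames: int,
    seed: int,
    density: float = 0.0334,
    rdf: SolvationRdf | None = None,
    r_structured: float = 6.0,
    box: float = 24.0,
) -> list[Structure]:
    """Independent snapshots of bulk solvation around a cation.

    Water-oxygen positions are drawn from the inhomogeneous Poisson
    process with intensity ``density * g(r)`` inside ``r_structured`` and
    uniform at ``density`` beyond it (out to the box walls). The mean
    first-shell census over frames converges to
    ``rdf.expected_coordination(shell_radius, density)``.
    """
    rdf = rdf or SolvationRdf()
    rng = np.random.default_rng(seed)
    rg = np.linspace(0, r_structured, 1201)
    intensity = density * rdf.g(rg) * 4 * np.pi * rg**2
    cum = np.concatenate([[0.0], np.cumsum((intensity[1:] + intensity[:-1]) / 2
                                           * np.diff(rg))])
    lam = cum[-1]
    out: list[Structure] = []
    v_box = box**3
    v_sphere = 4 / 3 * np.pi * r_structured**3
    lam_bg = density * (v_box - v_sphere)
    for _ in range(n_frames):
        n_in = rng.poisson(lam)
        u = rng.random(n_in) * lam
        r = np.interp(u, cum, rg)
        dirs = rng.standard_normal((n_in, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = [dirs * r[:, None]]
        n_bg = rng.poisson(lam_bg)
        cand = (rng.random((int(n_bg * 1.4) + 16, 3)) - 0.5) * box
        cand = cand[np.linalg.norm(cand, axis=1) > r_structured][: n_bg]
        pts.append(cand)
        pos_w = np.vstack(pts)
        pos = np.vstack([np.zeros((1, 3)), pos_w])
        nw = len(pos_w)
        out.append(
            build_structure(
                ["K"] + ["OW"] * nw, ["K"] + ["SOL"] * nw,
                list(range(1, nw + 2)), pos, box=np.array([box, box, box]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cylinder / hourglass pore fixtures (pore-radius oracle)
# ---------------------------------------------------------------------------


def make_cylinder_pore(
    axis_radius,
    atom_vdw: float = 1.5,
    z_extent: float = 30.0,
    n_rings: int = 31,
    atoms_per_ring: int = 12,
) -> Structure:
    """Rings of atoms of vdW radius ``atom_vdw`` stacked along z.

    ``axis_radius`` is either a number (cylinder) or a callable a(z)
    (e.g. an hourglass). The exact largest-inscribed-sphere radius on the
    axis is ``a - atom_vdw`` (cylinder case).
    """
    a_of_z = axis_radius if callable(axis_radius) else (lambda z: float(axis_radius))
    zs = np.linspace(-z_extent / 2, z_extent / 2, n_rings)
    if min(a_of_z(z) for z in zs) <= atom_vdw:
        raise ContractError("ring radius must exceed the atomic vdW radius")
    pos = []
    for z in zs:
        a = a_of_z(z)
        for k in range(atoms_per_ring):
            th = 2 * np.pi * k / atoms_per_ring
            pos.append([a * np.cos(th), a * np.sin(th), z])
    pos = np.array(pos)
    n = len(pos)
    names = ["C"] * n
    resnames = ["RNG"] * n
    resids = [i // atoms_per_ring + 1 for i in range(n)]
    s = build_structure(names, resnames, resids, pos,
                        box=np.array([6 * max(a_of_z(z) for z in zs)] * 2
                                     + [z_extent * 2]))
    s.atoms["vdw_radius"] = atom_vdw
    return s


# ---------------------------------------------------------------------------
# Two-state single-channel trace simulator
# ---------------------------------------------------------------------------


@dataclass
class TwoStateChannelModel:
    """Closed/open Markov gating with Gaussian recording noise.

    Defaults mirror a low-noise patch-clamp recording: 10 kHz sampling,
    1 kHz 4-pole Bessel filter corner, sub-pA unitary current.
    """

    k_open: float = 50.0        # 1/s, closed -> open
    k_close: float = 50.0       # 1/s, open -> closed
    i_open: float = -0.16       # pA
    noise_sigma: float = 0.05   # pA
    sampling_rate: float = 10_000.0  # Hz
    filter_corner: float = 1_000.0   # Hz

    def __post_init__(self):
        if self.k_open < 0 or self.k_close < 0:
            raise ContractError("rates must be >= 0")
        if self.k_open == 0 and self.k_close == 0:
            raise ContractError("at least one rate must be positive")
        if self.sampling_rate <= 2 * self.filter_corner:
            raise ContractError("sampling_rate must exceed 2 x filter_corner")

    @property
    def p_open(self) -> float:
        return self.k_open / (self.k_open + self.k_close)


def simulate_patch_trace(
    model: TwoStateChannelModel,
    duration: float,
    seed: int,
    apply_filter: bool = False,
    holding_voltage: float | None = None,
) -> CurrentTrace:
    """Sample a two-state gating trace at the model's sampling rate.

    Continuous-time exponential dwell times are generated first and then
    sampled; current is ``i_open`` while open and exactly 0 while closed,
    with additive Gaussian noise. ``apply_filter`` applies the 4-pole
    low-pass at ``filter_corner`` (off by default so the noise level of
    the samples equals ``noise_sigma`` exactly).
    """
    n_samples = int(round(duration * model.sampling_rate))
    if n_samples < 10_000:
        raise ContractError("duration x sampling_rate must be >= 1e4 samples")
    rng = np.random.default_rng(seed)
    ideal = np.zeros(n_samples)

    if model.k_open == 0.0:
        pass  # channel never opens
    elif model.k_close == 0.0:
        ideal[:] = model.i_open
    else:
        dt = 1.0 / model.sampling_rate
        state = 1 if rng.random() < model.p_open else 0
        t = 0.0
        i0 = 0
        while t < duration:
            rate = model.k_close if state == 1 else model.k_open
            dwell = rng.exponential(1.0 / rate)
            i1 = min(n_samples, int((t + dwell) / dt))
            if state == 1:
                ideal[i0:i1] = model.i_open
            t += dwell
            i0 = i1
            state = 1 - state

    samples = ideal + rng.standard_normal(n_samples) * model.noise_sigma
    if apply_filter:
        samples = bessel_lowpass(samples, model.sampling_rate, model.filter_corner)
    return CurrentTrace(
        samples=samples,
        sampling_rate=model.sampling_rate,
        filter_corner=model.filter_corner if apply_filter else None,
        holding_voltage=holding_voltage,
    )
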