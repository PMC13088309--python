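"""Transmembrane voltage for both simulation protocols.

Applied-field protocol: a uniform external field E along z generates

    V = E L_z                                        (mV from V/nm and nm)

Charge-imbalance (computational electrophysiology) protocol: the voltage
profile follows from the z-binned charge density by double integration of
the 1D Poisson equation

    -d^2 phi / dz^2 = rho(z) / eps0

under the periodic gauge (field and potential periodic across the box,
zero-mean potential). The compartment voltage difference is the mean
potential contrast between the two aqueous compartment interiors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    EPS0_E_PER_V_A,
    ContractError,
    FrameSeries,
)


@dataclass
class FieldVoltageSpec:
    """Uniform applied field along z and the voltage it generates."""

    E: float     # V/nm
    L_z: float   # nm

    def __post_init__(self):
        if self.L_z <= 0:
            raise ContractError("L_z must be positive")

    @property
    def V(self) -> float:
        return field_voltage(self.E, self.L_z)


def field_voltage(E: float, L_z: float) -> float:
    """V = E L_z in mV (E in V/nm, L_z in nm)."""
    if L_z <= 0:
        raise ContractError("L_z must be positive")
    return E * L_z * 1e3


def field_for_voltage(V: float, L_z: float) -> float:
    """Inverse mode: the field E (V/nm) producing target V (mV) over L_z (nm)."""
    if L_z <= 0:
        raise ContractError("L_z must be positive")
    return V / 1e3 / L_z


@dataclass
class CompELSpec:
    """Charge-imbalance voltage analysis inputs.

    ``charge_density`` holds per-bin charge density in e/Å^3 on the
    uniform grid ``z_edges`` (Å); ``compartment_bounds`` are the two
    aqueous compartments' z ranges. ``relative_permittivity`` stays 1
    when all charges are explicit.
    """

    z_edges: np.ndarray
    charge_density: np.ndarray          # e/Å^3 per bin
    compartment_bounds: list = field(
        default_factory=lambda: [(0.0, 0.0), (0.0, 0.0)]
    )
    charge_imbalance: float | None = None  # e, bookkeeping only
    relative_permittivity: float = 1.0
    neutrality_tol: float = 1e-6           # e/Å^2 of net areal charge

    def __post_init__(self):
        self.z_edges = np.asarray(self.z_edges, float)
        self.charge_density = np.asarray(self.charge_density, float)
        if len(self.charge_density) != len(self.z_edges) - 1:
            raise ContractError("charge_density must have one value per bin")
        dz = np.diff(self.z_edges)
        if not np.allclose(dz, dz[0]):
            raise ContractError("charge density must be binned on a uniform grid")


@dataclass
class VoltageProfile:
    z: np.ndarray         # bin edges, Å
    phi: np.ndarray       # V, at edges, zero-mean gauge
    delta_v: float | None  # V between compartment interiors (second - first)


def poisson_voltage_profile(spec: CompELSpec,
                            gauge: str = "periodic") -> VoltageProfile:
    """phi(z) from the binned charge density by cumulative double integration.

    The piecewise-constant density integrates exactly: the field is
    piecewise linear across each bin and the potential piecewise
    quadratic. ``gauge`` fixes the integration constants:

    * ``"periodic"`` (default, the double-bilayer setting) — field and
      potential periodic across the box, zero-mean potential;
    * ``"open"`` — zero field at the lower box edge, the isolated-membrane
      convention (reproduces the textbook parallel-plate formula
      |dV| = sigma d / eps0 exactly).

    Raises on net charge beyond ``neutrality_tol`` (per unit area), since
    a charged cell admits neither solution.
    """
    if gauge not in ("periodic", "open"):
        raise ContractError(f"unknown gauge {gauge!r}")
    rho = spec.charge_density / spec.relative_permittivity
    edges = spec.z_edges
    dz = float(edges[1] - edges[0])
    net = float(np.sum(rho) * dz)  # e/Å^2 of areal charge
    if abs(net) > spec.neutrality_tol:
        raise ContractError(
            f"net areal charge {net:.3e} e/Å^2 exceeds neutrality tolerance; "
            "a periodic potential does not exist"
        )
    eps0 = EPS0_E_PER_V_A
    # field at edges: E[j+1] = E[j] + rho_j dz / eps0 (Gauss)
    e_edges = np.concatenate([[0.0], np.cumsum(rho) * dz / eps0])
    if gauge == "periodic":
        # remove the mean of the piecewise-linear field over the box
        e_mid = (e_edges[:-1] + e_edges[1:]) / 2
        e_edges -= e_mid.mean()
    # potential: phi[j+1] = phi[j] - (E_j dz + rho_j dz^2 / (2 eps0))
    dphi = -(e_edges[:-1] * dz + rho * dz**2 / (2 * eps0))
    phi = np.concatenate([[0.0], np.cumsum(dphi)])
    phi -= phi.mean()

    delta_v = None
    (a0, b0), (a1, b1) = spec.compartment_bounds[0], spec.compartment_bounds[1]
    if b0 > a0 and b1 > a1:
        centers = (edges[:-1] + edges[1:]) / 2
        phi_c = (phi[:-1] + phi[1:]) / 2

        def interior_mean(a, b):
            # central 50 % of the compartment
            w = (b - a) / 4
            m = (centers >= a + w) & (centers <= b - w)
            if not np.any(m):
                raise ContractError(f"compartment ({a}, {b}) covers no bins")
            return float(phi_c[m].mean())

        delta_v = interior_mean(a1, b1) - interior_mean(a0, b0)
    return VoltageProfile(z=edges.copy(), phi=phi, delta_v=delta_v)


def charge_density_from_frames(
    frames: FrameSeries,
    z_edges: np.ndarray,
) -> np.ndarray:
    """Per-bin charge density in e/Å^3 averaged over frames.

    Uses the atom table's partial charges; raises listing the offending
    atoms when charges are missing (NaN).
    """
    q = frames.structure.atoms["partial_charge"].to_numpy(dtype=float)
    if np.any(~np.isfinite(q)):
        bad = frames.structure.atoms.loc[
            ~np.isfinite(q), "atom_name"
        ].tolist()
        raise ContractError(
            f"missing partial charges for atoms {bad[:8]}"
            + ("..." if len(bad) > 8 else "")
        )
    z_edges = np.asarray(z_edges, float)
    total = np.zeros(len(z_edges) - 1)
    for f in range(frames.n_frames):
        h, _ = np.histogram(frames.positions[f, :, 2], bins=z_edges, weights=q)
        total += h
    area = float(np.mean(frames.box[:, 0] * frames.box[:, 1]))
    volume = area * np.diff(z_edges)
    return total / frames.n_frames / volume
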