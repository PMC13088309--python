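"""Shared fixtures: synthetic trajectories and structures reused across tests.

The heavier Langevin runs are session-scoped so the Boltzmann-inversion
and conductance checks share one simulation each.
"""

from __future__ import annotations

import numpy as np
import pytest

import poreflow as pf
from poreflow.synth import Pmf, PoreModel, simulate_langevin_pore


@pytest.fixture(scope="session")
def doublewell_run():
    """1e6-step equilibrium run in the standard double-well PMF.

    Wells of -3 kcal/mol at ±8 Å separated by a 4 kcal/mol barrier
    (peak +1 relative to bulk), eight ions, D = 0.2 Å²/ps, 300 K.
    """
    pmf = Pmf.double_well()
    model = PoreModel(pmf=pmf)
    frames, gt = simulate_langevin_pore(model, 1_000_000, 0.2, seed=1,
                                        save_stride=5)
    return frames, gt, model


@pytest.fixture(scope="session")
def field_run():
    """Flat-PMF drift run under an applied field (known closed-form flux)."""
    model = PoreModel(pmf=Pmf.flat(40.0), applied_field=0.1)
    frames, gt = simulate_langevin_pore(model, 400_000, 0.2, seed=2,
                                        save_stride=50)
    return frames, gt, model


@pytest.fixture()
def ion_selection():
    return pf.SelectionSpec("resname K")


@pytest.fixture()
def ring_structure():
    """8-atom carbonyl-oxygen ring (an idealised SF plane) plus scaffold."""
    rng = np.random.default_rng(0)
    th = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    ring = np.c_[3 * np.cos(th), 3 * np.sin(th), np.zeros(8)]
    scaffold = rng.standard_normal((40, 3)) * 6 + [0, 0, -6]
    pos = np.vstack([ring, scaffold])
    names = ["O"] * 8 + ["CA"] * 40
    resnames = ["GLY"] * 8 + ["ALA"] * 40
    return pf.build_structure(names, resnames, list(range(1, 49)), pos,
                              box=np.array([60.0, 60.0, 60.0]))


def frames_from_positions(structure, positions, dt=10.0, box=None,
                          aligned=True):
    """Helper: wrap a (n_frames, n_atoms, 3) array into a FrameSeries."""
    positions = np.asarray(positions, float)
    n = len(positions)
    if box is None:
        box = structure.box if structure.box is not None else [100.0] * 3
    alignment = None
    if aligned:
        alignment = pf.PoreAlignment(
            rotation=np.eye(3), translation=np.zeros(3),
            sf_selection=pf.SelectionSpec("all"), z_orientation=+1,
        )
    return pf.FrameSeries(
        structure=structure,
        times=np.arange(n, dtype=float) * dt,
        positions=positions,
        box=np.tile(np.asarray(box, float), (n, 1)),
        alignment=alignment,
    )
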