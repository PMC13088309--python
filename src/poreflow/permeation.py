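"""Permeation-event detection and single-channel conductance.

A permeation event is one ion's complete traversal of the pore from one
mouth to the other. Detection uses a three-zone state machine per ion
(above the extracellular boundary / inside the pore / below the
intracellular boundary): an event is emitted only on the full sequence
above -> inside -> below (inward, direction -1) or below -> inside ->
above (outward, +1). Re-entry without completing the traversal emits
nothing, which gives the machine its hysteresis — boundary flicker can
never double count. While inside, the ion must stay within a lateral
cylinder of radius ``r_max``; leaving it resets the ion to whichever bulk
zone it next visits.

Event counts convert to conductance as g = |N_net e / (T V)| in pS, and
replicas aggregate as mean ± SD (n-1), the convention used for sets of
independent simulation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    E_CHARGE,
    AlignmentError,
    ContractError,
    FrameSeries,
    SelectionSpec,
)


@dataclass
class PoreBoundaries:
    """Axial and lateral extent of the pore for crossing classification.

    Defaults place the boundaries a few Å beyond typical SF-top and
    gate-residue planes of an aligned channel; all three are analysis
    parameters, not physical constants.
    """

    z_top: float          # Å, extracellular boundary (SF side)
    z_bottom: float       # Å, intracellular boundary (gate side)
    r_max: float = 8.0    # Å, lateral cylinder radius

    def __post_init__(self):
        if self.z_top <= self.z_bottom:
            raise ContractError("z_top must be above z_bottom")
        if self.r_max <= 0:
            raise ContractError("r_max must be positive")


@dataclass
class PermeationEvent:
    ion_id: int        # atom id
    t_enter: float     # ps, first frame inside the pore
    t_exit: float      # ps, frame completing the traversal
    direction: int     # +1 outward (toward +z), -1 inward
    charge: float = 1.0  # e

    def __post_init__(self):
        if self.t_exit <= self.t_enter:
            raise ContractError("t_exit must be after t_enter")


@dataclass
class ConductanceEstimate:
    n_events: int
    net_charge: float      # e, signed sum direction * charge
    duration: float        # µs
    voltage: float         # mV
    conductance: float     # pS
    gross_events: int = 0  # unsigned event count
    per_replica: list = field(default_factory=list)
    mean: float | None = None
    sd: float | None = None


# zone codes
_ABOVE, _INSIDE, _BELOW, _OUT = 2, 1, 0, -1


def _zones(z_wrapped: np.ndarray, r2: np.ndarray, bounds: PoreBoundaries) -> np.ndarray:
    zone = np.full(z_wrapped.shape, _OUT, dtype=np.int8)
    zone[z_wrapped > bounds.z_top] = _ABOVE
    zone[z_wrapped < bounds.z_bottom] = _BELOW
    inside_z = (z_wrapped >= bounds.z_bottom) & (z_wrapped <= bounds.z_top)
    zone[inside_z & (r2 <= bounds.r_max**2)] = _INSIDE
    return zone


def detect_permeation_events(
    frames: FrameSeries,
    ion_sel: SelectionSpec,
    bounds: PoreBoundaries,
) -> list[PermeationEvent]:
    """Classify complete pore traversals for every selected ion.

    Frames must carry a pore alignment. Ion z coordinates are re-wrapped
    by minimum image around the pore centre each frame before zone
    classification, so an ion re-entering through the periodic image
    cannot fabricate a traversal: a wrap jump moves it directly between
    the two bulk zones without ever visiting the inside zone.
    """
    if frames.alignment is None:
        raise AlignmentError(
            "frames carry no PoreAlignment; run align_to_pore_axis first"
        )
    idx = ion_sel.resolve(frames.structure)
    if len(idx) == 0:
        raise ContractError(f"ion selection {ion_sel.expression!r} is empty")
    atom_ids = frames.structure.atoms["atom_id"].to_numpy()[idx]
    charges = frames.structure.atoms["partial_charge"].to_numpy()[idx]
    charges = np.where(np.isfinite(charges) & (charges != 0), charges, 1.0)

    center = (bounds.z_top + bounds.z_bottom) / 2
    n_ions = len(idx)

    # state per ion: the last bulk zone visited (or _OUT when unknown),
    # plus whether it is currently transiting the inside zone
    last_bulk = np.full(n_ions, _OUT, dtype=np.int8)
    transiting = np.zeros(n_ions, dtype=bool)
    t_enter = np.zeros(n_ions)
    events: list[PermeationEvent] = []

    for f in range(frames.n_frames):
        lz = frames.box[f, 2]
        z = frames.positions[f, idx, 2]
        zw = np.mod(z - center + lz / 2, lz) - lz / 2 + center
        r2 = frames.positions[f, idx, 0] ** 2 + frames.positions[f, idx, 1] ** 2
        zone = _zones(zw, r2, bounds)
        t = frames.times[f]
        for i in range(n_ions):
            zi = zone[i]
            if zi == _INSIDE:
                if not transiting[i] and last_bulk[i] != _OUT:
                    transiting[i] = True
                    t_enter[i] = t
                continue
            if zi == _OUT:
                # left the r_max cylinder mid-pore: reset until a bulk zone
                transiting[i] = False
                last_bulk[i] = _OUT
                continue
            # in a bulk zone (above or below)
            if transiting[i] and zi != last_bulk[i]:
                direction = +1 if zi == _ABOVE else -1
                events.append(
                    PermeationEvent(
                        ion_id=int(atom_ids[i]),
                        t_enter=float(t_enter[i]),
                        t_exit=float(t),
                        direction=direction,
                        charge=float(charges[i]),
                    )
                )
            transiting[i] = False
            last_bulk[i] = zi
    return events


def estimate_conductance(
    events: list[PermeationEvent],
    duration: float,
    voltage: float,
    replica: str | int | None = None,
) -> ConductanceEstimate:
    """Convert crossing records into conductance.

    I = N_net e / T and g = |I / V| expressed in pS; ``duration`` in µs,
    ``voltage`` in mV. Net signed charge is used; the gross (unsigned)
    event count is reported alongside.
    """
    if voltage == 0:
        raise ContractError(
            f"voltage is zero for replica {replica!r}; conductance undefined"
        )
    if duration <= 0:
        raise ContractError("duration must be positive")
    net = sum(e.direction * e.charge for e in events)
    current_pa = net * E_CHARGE / (duration * 1e-6) * 1e12
    conductance = abs(current_pa / voltage) * 1e3  # pA/mV -> pS
    return ConductanceEstimate(
        n_events=len(events),
        net_charge=float(net),
        duration=duration,
        voltage=voltage,
        conductance=float(conductance),
        gross_events=len(events),
    )


def aggregate_replicas(estimates: list[ConductanceEstimate]) -> ConductanceEstimate:
    """Mean ± SD (n-1) conductance over parallel replicas at one voltage."""
    if len(estimates) < 2:
        raise ContractError("need >= 2 replicas to aggregate")
    voltages = {e.voltage for e in estimates}
    if len(voltages) > 1:
        raise ContractError(f"mixed replica voltages: {sorted(voltages)}")
    g = np.array([e.conductance for e in estimates])
    return ConductanceEstimate(
        n_events=int(sum(e.n_events for e in estimates)),
        net_charge=float(sum(e.net_charge for e in estimates)),
        duration=float(sum(e.duration for e in estimates)),
        voltage=estimates[0].voltage,
        conductance=float(g.mean()),
        gross_events=int(sum(e.gross_events for e in estimates)),
        per_replica=[float(x) for x in g],
        mean=float(g.mean()),
        sd=float(g.std(ddof=1)),
    )


def ion_z_traces(frames: FrameSeries, ion_sel: SelectionSpec) -> "np.ndarray":
    """Per-ion axial coordinate vs. time, for visual inspection of crossings.

    Returns an (n_frames, 1 + n_ions) array whose first column is time in
    ps and remaining columns the selected ions' z in Å.
    """
    idx = ion_sel.resolve(frames.structure)
    if len(idx) == 0:
        raise ContractError(f"ion selection {ion_sel.expression!r} is empty")
    return np.column_stack([frames.times, frames.positions[:, idx, 2]])


def events_table(events: list[PermeationEvent]) -> "np.ndarray":
    """Events as a structured array (ion_id, t_enter, t_exit, direction)."""
    dtype = [("ion_id", int), ("t_enter", float), ("t_exit", float),
             ("direction", int)]
    return np.array(
        [(e.ion_id, e.t_enter, e.t_exit, e.direction) for e in events],
        dtype=dtype,
    )
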