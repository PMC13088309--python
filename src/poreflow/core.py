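"""Structures, trajectories, atom selections and pore-axis alignment.

This module is the substrate for every analysis stage: it defines the
in-memory containers (:class:`Structure`, :class:`FrameSeries`), reads and
writes the standard structural-biology formats (PDB/GRO topologies,
XTC/DCD/TRR coordinate files, delegated to MDAnalysis) plus the package's
own HDF5 trajectory layout, and provides the rigid-body superposition that
places the channel's selectivity filter (SF) at the origin with the pore
axis along *z*.

Conventions
-----------
* coordinates in Å, times in ps, 0-based frame indices;
* residue ids are preserved verbatim from the topology (usually 1-based);
* boxes are orthorhombic edge lengths ``(Lx, Ly, Lz)`` in Å — triclinic
  input is rejected;
* after :func:`align_to_pore_axis`, +z points toward the extracellular
  side and the SF centroid sits at the origin in every frame.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("poreflow")

# ---------------------------------------------------------------------------
# Physical constants (CODATA-2018 where applicable)
# ---------------------------------------------------------------------------

#: Gas constant in kcal/(mol K)  (R = 8.314462618 J/(mol K) / 4184 J/kcal)
R_KCAL = 8.314462618e-3 / 4.184
#: Elementary charge, C
E_CHARGE = 1.602176634e-19
#: 1 eV in kcal/mol — converts (e x V/Å x Å) energies to kcal/mol
EV_TO_KCAL = 23.060548
#: Vacuum permittivity in e / (V Å):  eps0 = 8.8541878128e-12 C/(V m)
EPS0_E_PER_V_A = 8.8541878128e-12 / E_CHARGE * 1e-10


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class PoreflowError(Exception):
    """Base class for all package errors."""


class FormatError(PoreflowError):
    """Unreadable or unsupported file format (including triclinic boxes)."""


class EmptyInputError(PoreflowError):
    """A structure or selection that resolved to nothing where atoms are required."""


class TopologyError(PoreflowError):
    """Atom count or atom-table mismatch between topology and coordinates."""


class TrajectoryIOError(PoreflowError):
    """Failure while reading coordinate frames; carries the frame index."""

    def __init__(self, message: str, frame: int | None = None):
        super().__init__(message)
        self.frame = frame


class SelectionError(PoreflowError):
    """Malformed selection expression or empty selection where forbidden."""


class AlignmentError(PoreflowError):
    """Analysis requested on frames that lack the required pore alignment."""


class ContractError(PoreflowError):
    """A documented precondition of an operation was violated."""


# ---------------------------------------------------------------------------
# van der Waals radii — Bondi-style element table with atom-name overrides.
# Unresolvable names fall back to 1.5 Å (the HOLE default behaviour).
# ---------------------------------------------------------------------------

VDW_BY_ELEMENT: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "NA": 2.27, "MG": 1.73, "P": 1.80, "S": 1.80, "CL": 1.75,
    "K": 2.75, "CA": 2.31, "ZN": 1.39, "BR": 1.85, "I": 1.98,
    "LI": 1.82, "RB": 3.03, "CS": 3.43,
}

VDW_BY_ATOM_NAME: dict[str, float] = {
    "OW": 1.52, "HW1": 1.20, "HW2": 1.20, "MW": 0.0,
}

MASS_BY_ELEMENT: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06, "CL": 35.45,
    "K": 39.0983, "CA": 40.078, "ZN": 65.38, "BR": 79.904, "I": 126.904,
}

DEFAULT_VDW = 1.5

_TWO_LETTER_ELEMENTS = {"NA", "MG", "CL", "CA", "ZN", "BR", "LI", "RB", "CS", "FE", "MN"}


def guess_element(atom_name: str, residue_name: str = "") -> str:
    """Infer an element symbol from an atom name (PDB/GRO style)."""
    name = atom_name.strip().upper()
    stripped = "".join(ch for ch in name if ch.isalpha())
    if not stripped:
        return ""
    # Monatomic-ion residues (K, NA, CL, ...) name the atom after the element.
    if stripped in _TWO_LETTER_ELEMENTS and (
        residue_name.strip().upper().startswith(stripped) or name == stripped
    ):
        return stripped
    if stripped[:2] in _TWO_LETTER_ELEMENTS and residue_name.strip().upper() == stripped[:2]:
        return stripped[:2]
    return stripped[0]


def assign_vdw_radius(atom_name: str, element: str) -> float:
    name = atom_name.strip().upper()
    if name in VDW_BY_ATOM_NAME:
        return VDW_BY_ATOM_NAME[name]
    el = element.strip().upper()
    if el in VDW_BY_ELEMENT:
        return VDW_BY_ELEMENT[el]
    return -1.0  # caller logs the warning and applies DEFAULT_VDW


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

ATOM_COLUMNS = [
    "atom_id", "atom_name", "element", "residue_name", "residue_id",
    "chain_id", "vdw_radius", "partial_charge", "mass",
]


@dataclass
class AtomRecord:
    atom_id: int
    atom_name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    vdw_radius: float
    partial_charge: float
    mass: float


@dataclass
class Structure:
    """An atom table plus one coordinate set (Å)."""

    atoms: pd.DataFrame
    positions: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.atoms), 3):
            raise TopologyError(
                f"positions shape {self.positions.shape} inconsistent with "
                f"{len(self.atoms)} atoms"
            )
        if not self.atoms["atom_id"].is_unique:
            raise TopologyError("atom_id values must be unique within a structure")
        if (self.atoms["vdw_radius"] <= 0).any() and not (
            self.atoms["atom_name"].str.upper().isin(VDW_BY_ATOM_NAME).any()
        ):
            # virtual sites (e.g. MW) legitimately carry 0; anything else is a bug
            bad = self.atoms.loc[self.atoms["vdw_radius"] <= 0, "atom_name"].tolist()
            if bad:
                raise TopologyError(f"non-positive vdW radius for atoms {bad[:5]}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def record(self, i: int) -> AtomRecord:
        row = self.atoms.iloc[i]
        return AtomRecord(**{c: row[c] for c in ATOM_COLUMNS})


@dataclass(frozen=True)
class SelectionSpec:
    """Deterministic atom selection over the atom table.

    Expression grammar (whitespace separated, case-sensitive values)::

        expr      := term ('or' term)*
        term      := factor ('and' factor)*
        factor    := 'not' factor | '(' expr ')' | primitive
        primitive := 'all'
                   | 'protein'
                   | 'name'    VALUE+
                   | 'resname' VALUE+
                   | 'resid'   (N | N:M)+
                   | 'chain'   VALUE+
                   | 'element' VALUE+

    ``resolve`` returns the matching 0-based atom indices in ascending
    order — a deterministic, possibly empty, ordered list.
    """

    expression: str

    def resolve(self, structure: Structure) -> np.ndarray:
        mask = _parse_selection(self.expression, structure.atoms)
        return np.flatnonzero(mask)


_KEYWORDS = {"name", "resname", "resid", "chain", "element"}
_WATER_RESNAMES = {"SOL", "HOH", "WAT", "TIP3", "SPC", "TIP4"}
_ION_RESNAMES = {"K", "NA", "CL", "POT", "SOD", "CLA", "MG", "CA", "CAL"}


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


def _parse_selection(expression: str, atoms: pd.DataFrame) -> np.ndarray:
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_expr() -> np.ndarray:
        m = parse_term()
        while peek() == "or":
            take()
            m = m | parse_term()
        return m

    def parse_term() -> np.ndarray:
        m = parse_factor()
        while peek() == "and":
            take()
            m = m & parse_factor()
        return m

    def parse_factor() -> np.ndarray:
        tok = peek()
        if tok is None:
            raise SelectionError(f"unexpected end of expression: {expression!r}")
        if tok == "not":
            take()
            return ~parse_factor()
        if tok == "(":
            take()
            m = parse_expr()
            if peek() != ")":
                raise SelectionError(f"unbalanced parentheses in {expression!r}")
            take()
            return m
        return parse_primitive()

    def collect_values() -> list[str]:
        vals: list[str] = []
        while peek() is not None and peek() not in _KEYWORDS | {"and", "or", "not", "(", ")", "all", "protein"}:
            vals.append(take())
        if not vals:
            raise SelectionError(f"keyword without values in {expression!r}")
        return vals

    def parse_primitive() -> np.ndarray:
        tok = take()
        if tok == "all":
            return np.ones(len(atoms), dtype=bool)
        if tok == "protein":
            rn = atoms["residue_name"].str.upper()
            return (~rn.isin(_WATER_RESNAMES) & ~rn.isin(_ION_RESNAMES)).to_numpy()
        if tok == "name":
            return atoms["atom_name"].isin(collect_values()).to_numpy()
        if tok == "resname":
            return atoms["residue_name"].isin(collect_values()).to_numpy()
        if tok == "chain":
            return atoms["chain_id"].isin(collect_values()).to_numpy()
        if tok == "element":
            vals = [v.upper() for v in collect_values()]
            return atoms["element"].str.upper().isin(vals).to_numpy()
        if tok == "resid":
            m = np.zeros(len(atoms), dtype=bool)
            rid = atoms["residue_id"].to_numpy()
            for v in collect_values():
                if ":" in v:
                    lo, hi = v.split(":")
                    m |= (rid >= int(lo)) & (rid <= int(hi))
                else:
                    m |= rid == int(v)
            return m
        raise SelectionError(f"unknown token {tok!r} in {expression!r}")

    mask = parse_expr()
    if pos != len(tokens):
        raise SelectionError(f"trailing tokens after position {pos} in {expression!r}")
    return mask


@dataclass
class PoreAlignment:
    """Rigid transform that maps the reference frame onto the pore-axis frame.

    ``rotation`` has det +1; applying ``rotation @ x + translation`` to the
    reference frame places the SF centroid at the origin with the principal
    pore axis along z. ``z_orientation`` is +1 when the extracellular side
    points toward +z.
    """

    rotation: np.ndarray
    translation: np.ndarray
    sf_selection: SelectionSpec
    z_orientation: int = +1

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise AlignmentError("rotation must be proper (det = +1)")


@dataclass
class FrameSeries:
    """Time-ordered particle coordinates with a per-frame orthorhombic box."""

    structure: Structure
    times: np.ndarray          # (n_frames,) ps, strictly increasing
    positions: np.ndarray      # (n_frames, n_atoms, 3) Å
    box: np.ndarray            # (n_frames, 3) Å
    alignment: PoreAlignment | None = None
    ground_truth: "object | None" = field(default=None, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.times)
        if self.positions.shape != (n, self.structure.n_atoms, 3):
            raise TopologyError(
                f"positions shape {self.positions.shape} inconsistent with "
                f"{n} frames x {self.structure.n_atoms} atoms"
            )
        if self.box.shape != (n, 3):
            raise TopologyError(f"box shape {self.box.shape} != ({n}, 3)")
        if np.any(self.box <= 0):
            raise FormatError("all box edges must be positive")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.structure.n_atoms


# ---------------------------------------------------------------------------
# Topology / trajectory I/O (standard formats via MDAnalysis)
# ---------------------------------------------------------------------------


def _atoms_dataframe_from_universe(u) -> pd.DataFrame:
    import MDAnalysis as mda  # noqa: F401

    n = len(u.atoms)
    names = [str(x) for x in u.atoms.names]
    try:
        resnames = [str(x) for x in u.atoms.resnames]
    except Exception:
        resnames = ["UNK"] * n
    try:
        resids = [int(x) for x in u.atoms.resids]
    except Exception:
        resids = [1] * n
    chain = [""] * n
    for attr in ("chainIDs", "segids"):
        try:
            chain = [str(x) for x in getattr(u.atoms, attr)]
            break
        except Exception:
            continue
    try:
        elements = [str(x).upper() for x in u.atoms.elements]
    except Exception:
        elements = [guess_element(nm, rn) for nm, rn in zip(names, resnames)]
    try:
        charges = np.asarray(u.atoms.charges, dtype=float)
    except Exception:
        charges = np.full(n, np.nan)

    vdw = np.empty(n)
    unknown: list[str] = []
    for i, (nm, el) in enumerate(zip(names, elements)):
        r = assign_vdw_radius(nm, el)
        if r < 0:
            unknown.append(nm)
            r = DEFAULT_VDW
        vdw[i] = r
    if unknown:
        msg = (
            f"no vdW radius for atom name(s) {sorted(set(unknown))[:8]}; "
            f"defaulting to {DEFAULT_VDW} Å"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=3)

    masses = np.array(
        [MASS_BY_ELEMENT.get(el, 0.0) for el in elements], dtype=float
    )
    try:
        m = np.asarray(u.atoms.masses, dtype=float)
        masses = np.where(m > 0, m, masses)
    except Exception:
        pass

    return pd.DataFrame(
        {
            "atom_id": np.arange(1, n + 1, dtype=int),
            "atom_name": names,
            "element": elements,
            "residue_name": resnames,
            "residue_id": resids,
            "chain_id": chain,
            "vdw_radius": vdw,
            "partial_charge": charges,
            "mass": masses,
        }
    )


def _check_orthorhombic(dimensions, frame: int) -> np.ndarray:
    if dimensions is None or np.all(np.asarray(dimensions)[:3] == 0):
        raise FormatError(f"frame {frame}: no box information")
    dims = np.asarray(dimensions, dtype=float)
    if np.any(np.abs(dims[3:6] - 90.0) > 1e-3):
        raise FormatError(
            f"frame {frame}: triclinic box (angles {dims[3:6]}) is not supported; "
            "orthorhombic boxes only"
        )
    return dims[:3].copy()


def load_structure(topology_path: str | Path) -> Structure:
    """Read a PDB or GRO file into a :class:`Structure` (coordinates in Å)."""
    import MDAnalysis as mda

    path = Path(topology_path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:
        raise FormatError(f"could not read topology {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise EmptyInputError(f"{path} contains zero atoms")
    atoms = _atoms_dataframe_from_universe(u)
    box = None
    if u.dimensions is not None and np.any(np.asarray(u.dimensions)[:3] > 0):
        box = _check_orthorhombic(u.dimensions, 0)
    return Structure(atoms=atoms, positions=u.atoms.positions.astype(float), box=box)


def load_trajectory(structure: Structure, coords_path: str | Path) -> FrameSeries:
    """Read XTC/DCD/TRR or the internal HDF5 format into a :class:`FrameSeries`."""
    import MDAnalysis as mda

    path = Path(coords_path)
    if not path.exists():
        raise TrajectoryIOError(f"no such file: {path}")
    if path.suffix.lower() in {".h5", ".hdf5"}:
        frames = load_frames_h5(path)
        if frames.n_atoms != structure.n_atoms:
            raise TopologyError(
                f"trajectory has {frames.n_atoms} atoms, structure has "
                f"{structure.n_atoms}"
            )
        return FrameSeries(
            structure=structure,
            times=frames.times,
            positions=frames.positions,
            box=frames.box,
            ground_truth=frames.ground_truth,
        )

    u = mda.Universe.empty(structure.n_atoms, trajectory=True)
    try:
        u.load_new(str(path))
    except Exception as exc:
        msg = str(exc)
        if "atoms" in msg or "natoms" in msg or "shape" in msg:
            raise TopologyError(
                f"atom count mismatch between structure ({structure.n_atoms} "
                f"atoms) and {path}: {exc}"
            ) from exc
        raise TrajectoryIOError(f"could not open trajectory {path}: {exc}") from exc

    times, boxes, positions = [], [], []
    i = 0
    try:
        for ts in u.trajectory:
            boxes.append(_check_orthorhombic(ts.dimensions, i))
            times.append(float(ts.time))
            positions.append(ts.positions.astype(float).copy())
            i += 1
    except FormatError:
        raise
    except Exception as exc:
        raise TrajectoryIOError(
            f"error reading {path} at frame {i}: {exc}", frame=i
        ) from exc
    if not positions:
        raise TrajectoryIOError(f"{path} contains no frames", frame=0)
    times_arr = np.asarray(times)
    if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
        logger.warning("trajectory times not strictly increasing; using frame index as ps")
        times_arr = np.arange(len(times_arr), dtype=float)
    return FrameSeries(
        structure=structure,
        times=times_arr,
        positions=np.stack(positions),
        box=np.stack(boxes),
    )


# ---------------------------------------------------------------------------
# Internal synthetic trajectory format (HDF5).
#
# Layout (stable, version attribute checked on read):
#   attrs:  format="poreflow-trajectory", version=1,
#           ground_truth=<JSON string, optional>
#   /times      (n_frames,)           float64, ps
#   /box        (n_frames, 3)         float64, Å
#   /positions  (n_frames, n_atoms, 3) float64, Å
#   /atoms/<column>  one dataset per atom-table column
# ---------------------------------------------------------------------------

_H5_FORMAT = "poreflow-trajectory"
_H5_VERSION = 1
_STR_COLUMNS = ("atom_name", "element", "residue_name", "chain_id")


def save_frames_h5(frames: FrameSeries, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _H5_FORMAT
        f.attrs["version"] = _H5_VERSION
        if frames.ground_truth is not None:
            f.attrs["ground_truth"] = json.dumps(
                frames.ground_truth.to_dict()
                if hasattr(frames.ground_truth, "to_dict")
                else frames.ground_truth
            )
        if frames.alignment is not None:
            f.attrs["alignment"] = json.dumps({
                "rotation": frames.alignment.rotation.tolist(),
                "translation": frames.alignment.translation.tolist(),
                "sf_selection": frames.alignment.sf_selection.expression,
                "z_orientation": frames.alignment.z_orientation,
            })
        f.create_dataset("times", data=frames.times)
        f.create_dataset("box", data=frames.box)
        f.create_dataset("positions", data=frames.positions)
        g = f.create_group("atoms")
        for col in ATOM_COLUMNS:
            data = frames.structure.atoms[col].to_numpy()
            if col in _STR_COLUMNS:
                data = np.array([str(x).encode() for x in data])
            g.create_dataset(col, data=data)


def load_frames_h5(path: str | Path) -> FrameSeries:
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except Exception as exc:
        raise FormatError(f"could not open HDF5 trajectory {path}: {exc}") from exc
    with f:
        if f.attrs.get("format") != _H5_FORMAT:
            raise FormatError(f"{path} is not a {_H5_FORMAT} file")
        cols = {}
        for col in ATOM_COLUMNS:
            data = f["atoms"][col][...]
            if col in _STR_COLUMNS:
                data = np.array([x.decode() for x in data])
            cols[col] = data
        atoms = pd.DataFrame(cols)
        atoms["atom_id"] = atoms["atom_id"].astype(int)
        atoms["residue_id"] = atoms["residue_id"].astype(int)
        positions = f["positions"][...]
        structure = Structure(atoms=atoms, positions=positions[0].copy())
        gt = None
        if "ground_truth" in f.attrs:
            from .synth import GroundTruth

            gt = GroundTruth.from_dict(json.loads(f.attrs["ground_truth"]))
        alignment = None
        if "alignment" in f.attrs:
            a = json.loads(f.attrs["alignment"])
            alignment = PoreAlignment(
                rotation=np.asarray(a["rotation"]),
                translation=np.asarray(a["translation"]),
                sf_selection=SelectionSpec(a["sf_selection"]),
                z_orientation=int(a["z_orientation"]),
            )
        return FrameSeries(
            structure=structure,
            times=f["times"][...],
            positions=positions,
            box=f["box"][...],
            alignment=alignment,
            ground_truth=gt,
        )


def export_trajectory(frames: FrameSeries, path: str | Path) -> None:
    """Write frames to the internal HDF5 format or XTC/DCD/TRR/PDB."""
    import MDAnalysis as mda

    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        save_frames_h5(frames, path)
        return
    u = mda.Universe.empty(frames.n_atoms, trajectory=True)
    u.add_TopologyAttr("names", list(frames.structure.atoms["atom_name"]))
    u.add_TopologyAttr("resnames", [str(frames.structure.atoms["residue_name"].iloc[0])])
    with mda.Writer(str(path), n_atoms=frames.n_atoms) as w:
        for i in range(frames.n_frames):
            u.atoms.positions = frames.positions[i].astype(np.float32)
            u.trajectory.ts.dimensions = [*frames.box[i], 90.0, 90.0, 90.0]
            u.trajectory.ts.time = frames.times[i]
            w.write(u.atoms)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-frame structure as PDB or GRO."""
    import MDAnalysis as mda

    path = Path(path)
    a = structure.atoms
    n = structure.n_atoms
    resids_in = a["residue_id"].to_numpy()
    # compress to contiguous residue indices for the Universe factory
    uniq, residx = np.unique(resids_in, return_inverse=True)
    u = mda.Universe.empty(
        n, n_residues=len(uniq), atom_resindex=residx, trajectory=True
    )
    u.add_TopologyAttr("names", list(a["atom_name"]))
    resnames = []
    seen = {}
    for rid, rn in zip(resids_in, a["residue_name"]):
        if rid not in seen:
            seen[rid] = rn
    resnames = [seen[rid] for rid in uniq]
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", [int(x) for x in uniq])
    u.atoms.positions = structure.positions.astype(np.float32)
    if structure.box is not None:
        u.dimensions = [*structure.box, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# Superposition and pore-axis alignment
# ---------------------------------------------------------------------------


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform: returns (R, t) with R @ p + t ≈ q.

    The optimal translation maps the centroid of P exactly onto the
    centroid of Q; R is the proper rotation minimising the RMSD.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    return R, t


def minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest proper rotation taking unit vector a onto unit vector b."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s2 = float(np.dot(v, v))
    if s2 < 1e-24:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis perpendicular to a
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s2)


def align_to_pore_axis(
    frames: FrameSeries,
    sf_selection: SelectionSpec,
    reference_frame: int = 0,
    fit_selection: SelectionSpec | None = None,
    z_orientation: int = +1,
) -> tuple[FrameSeries, PoreAlignment]:
    """Superpose every frame on a reference and put the pore axis on z.

    Each frame is rigid-body superposed (least squares on ``fit_selection``,
    defaulting to the SF selection) onto ``reference_frame``; the whole
    series is then rotated so the principal pore axis — the direction of
    least spatial extent of the SF ring — lies on z, and translated so the
    SF centroid sits at the origin. ``z_orientation = -1`` flips the axis
    when the extracellular side points toward -z in the input.
    """
    sf_idx = sf_selection.resolve(frames.structure)
    if len(sf_idx) == 0:
        raise SelectionError(f"SF selection {sf_selection.expression!r} is empty")
    if len(sf_idx) < 8:
        logger.warning(
            "SF selection resolves to only %d atoms; axis estimate may be poor",
            len(sf_idx),
        )
    fit_sel = fit_selection or sf_selection
    fit_idx = fit_sel.resolve(frames.structure)
    if len(fit_idx) < 3:
        raise SelectionError("fit selection must resolve to at least 3 atoms")

    ref = frames.positions[reference_frame]
    ref_fit = ref[fit_idx]

    # principal pore axis: eigenvector of smallest covariance eigenvalue of
    # the SF ring (the ring is wide in-plane, thin along the pore axis)
    sf_ref = ref[sf_idx]
    cov = np.cov((sf_ref - sf_ref.mean(axis=0)).T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, 0]
    if axis[2] < 0:
        axis = -axis
    axis = axis * (1 if z_orientation >= 0 else -1)
    R0 = minimal_rotation(axis, np.array([0.0, 0.0, 1.0]))
    c_ref = sf_ref.mean(axis=0)

    out = np.empty_like(frames.positions)
    for i in range(frames.n_frames):
        Rf, tf = kabsch(frames.positions[i][fit_idx], ref_fit)
        moved = frames.positions[i] @ Rf.T + tf
        out[i] = (moved - c_ref) @ R0.T

    alignment = PoreAlignment(
        rotation=R0,
        translation=-R0 @ c_ref,
        sf_selection=sf_selection,
        z_orientation=+1 if z_orientation >= 0 else -1,
    )
    aligned = FrameSeries(
        structure=Structure(
            atoms=frames.structure.atoms.copy(),
            positions=out[reference_frame].copy(),
            box=frames.structure.box,
        ),
        times=frames.times.copy(),
        positions=out,
        box=frames.box.copy(),
        alignment=alignment,
        ground_truth=frames.ground_truth,
    )
    return aligned, alignment


def rmsd(P: np.ndarray, Q: np.ndarray, superpose: bool = True) -> float:
    """RMSD in Å between two coordinate sets, optionally after superposition."""
    if superpose:
        R, t = kabsch(P, Q)
        P = P @ R.T + t
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def build_structure(
    names: list[str],
    resnames: list[str],
    resids: list[int],
    positions: np.ndarray,
    charges: np.ndarray | None = None,
    chain: str = "",
    box: np.ndarray | None = None,
) -> Structure:
    """Convenience factory for synthetic structures."""
    n = len(names)
    elements = [guess_element(nm, rn) for nm, rn in zip(names, resnames)]
    vdw = []
    for nm, el in zip(names, elements):
        r = assign_vdw_radius(nm, el)
        vdw.append(DEFAULT_VDW if r < 0 else r)
    atoms = pd.DataFrame(
        {
            "atom_id": np.arange(1, n + 1, dtype=int),
            "atom_name": names,
            "element": elements,
            "residue_name": resnames,
            "residue_id": np.asarray(resids, dtype=int),
            "chain_id": [chain] * n,
            "vdw_radius": np.asarray(vdw, dtype=float),
            "partial_charge": np.zeros(n) if charges is None else np.asarray(charges, float),
            "mass": [MASS_BY_ELEMENT.get(el, 0.0) for el in elements],
        }
    )
    return Structure(atoms=atoms, positions=np.asarray(positions, float), box=box)
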