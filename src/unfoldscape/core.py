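"""Trajectory and topology data model plus readers/writers.

Coordinates are always in Angstroms, times in nanoseconds, energies in
kcal/mol; unit conversion happens only at the I/O boundary (mdtraj works
in nanometres internally).

Residue and atom indexing is 0-based internally; the residue numbering of
the source PDB is retained on :class:`Topology` so user-facing reports
(e.g. per-mutant phi tables) can use the original numbering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import mdtraj as md
import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "Trajectory",
    "load_structure",
    "load_trajectory",
    "write_trajectory",
    "write_table",
    "read_table",
]

_NM_TO_ANG = 10.0


@dataclass
class Topology:
    """Minimal Calpha-aware topology.

    Attributes
    ----------
    atom_names : list of str
        PDB atom names, e.g. ``"CA"``.
    residue_index_per_atom : ndarray of int
        0-based residue index of each atom; non-decreasing.
    residue_names : list of str
        One name per residue.
    masses : ndarray of float
        Atomic masses in amu, all positive.
    calpha_mask : ndarray of bool
        Selects exactly one CA atom per residue that has one.
    pdb_residue_numbers : ndarray of int
        Original (1-based) residue numbers from the source file, one per
        residue, for reporting.
    """

    atom_names: list[str]
    residue_index_per_atom: np.ndarray
    residue_names: list[str]
    masses: np.ndarray
    calpha_mask: np.ndarray
    pdb_residue_numbers: np.ndarray = field(default=None)

    def __post_init__(self):
        self.residue_index_per_atom = np.asarray(self.residue_index_per_atom, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        self.calpha_mask = np.asarray(self.calpha_mask, dtype=bool)
        if self.pdb_residue_numbers is None:
            self.pdb_residue_numbers = np.arange(1, self.n_residues + 1)
        else:
            self.pdb_residue_numbers = np.asarray(self.pdb_residue_numbers, dtype=int)
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    def validate(self) -> None:
        if np.any(np.diff(self.residue_index_per_atom) < 0):
            raise ValueError("residue indices must be non-decreasing along the atom list")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if len(self.residue_index_per_atom) != self.n_atoms or len(self.masses) != self.n_atoms:
            raise ValueError("per-atom arrays must match the atom count")
        if len(self.calpha_mask) != self.n_atoms:
            raise ValueError("calpha_mask must have one entry per atom")
        # at most one CA per residue
        ca_res = self.residue_index_per_atom[self.calpha_mask]
        if len(np.unique(ca_res)) != len(ca_res):
            raise ValueError("calpha_mask selects more than one atom in some residue")

    def calpha_residues(self) -> np.ndarray:
        """0-based residue indices that have a CA atom, in chain order."""
        return self.residue_index_per_atom[self.calpha_mask]

    def to_mdtraj(self) -> md.Topology:
        top = md.Topology()
        chain = top.add_chain()
        res_objs = []
        for i, rname in enumerate(self.residue_names):
            num = int(self.pdb_residue_numbers[i])
            res_objs.append(top.add_residue(rname, chain, resSeq=num))
        for name, ridx in zip(self.atom_names, self.residue_index_per_atom):
            try:
                elem = md.element.Element.getBySymbol(name.strip()[0])
            except KeyError:
                elem = md.element.carbon
            top.add_atom(name, elem, res_objs[int(ridx)])
        return top

    @classmethod
    def from_mdtraj(cls, top: md.Topology) -> "Topology":
        atom_names = [a.name for a in top.atoms]
        residue_index = np.array([a.residue.index for a in top.atoms], dtype=int)
        residue_names = [r.name for r in top.residues]
        pdb_numbers = np.array([r.resSeq for r in top.residues], dtype=int)
        masses = np.array(
            [a.element.mass if a.element is not None and a.element.mass > 0 else 12.011
             for a in top.atoms], dtype=float)
        calpha = np.array([a.name == "CA" for a in top.atoms], dtype=bool)
        return cls(atom_names, residue_index, residue_names, masses, calpha, pdb_numbers)


@dataclass
class Trajectory:
    """Ordered frames of coordinates with a topology and frame spacing.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstroms;
    ``frame_interval`` is the time between saved frames in ns.
    """

    topology: Topology
    coords: np.ndarray
    frame_interval: float = 1.0
    origin_label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def stride(self, step: int) -> "Trajectory":
        if step < 1:
            raise ValueError("stride must be a positive integer")
        out = self.coords[::step]
        if out.shape[0] == 0:
            raise ValueError("zero frames after stride")
        return Trajectory(self.topology, out.copy(), self.frame_interval * step,
                          self.origin_label)

    def calpha_coords(self) -> np.ndarray:
        return self.coords[:, self.topology.calpha_mask, :]


def load_structure(path, model: int = 0):
    """Read a PDB structure; return ``(Topology, coords)`` for one model.

    Parameters
    ----------
    path : str or Path
        PDB file with at least one model.
    model : int
        0-based model index (default first model; NMR ensembles often
        deposit several near-identical models).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    t = md.load(str(path))
    if t.n_frames == 0:
        raise ValueError(f"no models found in {path}")
    if not (0 <= model < t.n_frames):
        raise IndexError(f"model {model} out of range (file has {t.n_frames} models)")
    top = Topology.from_mdtraj(t.topology)
    if not np.any(top.calpha_mask):
        raise ValueError(f"no CA atoms in {path}")
    nums = top.pdb_residue_numbers
    if np.any(np.diff(nums) > 1):
        warnings.warn(f"chain discontinuity in residue numbering of {path}", stacklevel=2)
    coords = np.asarray(t.xyz[model], dtype=float) * _NM_TO_ANG
    return top, coords


def load_trajectory(traj_path, topology: Topology, stride: int = 1,
                    frame_interval: float = 1.0) -> Trajectory:
    """Read a trajectory (multi-model PDB, DCD or XTC) against a topology.

    ``frame_interval`` is the spacing of the *saved* frames in ns; the
    stored trajectory's interval is scaled by ``stride``.
    """
    traj_path = Path(traj_path)
    if not traj_path.exists():
        raise FileNotFoundError(str(traj_path))
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    suffix = traj_path.suffix.lower()
    if suffix == ".pdb":
        t = md.load(str(traj_path))
    else:
        t = md.load(str(traj_path), top=topology.to_mdtraj())
    if t.n_atoms != topology.n_atoms:
        raise ValueError(
            f"trajectory has {t.n_atoms} atoms but topology has {topology.n_atoms}")
    coords = np.asarray(t.xyz[::stride], dtype=float) * _NM_TO_ANG
    if coords.shape[0] == 0:
        raise ValueError("zero frames after stride")
    return Trajectory(topology, coords, frame_interval * stride, str(traj_path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-model PDB, DCD or XTC (by extension)."""
    path = Path(path)
    t = md.Trajectory(traj.coords / _NM_TO_ANG, traj.topology.to_mdtraj())
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        t.save_pdb(str(path))
    elif suffix == ".dcd":
        t.save_dcd(str(path))
    elif suffix == ".xtc":
        t.save_xtc(str(path))
    else:
        raise ValueError(f"unsupported trajectory format: {suffix}")


def write_table(records, path, format: str = "csv") -> None:
    """Write labelled rows losslessly (>= 12 significant digits).

    ``records`` is a DataFrame or a list of dicts with identical keys.
    NaN is serialized as an explicit null token (``NA`` in CSV, ``null``
    in JSON) and re-read as missing.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    path = Path(path)
    if format == "csv":
        records.to_csv(path, index=False, na_rep="NA", float_format="%.17g")
    elif format == "json":
        rows = [{k: (None if isinstance(v, float) and np.isnan(v) else v)
                 for k, v in row.items()}
                for row in records.to_dict(orient="records")]
        payload = {"columns": list(records.columns), "rows": rows}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, allow_nan=False, default=float)
    else:
        raise ValueError(f"unsupported table format: {format}")


def read_table(path, format: str = "csv") -> pd.DataFrame:
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path)
    elif format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return pd.DataFrame(payload["rows"], columns=payload["columns"])
    raise ValueError(f"unsupported table format: {format}")
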