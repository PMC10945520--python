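"""Data model and file I/O for the analysis pipeline.

The in-memory containers are deliberately small: a flat per-atom
:class:`Topology`, a dense-coordinate :class:`Trajectory`, a tidy
:class:`StateLabelTable` mapping frames to discrete conformational-state
labels, and a :class:`VolumetricGrid` for occupancy densities.  File parsing
and writing is delegated to MDAnalysis (PDB/GRO/XTC/DCD), GridDataFormats
(OpenDX) and mrcfile (MRC/CCP4); this module only adapts between those
libraries and the containers above.

Conventions: lengths in Å, times in ns, frame indices 0-based, residue
numbers taken verbatim from input files, grids stored as ``values[ix, iy, iz]``
with an isotropic voxel spacing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: residue names treated as lipids unless the caller overrides the list
DEFAULT_LIPID_RESNAMES = frozenset(
    {"POPC", "POPE", "POPG", "POPS", "DPPC", "DOPC", "DMPC", "CHOL", "LIP"}
)

#: fallback van der Waals radii by element symbol (Å)
VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "P": 1.8, "S": 1.8}
DEFAULT_RADIUS = 1.7

UNASSIGNED = "unassigned"


class FormatError(ValueError):
    """Raised when an input file cannot be parsed or is inconsistent."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Topology:
    """Flat per-atom description of the system.

    Arrays are aligned per atom.  ``kind`` is ``"protein"`` or ``"lipid"``;
    every lipid atom carries a non-negative ``lipid_id`` identifying its
    molecule, protein atoms carry ``-1``.
    """

    resid: np.ndarray
    resname: np.ndarray
    chain: np.ndarray
    name: np.ndarray
    kind: np.ndarray
    lipid_id: np.ndarray
    radius: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.resid)
        for f in ("resname", "chain", "name", "kind", "lipid_id", "radius"):
            if len(getattr(self, f)) != n:
                raise ValueError(f"topology field {f!r} has wrong length")
        if np.any(self.radius <= 0):
            raise ValueError("van der Waals radii must be positive")
        lip = self.kind == "lipid"
        if np.any(self.lipid_id[lip] < 0):
            raise ValueError("every lipid atom needs a lipid molecule id")

    @property
    def n_atoms(self) -> int:
        return len(self.resid)

    @property
    def protein_mask(self) -> np.ndarray:
        return self.kind == "protein"

    @property
    def lipid_mask(self) -> np.ndarray:
        return self.kind == "lipid"

    @property
    def lipid_ids(self) -> np.ndarray:
        """Sorted unique lipid molecule ids."""
        return np.unique(self.lipid_id[self.lipid_mask])

    @property
    def n_lipids(self) -> int:
        return len(self.lipid_ids)

    def protein_residues(self) -> list[tuple[str, int, str, np.ndarray]]:
        """Protein residues as ``(chain, resid, resname, atom_indices)``.

        Order follows first appearance in the atom list.
        """
        out: list[tuple[str, int, str, np.ndarray]] = []
        idx = np.flatnonzero(self.protein_mask)
        if idx.size == 0:
            return out
        keys = list(zip(self.chain[idx], self.resid[idx]))
        seen: dict[tuple[str, int], list[int]] = {}
        order: list[tuple[str, int]] = []
        for i, key in zip(idx, keys):
            if key not in seen:
                seen[key] = []
                order.append(key)
            seen[key].append(int(i))
        for chain, resid in order:
            ai = np.asarray(seen[(chain, resid)])
            out.append((chain, int(resid), str(self.resname[ai[0]]), ai))
        return out

    def lipid_atom_indices(self) -> dict[int, np.ndarray]:
        """Atom indices per lipid molecule id."""
        idx = np.flatnonzero(self.lipid_mask)
        ids = self.lipid_id[idx]
        return {int(l): idx[ids == l] for l in np.unique(ids)}

    def residue_atoms(self, chain: str, resid: int) -> np.ndarray:
        ai = np.flatnonzero((self.chain == chain) & (self.resid == resid))
        if ai.size == 0:
            raise KeyError(f"residue {chain}/{resid} not in topology")
        return ai


@dataclass
class Trajectory:
    """Ordered coordinate frames for one simulation.

    ``coords`` are wrapped into the periodic box; ``unwrapped`` (optional)
    carries the continuous-image coordinates needed for displacement
    statistics.  ``box`` holds per-frame orthorhombic box lengths.
    """

    traj_id: str
    coords: np.ndarray  # (n_frames, n_atoms, 3) Å
    box: np.ndarray  # (n_frames, 3) Å
    dt: float  # ns per frame
    condition: str = ""
    unwrapped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.box.shape != (self.coords.shape[0], 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.unwrapped is not None and self.unwrapped.shape != self.coords.shape:
            raise ValueError("unwrapped coords must match coords shape")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def mda_box(self, frame: int) -> np.ndarray:
        """Box in MDAnalysis ``[lx, ly, lz, 90, 90, 90]`` convention."""
        return np.array([*self.box[frame], 90.0, 90.0, 90.0])


@dataclass
class StateLabelTable:
    """Mapping ``(traj_id, frame) -> state label``.

    Frames absent from the table are implicitly ``"unassigned"``.
    """

    table: pd.DataFrame  # columns: traj_id, frame, state
    vocabulary: tuple[str, ...]

    def __post_init__(self) -> None:
        required = {"traj_id", "frame", "state"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"label table needs columns {sorted(required)}")
        dup = self.table.duplicated(subset=["traj_id", "frame"])
        if dup.any():
            bad = self.table.loc[dup, ["traj_id", "frame"]].to_records(index=False)
            raise ValueError(f"duplicate (traj_id, frame) rows: {list(bad)[:5]}")
        unknown = set(self.table["state"]) - set(self.vocabulary) - {UNASSIGNED}
        if unknown:
            raise ValueError(f"unknown state labels: {sorted(unknown)}")

    def labels_for(self, traj_id: str, n_frames: int) -> np.ndarray:
        """Per-frame label array for one trajectory (missing -> unassigned)."""
        out = np.full(n_frames, UNASSIGNED, dtype=object)
        sub = self.table[self.table["traj_id"] == traj_id]
        frames = sub["frame"].to_numpy(dtype=int)
        if frames.size and (frames.min() < 0 or frames.max() >= n_frames):
            raise ValueError(
                f"label frame index out of range for trajectory {traj_id!r}"
            )
        out[frames] = sub["state"].to_numpy()
        return out

    def frames_with(self, traj_id: str, state: str) -> np.ndarray:
        sub = self.table[
            (self.table["traj_id"] == traj_id) & (self.table["state"] == state)
        ]
        return np.sort(sub["frame"].to_numpy(dtype=int))


@dataclass
class VolumetricGrid:
    """Regular isotropic 3D grid; ``values[ix, iy, iz]``, x fastest index."""

    origin: np.ndarray  # (3,) Å, position of voxel (0, 0, 0) center
    spacing: float  # Å
    values: np.ndarray  # (nx, ny, nz)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a non-empty 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_geometry(self, other: "VolumetricGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing - other.spacing) <= tol
            and bool(np.all(np.abs(self.origin - other.origin) <= tol))
        )

    def copy(self) -> "VolumetricGrid":
        return VolumetricGrid(
            self.origin.copy(), self.spacing, self.values.copy(), dict(self.metadata)
        )


# ---------------------------------------------------------------------------
# MDAnalysis adapters
# ---------------------------------------------------------------------------


def _element_radius(name: str) -> float:
    sym = name.strip()[:1].upper()
    return VDW_RADII.get(sym, DEFAULT_RADIUS)


def _universe_from_file(path: str | Path, topology_path: str | Path | None = None):
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"empty file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if topology_path is not None:
                return mda.Universe(str(topology_path), str(path))
            return mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - surface as one error type
        raise FormatError(f"could not parse {path}: {exc}") from exc


def read_topology(
    path: str | Path,
    lipid_resnames: set[str] | frozenset[str] = DEFAULT_LIPID_RESNAMES,
    radii: dict[str, float] | None = None,
) -> Topology:
    """Read a PDB or GRO file into a :class:`Topology`.

    Molecule kind is inferred from the residue name: names in
    ``lipid_resnames`` become lipids (each residue one lipid molecule, ids
    assigned in file order), everything else is treated as protein.  ``radii``
    optionally maps atom names to van der Waals radii; unknown names fall back
    to an element guess from the first character.
    """
    u = _universe_from_file(path)
    atoms = u.atoms
    n = len(atoms)
    if n == 0:
        raise FormatError(f"no atoms in {path}")
    resnames = atoms.resnames.astype(object)
    resids = atoms.resids.astype(int)
    names = atoms.names.astype(object)
    try:
        chains = atoms.chainIDs.astype(object)
    except Exception:  # GRO files carry no chain record
        chains = np.array([""] * n, dtype=object)

    kind = np.empty(n, dtype=object)
    lipid_id = np.full(n, -1, dtype=int)
    unknown: set[str] = set()
    is_lipid_res = np.array([rn in lipid_resnames for rn in resnames])
    kind[:] = "protein"
    kind[is_lipid_res] = "lipid"
    # one lipid molecule per lipid residue, numbered in order of appearance
    next_id = 0
    current = None
    for i in np.flatnonzero(is_lipid_res):
        key = (chains[i], resids[i])
        if key != current:
            current = key
            lipid_id[i] = next_id
            next_id += 1
        else:
            lipid_id[i] = next_id - 1
    for rn in set(resnames[~is_lipid_res]):
        if rn not in _KNOWN_PROTEIN_RESNAMES and rn not in lipid_resnames:
            unknown.add(rn)
    if unknown:
        logger.warning("unrecognised residue names treated as protein: %s",
                       sorted(unknown))

    radius = np.array(
        [
            (radii.get(str(nm), _element_radius(str(nm))) if radii else
             _element_radius(str(nm)))
            for nm in names
        ]
    )
    return Topology(resids, resnames, chains, names, kind, lipid_id, radius)


_KNOWN_PROTEIN_RESNAMES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP
    TYR VAL SCF GAT STE""".split()
)


def read_trajectory(
    path: str | Path,
    topology: Topology,
    topology_path: str | Path | None = None,
    dt: float | None = None,
    traj_id: str | None = None,
    condition: str = "",
) -> Trajectory:
    """Read a multi-model PDB, XTC or DCD into a :class:`Trajectory`.

    XTC/DCD need ``topology_path`` (a PDB/GRO of the same system).  ``dt`` in
    ns overrides whatever the file metadata claims (PDB models carry none).
    """
    u = _universe_from_file(path, topology_path)
    if len(u.atoms) != topology.n_atoms:
        raise FormatError(
            f"atom count mismatch: file has {len(u.atoms)}, "
            f"topology has {topology.n_atoms}"
        )
    coords = []
    boxes = []
    for ts in u.trajectory:
        coords.append(ts.positions.astype(float).copy())
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            boxes.append(np.zeros(3))
        else:
            boxes.append(np.asarray(ts.dimensions[:3], dtype=float))
    if dt is None:
        dt = float(getattr(u.trajectory, "dt", 1.0) or 1.0) / 1000.0  # ps -> ns
        if dt <= 0:
            dt = 1.0
    return Trajectory(
        traj_id=traj_id or Path(path).stem,
        coords=np.asarray(coords),
        box=np.asarray(boxes),
        dt=dt,
        condition=condition,
    )


def _build_universe(topology: Topology, coords: np.ndarray, box: np.ndarray):
    """MDAnalysis Universe for writing (single frame loaded)."""
    import MDAnalysis as mda

    n = topology.n_atoms
    # contiguous residue blocks in atom order
    res_index = np.zeros(n, dtype=int)
    res_keys: list[tuple[str, int, str]] = []
    current = None
    for i in range(n):
        key = (str(topology.chain[i]), int(topology.resid[i]),
               str(topology.resname[i]))
        if key != current:
            current = key
            res_keys.append(key)
        res_index[i] = len(res_keys) - 1
    seg_names: list[str] = []
    res_seg = np.zeros(len(res_keys), dtype=int)
    for ri, (chain, _, _) in enumerate(res_keys):
        label = chain or "X"
        if label not in seg_names:
            seg_names.append(label)
        res_seg[ri] = seg_names.index(label)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=n,
            n_residues=len(res_keys),
            n_segments=len(seg_names),
            atom_resindex=res_index,
            residue_segindex=res_seg,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [str(x) for x in topology.name])
        u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.add_TopologyAttr("segids", seg_names)
        u.add_TopologyAttr("chainIDs",
                           [str(topology.chain[i]) or "X" for i in range(n)])
        u.add_TopologyAttr("tempfactors", np.zeros(n))
        u.add_TopologyAttr("occupancies", np.ones(n))
        u.atoms.positions = coords
        u.dimensions = [*box, 90.0, 90.0, 90.0]
    return u


def write_topology(topology: Topology, coords: np.ndarray,
                   box: np.ndarray, path: str | Path) -> None:
    """Write a single-frame PDB or GRO snapshot."""
    u = _build_universe(topology, coords, box)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, topology: Topology,
                     path: str | Path) -> None:
    """Write a trajectory as multi-model PDB, XTC or DCD (by extension)."""
    import MDAnalysis as mda

    u = _build_universe(topology, traj.coords[0], traj.box[0])
    path = str(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=topology.n_atoms) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f]
                u.dimensions = [*traj.box[f], 90.0, 90.0, 90.0]
                w.write(u.atoms)


def write_bfactor_pdb(
    topology: Topology,
    coords: np.ndarray,
    per_residue_scalar: dict[tuple[str, int], float],
    path: str | Path,
    box: np.ndarray | None = None,
) -> None:
    """Write a PDB whose B-factor column carries a per-residue scalar.

    Used to project per-residue statistics (e.g. mean contact durations) onto
    a structure for visualisation.  Missing residues get 0 with a warning;
    values are clipped to the PDB-representable [0, 999.99].
    """
    if box is None:
        span = coords.max(axis=0) - coords.min(axis=0) + 10.0
        box = span
    u = _build_universe(topology, coords, box)
    b = np.zeros(topology.n_atoms)
    missing = []
    for chain, resid, _resname, ai in topology.protein_residues():
        key = (chain, resid)
        if key in per_residue_scalar:
            val = float(per_residue_scalar[key])
            if not 0.0 <= val <= 999.99:
                logger.warning("B-factor for %s/%s clipped from %g", chain,
                               resid, val)
            b[ai] = min(max(val, 0.0), 999.99)
        else:
            missing.append(key)
    if missing:
        logger.warning("no scalar for %d residues; B-factor set to 0",
                       len(missing))
    u.atoms.tempfactors = b
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def read_state_labels(
    path: str | Path, vocabulary: tuple[str, ...] | None = None
) -> StateLabelTable:
    """Read a TSV of per-frame state labels (columns traj_id, frame, state)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"traj_id": str})
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not parse label table {path}: {exc}") from exc
    required = {"traj_id", "frame", "state"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"label table {path} missing columns "
            f"{sorted(required - set(df.columns))}"
        )
    vocab = vocabulary or tuple(sorted(set(df["state"])))
    return StateLabelTable(df[["traj_id", "frame", "state"]].copy(), vocab)


def write_state_labels(labels: StateLabelTable, path: str | Path) -> None:
    labels.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# volumetric grids
# ---------------------------------------------------------------------------


def write_grid(grid: VolumetricGrid, path: str | Path,
               fmt: str | None = None) -> None:
    """Write a grid as OpenDX (.dx) or MRC/CCP4 (.mrc), inferred from suffix."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "dx":
        from gridData import Grid

        g = Grid(grid.values, origin=grid.origin,
                 delta=[grid.spacing] * 3)
        g.export(str(path), "DX")
    elif fmt in ("mrc", "ccp4", "map"):
        import mrcfile

        with mrcfile.new(str(path), overwrite=True) as m:
            # MRC stores data as (nz, ny, nx)
            m.set_data(np.ascontiguousarray(
                grid.values.T.astype("<f4")))
            m.voxel_size = grid.spacing
            m.header.origin.x = grid.origin[0]
            m.header.origin.y = grid.origin[1]
            m.header.origin.z = grid.origin[2]
    else:
        raise ValueError(f"unsupported grid format {fmt!r} (use dx or mrc)")


def read_grid(path: str | Path, fmt: str | None = None) -> VolumetricGrid:
    """Read an OpenDX or MRC grid written by :func:`write_grid`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "dx":
        from gridData import Grid

        try:
            g = Grid(str(path))
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"could not parse DX grid {path}: {exc}") from exc
        delta = np.asarray(g.delta)
        if delta.ndim == 2:
            delta = np.diag(delta)
        if not np.allclose(delta, delta[0]):
            raise FormatError("anisotropic grid spacing is not supported")
        return VolumetricGrid(np.asarray(g.origin), float(delta[0]),
                              np.asarray(g.grid))
    if fmt in ("mrc", "ccp4", "map"):
        import mrcfile

        try:
            with mrcfile.open(str(path)) as m:
                values = np.asarray(m.data, dtype=float).T.copy()
                vs = m.voxel_size
                spacing = float(vs.x)
                if not (np.isclose(vs.y, spacing) and np.isclose(vs.z, spacing)):
                    raise FormatError("anisotropic voxel size not supported")
                origin = np.array(
                    [m.header.origin.x, m.header.origin.y, m.header.origin.z],
                    dtype=float,
                )
        except FormatError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"could not parse MRC grid {path}: {exc}") from exc
        return VolumetricGrid(origin, spacing, values)
    raise ValueError(f"unsupported grid format {fmt!r} (use dx or mrc)")
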