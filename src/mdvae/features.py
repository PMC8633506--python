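"""Trajectory containers, I/O, alignment and MinMax featurization.

An MD trajectory enters as a reference-frame-aligned set of Cartesian
coordinates.  Each of the 3·M coordinate columns is scaled to [0, 1]
with the per-column minimum and maximum over frames,

    normed c_ik = (c_ik - min_c) / (max_c - min_c),

and the stored scaler inverts the map so that decoder outputs can be
turned back into ångström coordinates (values outside [0, 1] are
extrapolated linearly).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import kabsch_rotation

__all__ = [
    "AtomRecord",
    "TrajectoryEnsemble",
    "FeatureScaler",
    "FeatureMatrix",
    "SplitIndex",
    "read_trajectory",
    "write_trajectory",
    "select_atoms",
    "align_to_first_frame",
    "fit_transform",
    "inverse_transform",
    "stride_split",
]

_HYDROGEN_NAMES = ("H", "D")


@dataclass(frozen=True)
class AtomRecord:
    """Minimal per-atom metadata carried alongside coordinates."""

    name: str = "CA"
    resname: str = "GLY"
    resseq: int = 1
    chain: str = "A"
    element: str = "C"


@dataclass
class TrajectoryEnsemble:
    """Per-frame Cartesian coordinates (Å) plus atom metadata.

    ``coordinates`` has shape (n_frames, n_atoms, 3).
    """

    coordinates: np.ndarray
    atom_records: list[AtomRecord]
    frame_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinates must be (n_frames, n_atoms, 3), got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("coordinates contain NaN/Inf")
        if len(self.atom_records) != self.coordinates.shape[1]:
            raise ValueError(
                f"{len(self.atom_records)} atom records for "
                f"{self.coordinates.shape[1]} atoms"
            )
        if self.frame_ids is None:
            self.frame_ids = np.arange(self.n_frames)
        else:
            self.frame_ids = np.asarray(self.frame_ids, dtype=int)
            if self.frame_ids.shape != (self.n_frames,):
                raise ValueError("frame_ids length must equal n_frames")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


def generic_atom_records(n_atoms: int) -> list[AtomRecord]:
    """CA pseudo-atom metadata for coordinate-matrix input."""
    return [
        AtomRecord(name="CA", resname="GLY", resseq=i + 1, chain="A", element="C")
        for i in range(n_atoms)
    ]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    return "pdb" if path.suffix.lower() in (".pdb", ".ent") else "matrix"


def read_trajectory(path: str | Path, format: str | None = None) -> TrajectoryEnsemble:
    """Read a multi-model PDB or a flat frames×(3·atoms) coordinate matrix.

    Flat-matrix rows are one frame each with columns x1 y1 z1 x2 …
    (whitespace- or comma-delimited); atom metadata is synthesised as
    generic CA pseudo-atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt in ("pdb", "multi-model-PDB"):
        return _read_pdb(path)
    if fmt in ("matrix", "flat-matrix"):
        return _read_matrix(path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def _read_pdb(path: Path) -> TrajectoryEnsemble:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    frames: list[np.ndarray] = []
    records: list[AtomRecord] | None = None
    n_ref = None
    for model in structure:
        coords = []
        recs = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    coords.append(atom.get_coord())
                    recs.append(
                        AtomRecord(
                            name=atom.get_name(),
                            resname=residue.get_resname(),
                            resseq=residue.get_id()[1],
                            chain=chain.get_id(),
                            element=(atom.element or "C").strip() or "C",
                        )
                    )
        if n_ref is None:
            n_ref = len(coords)
            records = recs
        elif len(coords) != n_ref:
            raise ValueError(
                f"model {model.get_id() + 1} in {path.name} has {len(coords)} atoms, "
                f"expected {n_ref}"
            )
        frames.append(np.asarray(coords, dtype=float))
    if not frames:
        raise ValueError(f"no models found in {path}")
    assert records is not None
    return TrajectoryEnsemble(np.stack(frames), records)


def _read_matrix(path: Path) -> TrajectoryEnsemble:
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    values = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if values.shape[1] % 3 != 0:
        raise ValueError(
            f"{path.name}: {values.shape[1]} columns is not a multiple of 3"
        )
    n_atoms = values.shape[1] // 3
    coords = values.reshape(values.shape[0], n_atoms, 3)
    return TrajectoryEnsemble(coords, generic_atom_records(n_atoms))


def write_trajectory(
    traj: TrajectoryEnsemble, path: str | Path, format: str | None = None
) -> Path:
    """Write as multi-model PDB or flat coordinate matrix (one frame/row)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("pdb", "multi-model-PDB"):
        _write_pdb(traj, path)
    elif fmt in ("matrix", "flat-matrix"):
        np.savetxt(path, traj.coordinates.reshape(traj.n_frames, -1), fmt="%.6f")
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    return path


def _build_structure(traj: TrajectoryEnsemble, frames: np.ndarray):
    from Bio.PDB.StructureBuilder import StructureBuilder

    builder = StructureBuilder()
    builder.init_structure("traj")
    for m, frame in enumerate(frames):
        builder.init_model(m)
        current_chain = None
        current_res = None
        for rec, xyz in zip(traj.atom_records, frame):
            if rec.chain != current_chain:
                builder.init_chain(rec.chain)
                builder.init_seg("    ")
                current_chain = rec.chain
                current_res = None
            if rec.resseq != current_res:
                builder.init_residue(rec.resname, " ", rec.resseq, " ")
                current_res = rec.resseq
            builder.init_atom(
                rec.name,
                np.asarray(xyz, dtype=float),
                0.0,
                1.0,
                " ",
                rec.name.center(4)[:4],
                element=rec.element,
            )
    return builder.get_structure()


def _write_pdb(traj: TrajectoryEnsemble, path: Path) -> None:
    from Bio.PDB import PDBIO

    io = PDBIO()
    io.set_structure(_build_structure(traj, traj.coordinates))
    io.save(str(path))


def write_frame_pdb(
    traj: TrajectoryEnsemble, coordinates: np.ndarray, path: str | Path
) -> Path:
    """Write a single conformation onto ``traj``'s atom records."""
    from Bio.PDB import PDBIO

    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (traj.n_atoms, 3):
        raise ValueError(
            f"coordinates shape {coordinates.shape} does not match "
            f"({traj.n_atoms}, 3)"
        )
    path = Path(path)
    io = PDBIO()
    io.set_structure(_build_structure(traj, coordinates[None]))
    io.save(str(path))
    return path


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------


def _matches(rec: AtomRecord, clause: str) -> bool:
    clause = clause.strip()
    if clause == "all":
        return True
    negate = False
    if clause.startswith("not "):
        negate = True
        clause = clause[4:].strip()
    tokens = clause.split(None, 1)
    if len(tokens) != 2:
        raise ValueError(f"cannot parse selection clause {clause!r}")
    key, arg = tokens
    if key == "name":
        hit = rec.name in {a.strip() for a in arg.split(",")}
    elif key == "element":
        hit = rec.element.upper() in {a.strip().upper() for a in arg.split(",")}
    elif key == "chain":
        hit = rec.chain in {a.strip() for a in arg.split(",")}
    elif key == "resid":
        hit = False
        for part in arg.split(","):
            part = part.strip()
            if "-" in part[1:]:
                lo, hi = part.split("-", 1)
                hit = hit or int(lo) <= rec.resseq <= int(hi)
            else:
                hit = hit or rec.resseq == int(part)
    elif key == "hydrogen" and arg == "atoms":  # convenience predicate
        hit = rec.element.upper() in _HYDROGEN_NAMES
    else:
        raise ValueError(f"unsupported selection predicate {key!r}")
    return hit != negate


def selection_mask(records: list[AtomRecord], selection: str) -> np.ndarray:
    """Boolean mask for a selection string.

    Clauses joined with ``and``: ``all``, ``name CA,CB``, ``resid 10-50``,
    ``chain A``, ``element C,N,O``, each optionally negated with ``not``
    (e.g. ``not element H``).
    """
    clauses = [c for c in selection.split(" and ")]
    mask = np.ones(len(records), dtype=bool)
    for clause in clauses:
        mask &= np.array([_matches(r, clause) for r in records], dtype=bool)
    return mask


def select_atoms(traj: TrajectoryEnsemble, selection: str) -> TrajectoryEnsemble:
    """Sub-ensemble with only matching atoms, original order preserved."""
    mask = selection_mask(traj.atom_records, selection)
    if not mask.any():
        raise ValueError(f"selection {selection!r} matches no atoms")
    records = [r for r, m in zip(traj.atom_records, mask) if m]
    return TrajectoryEnsemble(
        traj.coordinates[:, mask, :].copy(), records, traj.frame_ids.copy()
    )


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def align_to_first_frame(
    traj: TrajectoryEnsemble, fit_selection: str = "all"
) -> TrajectoryEnsemble:
    """Rigid-body superpose every frame onto frame 0 (Kabsch fit over the
    fit-selection atoms, transform applied to all atoms).  Frame 0 is
    returned unchanged; internal geometry of every frame is preserved.
    """
    mask = selection_mask(traj.atom_records, fit_selection)
    if mask.sum() < 3:
        raise ValueError("alignment requires at least 3 fit atoms")
    ref = traj.coordinates[0, mask, :]
    ref_centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(ref_centered, tol=1e-9) < 2:
        raise ValueError("reference fit atoms are collinear; alignment is degenerate")
    out = traj.coordinates.copy()
    ref_c = ref.mean(axis=0)
    for i in range(1, traj.n_frames):
        mob = traj.coordinates[i, mask, :]
        mob_c = mob.mean(axis=0)
        R = kabsch_rotation(mob - mob_c, ref_centered)
        out[i] = (traj.coordinates[i] - mob_c) @ R.T + ref_c
    return TrajectoryEnsemble(out, list(traj.atom_records), traj.frame_ids.copy())


# ---------------------------------------------------------------------------
# MinMax featurization
# ---------------------------------------------------------------------------


@dataclass
class FeatureScaler:
    """Per-column (min, max) pairs in Å; constant columns are flagged."""

    mins: np.ndarray
    maxs: np.ndarray
    constant_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if self.constant_mask is None:
            self.constant_mask = self.maxs <= self.mins
        self.constant_mask = np.asarray(self.constant_mask, dtype=bool)

    @property
    def n_features(self) -> int:
        return self.mins.size

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] != self.n_features:
            raise ValueError(
                f"width {values.shape[1]} does not match scaler ({self.n_features})"
            )
        span = np.where(self.constant_mask, 1.0, self.maxs - self.mins)
        out = (values - self.mins) / span
        out[:, self.constant_mask] = 0.0
        return out

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        """Map scaled values back to Å; values outside [0, 1] extrapolate
        linearly (decoder outputs may exceed the training range)."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] != self.n_features:
            raise ValueError(
                f"width {values.shape[1]} does not match scaler ({self.n_features})"
            )
        span = np.where(self.constant_mask, 0.0, self.maxs - self.mins)
        return values * span + self.mins

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "format": "mdvae-scaler-v1",
            "min": self.mins.tolist(),
            "max": self.maxs.tolist(),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureScaler":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "mdvae-scaler-v1":
            raise ValueError(f"{path}: not an mdvae scaler file")
        return cls(np.asarray(payload["min"]), np.asarray(payload["max"]))


@dataclass
class FeatureMatrix:
    """Flattened, MinMax-scaled frames×(3·atoms) feature array."""

    values: np.ndarray
    scaler: FeatureScaler
    frame_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_ids is None:
            self.frame_ids = np.arange(self.values.shape[0])

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def atom_index(self, column: int) -> tuple[int, str]:
        """Map a feature column to its (atom index, axis) pair."""
        return column // 3, "xyz"[column % 3]


def fit_transform(traj: TrajectoryEnsemble) -> FeatureMatrix:
    """MinMax-scale flattened coordinates; scaler min/max are the exact
    column-wise extrema over frames.  Columns with max == min are mapped
    to 0.0 and flagged (the scaling is undefined there).
    """
    flat = traj.coordinates.reshape(traj.n_frames, -1)
    mins = flat.min(axis=0)
    maxs = flat.max(axis=0)
    scaler = FeatureScaler(mins, maxs)
    if scaler.constant_mask.any():
        warnings.warn(
            f"{int(scaler.constant_mask.sum())} constant feature column(s) "
            "mapped to 0.0",
            stacklevel=2,
        )
    return FeatureMatrix(scaler.transform(flat), scaler, traj.frame_ids.copy())


def inverse_transform(values: np.ndarray, scaler: FeatureScaler) -> np.ndarray:
    """Scaled feature rows → (n_frames, n_atoms, 3) Å coordinates."""
    coords = scaler.inverse_transform(values)
    return coords.reshape(coords.shape[0], -1, 3)


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitIndex:
    """Disjoint train/test frame indices covering all frames."""

    train_indices: np.ndarray
    test_indices: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.train_indices.size + self.test_indices.size


def stride_split(n_frames: int, test_stride: int = 4) -> SplitIndex:
    """Every ``test_stride``-th frame (1-based: frames 4, 8, …) is test,
    the rest train — a 75/25 split at the default stride."""
    if test_stride < 2:
        raise ValueError("test_stride must be >= 2")
    if n_frames < test_stride:
        raise ValueError(f"n_frames={n_frames} < test_stride={test_stride}")
    idx = np.arange(n_frames)
    test = idx[(idx + 1) % test_stride == 0]
    train = idx[(idx + 1) % test_stride != 0]
    return SplitIndex(train, test)
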