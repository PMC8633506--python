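"""Latent-space exploration: seed generation and domain-angle CVs.

Once the two metastable-state regions are identified in the latent
space, candidate points on the segment between their centroids are
decoded into Cartesian conformations and written as single-model PDB
files, ready to seed new MD simulations.  Domain-angle collective
variables (e.g. the CORE–LID and CORE–NMP angles of adenylate kinase)
are computed from centre-of-mass difference vectors over residue
ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models as _models
from .features import FeatureScaler, TrajectoryEnsemble, inverse_transform, write_frame_pdb

__all__ = [
    "AngleDefinition",
    "SeedRequest",
    "load_angle_definitions",
    "adk_angle_definitions",
    "compute_domain_angle",
    "midpoint_candidates",
    "decode_to_pdb",
    "latent_map_report",
]

ResidueRanges = tuple[tuple[int, int], ...]


def _normalise_ranges(ranges) -> ResidueRanges:
    out = []
    for r in ranges:
        lo, hi = int(r[0]), int(r[1])
        if hi < lo:
            raise ValueError(f"invalid residue range {lo}-{hi}")
        out.append((lo, hi))
    if not out:
        raise ValueError("residue range set must be non-empty")
    return tuple(out)


def _range_set(ranges: ResidueRanges) -> set[int]:
    s: set[int] = set()
    for lo, hi in ranges:
        s.update(range(lo, hi + 1))
    return s


@dataclass
class AngleDefinition:
    """An angle between two centre-of-mass difference vectors.

    Each vector points from the centroid of its tail residue set to the
    centroid of its head residue set; residue ranges are inclusive.
    """

    name: str
    vector1: tuple[ResidueRanges, ResidueRanges]  # (tail, head)
    vector2: tuple[ResidueRanges, ResidueRanges]

    def __post_init__(self) -> None:
        v1 = tuple(_normalise_ranges(r) for r in self.vector1)
        v2 = tuple(_normalise_ranges(r) for r in self.vector2)
        for label, (tail, head) in (("vector1", v1), ("vector2", v2)):
            ts, hs = _range_set(tail), _range_set(head)
            if ts == hs:
                raise ValueError(f"{self.name}/{label}: tail and head sets identical")
            if ts & hs:
                warnings.warn(
                    f"{self.name}/{label}: tail and head residue sets overlap "
                    f"({sorted(ts & hs)})",
                    stacklevel=2,
                )
        self.vector1 = v1
        self.vector2 = v2


@dataclass
class SeedRequest:
    """Latent points (with labels) to decode into seed structures."""

    latent_points: np.ndarray
    labels: list[str] = field(default_factory=list)
    name_template: str = "seed_{label}.pdb"

    def __post_init__(self) -> None:
        self.latent_points = np.atleast_2d(np.asarray(self.latent_points, dtype=float))
        if not self.labels:
            self.labels = [str(i + 1) for i in range(len(self.latent_points))]
        if len(self.labels) != len(self.latent_points):
            raise ValueError("one label per latent point required")


def load_angle_definitions(path: str | Path) -> dict[str, AngleDefinition]:
    """Read angle definitions from a small YAML config."""
    payload = yaml.safe_load(Path(path).read_text())
    return _parse_angle_payload(payload)


def _parse_angle_payload(payload: dict) -> dict[str, AngleDefinition]:
    out = {}
    for name, spec in payload.items():
        out[name] = AngleDefinition(
            name=name,
            vector1=(spec["vector1"]["tail"], spec["vector1"]["head"]),
            vector2=(spec["vector2"]["tail"], spec["vector2"]["head"]),
        )
    return out


def adk_angle_definitions(numbering: str = "1ake-4ake") -> dict[str, AngleDefinition]:
    """Packaged CORE–NMP / CORE–LID angle definitions for adenylate
    kinase, in the residue numbering of the chosen crystal structure."""
    text = resources.files("mdvae.data").joinpath("adk_angles.yaml").read_text()
    payload = yaml.safe_load(text)
    if numbering not in payload:
        raise KeyError(f"unknown numbering {numbering!r}; have {sorted(payload)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the published LID ranges overlap at one residue
        return _parse_angle_payload(payload[numbering])


def _com(
    coords: np.ndarray,
    records,
    ranges: ResidueRanges,
    masses: np.ndarray | None,
) -> np.ndarray:
    resids = _range_set(ranges)
    mask = np.array([r.resseq in resids for r in records], dtype=bool)
    if not mask.any():
        missing = sorted(resids)
        raise ValueError(f"no atoms found for residues {missing}")
    if masses is None:
        return coords[mask].mean(axis=0)
    w = masses[mask]
    return (coords[mask] * w[:, None]).sum(axis=0) / w.sum()


def compute_domain_angle(
    traj: TrajectoryEnsemble,
    adef: AngleDefinition,
    mass_weighted: bool = False,
    masses: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame angle (degrees, in [0, 180]) between the two COM
    vectors.  Centres of mass are unweighted centroids by default;
    supply ``masses`` with ``mass_weighted=True`` to weight them.
    Invariant to global rigid motion of the frame."""
    present = {r.resseq for r in traj.atom_records}
    needed = set()
    for tail, head in (adef.vector1, adef.vector2):
        needed |= _range_set(tail) | _range_set(head)
    missing = sorted(needed - present)
    if missing:
        raise ValueError(f"residues missing from trajectory: {missing}")
    w = masses if mass_weighted else None
    if mass_weighted and masses is None:
        raise ValueError("mass_weighted=True requires a masses array")
    angles = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.coordinates):
        v1 = _com(frame, traj.atom_records, adef.vector1[1], w) - _com(
            frame, traj.atom_records, adef.vector1[0], w
        )
        v2 = _com(frame, traj.atom_records, adef.vector2[1], w) - _com(
            frame, traj.atom_records, adef.vector2[0], w
        )
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            raise ValueError(f"zero-length vector in frame {i}")
        c = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
        angles[i] = np.degrees(np.arccos(c))
    return angles


def midpoint_candidates(
    embedding: "_models.LatentEmbedding | np.ndarray",
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    n_points: int = 1,
    jitter: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Candidate latent points between two labelled state regions.

    Points sit at evenly spaced interpolation parameters in (0, 1) along
    the segment between the two group centroids (a single point lands
    exactly at the midpoint), plus optional Gaussian jitter of width
    ``jitter``.
    """
    pts = embedding.points if hasattr(embedding, "points") else np.asarray(embedding)
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("both frame index sets must be non-empty")
    ca = pts[a].mean(axis=0)
    cb = pts[b].mean(axis=0)
    if np.allclose(ca, cb):
        raise ValueError("group centroids coincide; interpolation direction undefined")
    t = (np.arange(n_points) + 1.0) / (n_points + 1.0)
    out = ca[None, :] + t[:, None] * (cb - ca)[None, :]
    if jitter > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(scale=jitter, size=out.shape)
    return out


def decode_to_pdb(
    model: "_models.TrainedModel",
    scaler: FeatureScaler,
    request: SeedRequest,
    template: TrajectoryEnsemble,
    outdir: str | Path,
) -> list[Path]:
    """Decode latent points and write each conformation as a
    single-model PDB on the template's atom records."""
    if template.n_atoms * 3 != scaler.n_features:
        raise ValueError(
            f"template atom count {template.n_atoms} x 3 != feature width "
            f"{scaler.n_features}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    values = _models.decode(model, request.latent_points)
    coords = inverse_transform(values, scaler)
    paths = []
    for label, xyz in zip(request.labels, coords):
        path = outdir / request.name_template.format(label=label)
        write_frame_pdb(template, xyz, path)
        paths.append(path)
    return paths


def latent_map_report(
    embedding: "_models.LatentEmbedding",
    labels: np.ndarray,
    angles: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Tidy (frame, z1, z2, label, angle…) table for external plotting."""
    pts = embedding.points
    labels = np.asarray(labels)
    if len(labels) != len(pts):
        raise ValueError("labels length must match embedding frame count")
    data = {"frame": np.asarray(embedding.frame_ids)}
    for d in range(pts.shape[1]):
        data[f"z{d + 1}"] = pts[:, d]
    data["label"] = labels
    for name, values in (angles or {}).items():
        values = np.asarray(values)
        if len(values) != len(pts):
            raise ValueError(f"angle series {name!r} length mismatch")
        data[name] = values
    return pd.DataFrame(data)
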