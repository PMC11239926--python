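"""Readers and writers for the standard formats the pipeline touches.

Masks travel as NIfTI, surface meshes as PLY/STL/OBJ, size-measurement
tables as comma-separated CSV with a fixed header.  All world coordinates
are millimetres; the voxel-to-world mapping is the NIfTI affine.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh
import yaml

from aneumorph.errors import FormatError, ValidationError

logger = logging.getLogger("aneumorph")

MESH_EXTENSIONS = {".ply", ".stl", ".obj"}
RUPTURE_LABELS = {"ruptured", "unruptured"}
TABLE_COLUMNS = ["case_id", "rater_id", "session", "timepoint", "size_mm", "rupture_status"]


def setup_logging(verbose: bool = False) -> None:
    """Route structured package logs to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# Binary volumes


@dataclass
class BinaryVolume:
    """A binary vascular segmentation with its world geometry.

    Parameters
    ----------
    voxels : (I, J, K) uint8 array with values in {0, 1}.
    affine : (4, 4) voxel-index to world-mm affine (NIfTI convention).
    """

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise FormatError(f"voxels must be 3D, got {self.voxels.ndim}D")
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, [0, 1])):
            raise FormatError(f"voxels must be binary, found values {vals[:5]}")
        self.voxels = self.voxels.astype(np.uint8)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine must be an invertible 4x4 matrix")
        if np.any(self.spacing <= 0):
            raise FormatError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        """World coordinate of voxel (0, 0, 0) in mm."""
        return self.affine[:3, 3].copy()

    @property
    def axis_orientation(self) -> tuple[str, str, str]:
        """Anatomical axis codes of the voxel axes (e.g. ('R', 'A', 'S'))."""
        return nib.orientations.aff2axcodes(self.affine)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (N, 3) to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())


def read_binary_mask(path: str | Path) -> BinaryVolume:
    """Read a NIfTI label volume and binarize it at 0.5.

    Masks are nominally {0, 1}; any voxel strictly above 0.5 becomes
    foreground. Spacing and origin come from the file's affine and are in mm.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"mask must be a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"non-positive voxel spacing in header: {zooms}")
    return BinaryVolume(voxels=(data > 0.5).astype(np.uint8), affine=img.affine)


def write_binary_mask(volume: BinaryVolume, path: str | Path) -> None:
    """Write a BinaryVolume as NIfTI (.nii or .nii.gz)."""
    img = nib.Nifti1Image(volume.voxels.astype(np.uint8), volume.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Surface meshes


def read_mesh(path: str | Path):
    """Read a triangle surface mesh (PLY/STL/OBJ) as a SurfaceMesh.

    Vertex order and count are preserved for PLY and OBJ. STL stores an
    unindexed triangle soup, so vertices shared between faces are merged on
    load and the original vertex order is not recoverable.
    """
    from aneumorph.mesh_geometry import SurfaceMesh

    path = Path(path)
    ext = path.suffix.lower()
    if ext not in MESH_EXTENSIONS:
        raise FormatError(f"unsupported mesh extension {ext!r}; use one of {sorted(MESH_EXTENSIONS)}")
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    process = ext == ".stl"  # merge the STL triangle soup into an indexed mesh
    loaded = trimesh.load(str(path), file_type=ext[1:], process=process, force="mesh")
    faces = np.asarray(loaded.faces)
    if faces.size == 0 or len(loaded.vertices) == 0:
        raise FormatError(f"mesh in {path} has no faces")
    if faces.shape[1] != 3:
        raise FormatError(f"mesh in {path} has non-triangular faces")
    return SurfaceMesh(vertices=np.asarray(loaded.vertices, dtype=float), faces=faces.astype(np.int64))


def write_mesh(mesh, path: str | Path) -> None:
    """Write a SurfaceMesh to PLY/STL/OBJ (by extension)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in MESH_EXTENSIONS:
        raise FormatError(f"unsupported mesh extension {ext!r}; use one of {sorted(MESH_EXTENSIONS)}")
    if len(mesh.faces) == 0:
        raise FormatError("refusing to write an empty mesh")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))


# ---------------------------------------------------------------------------
# Measurement tables


@dataclass(frozen=True)
class MeasurementRecord:
    """One size measurement of one aneurysm by one rater.

    ``session`` indexes repeat measurements (intra-rater analysis),
    ``timepoint`` indexes follow-up scans (growth monitoring).
    """

    case_id: str
    rater_id: str
    session: int
    timepoint: int
    size_mm: float
    rupture_status: str

    def __post_init__(self) -> None:
        if self.size_mm <= 0:
            raise ValidationError(f"size_mm must be positive, got {self.size_mm}")
        if self.session < 1:
            raise ValidationError(f"session must be >= 1, got {self.session}")
        if self.timepoint < 0:
            raise ValidationError(f"timepoint must be >= 0, got {self.timepoint}")
        if self.rupture_status not in RUPTURE_LABELS:
            raise ValidationError(
                f"unknown rupture_status {self.rupture_status!r}; expected one of {sorted(RUPTURE_LABELS)}"
            )

    @property
    def key(self) -> tuple:
        return (self.case_id, self.rater_id, self.session, self.timepoint)


class MeasurementTable:
    """Long-format collection of MeasurementRecord rows.

    Wraps a validated pandas DataFrame with columns
    case_id, rater_id, session, timepoint, size_mm, rupture_status;
    the key (case_id, rater_id, session, timepoint) is unique.
    """

    def __init__(self, records: Iterable[MeasurementRecord] | pd.DataFrame):
        if isinstance(records, pd.DataFrame):
            records = _records_from_frame(records)
        records = list(records)
        seen: dict[tuple, int] = {}
        for i, rec in enumerate(records):
            if rec.key in seen:
                raise ValidationError(
                    f"duplicate measurement key {rec.key} at rows {seen[rec.key]} and {i}"
                )
            seen[rec.key] = i
        self.records: list[MeasurementRecord] = records

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.case_id, r.rater_id, r.session, r.timepoint, r.size_mm, r.rupture_status)
                for r in self.records
            ],
            columns=TABLE_COLUMNS,
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, MeasurementTable) and self.records == other.records


def _records_from_frame(df: pd.DataFrame) -> list[MeasurementRecord]:
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"measurement table missing columns: {missing}")
    records, bad_rows = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                MeasurementRecord(
                    case_id=str(row.case_id),
                    rater_id=str(row.rater_id),
                    session=int(row.session),
                    timepoint=int(row.timepoint),
                    size_mm=float(row.size_mm),
                    rupture_status=str(row.rupture_status),
                )
            )
        except (ValidationError, ValueError) as exc:
            bad_rows.append((i, str(exc)))
    if bad_rows:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:10])
        raise ValidationError(f"{len(bad_rows)} invalid measurement rows ({detail})")
    return records


def read_measurement_table(path: str | Path) -> MeasurementTable:
    """Read a CSV measurement table (comma-separated, header required, UTF-8)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"measurement table not found: {path}")
    df = pd.read_csv(path, encoding="utf-8")
    return MeasurementTable(df)


def write_measurement_table(table: MeasurementTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Configuration

DEFAULT_CONFIG: dict = {
    "roi": {"n_points": 5000},
    "smoothing": {"iterations": 10, "shrink_factor": 0.5, "inflate_factor": -0.53},
    "isosurface": {"level": 0.5},
    "growth": {"threshold_mm": 1.0, "aggregation": "any_growing"},
    "icc": {"variant": "two_way_random_absolute_single"},
}


def load_config(path: str | Path | None = None) -> dict:
    """Load pipeline parameters from YAML or JSON, merged over defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is None:
        return cfg
    path = Path(path)
    if not path.exists():
        raise FormatError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    user = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if user is None:
        return cfg
    if not isinstance(user, dict):
        raise FormatError("config root must be a mapping")
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg
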