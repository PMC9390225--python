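"""Reading and writing CT volumes, label masks and per-case feature tables.

Volumes are NIfTI-1 (HU as signed 16-bit, masks as unsigned 8-bit); tables
are CSV with one row per (case, side). All geometry downstream is computed
in physical millimetres via the stored voxel spacing, so the axis order of
the arrays never affects results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CTVolume",
    "LabelMask",
    "CaseTable",
    "GridMismatchError",
    "LabelError",
    "SchemaError",
    "load_case",
    "save_case",
    "feature_table_io",
]

HU_MIN = -1024.0
HU_MAX = 3071.0
#: default label semantics: background / lung / pleural collection / airway
DEFAULT_LABEL_MAP = {0: "background", 1: "lung", 2: "pleura", 3: "airway"}

SPACING_ATOL_MM = 1e-3


class GridMismatchError(ValueError):
    """Volume and mask do not share shape/spacing within tolerance."""


class LabelError(ValueError):
    """Mask contains labels outside its declared label map."""


class SchemaError(ValueError):
    """A tabular file is missing required columns."""


@dataclass
class CTVolume:
    """A 3D CT scalar grid in Hounsfield units with physical geometry.

    Parameters
    ----------
    data : ndarray
        3D array of HU values; clamped to the 12-bit CT range
        [-1024, 3071] on construction.
    spacing : tuple of float
        Voxel edge lengths (sx, sy, sz) in mm, all > 0.
    origin : tuple of float
        Physical offset of the first voxel in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"CT volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        np.clip(self.data, HU_MIN, HU_MAX, out=self.data)

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class LabelMask:
    """Integer label grid co-registered with a :class:`CTVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label mask must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise LabelError("mask values are not integral")
            self.data = rounded
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.label_map = {int(k): str(v) for k, v in self.label_map.items()}
        present = set(np.unique(self.data).tolist())
        undeclared = present - set(self.label_map)
        if undeclared:
            raise LabelError(
                f"mask contains undeclared labels {sorted(undeclared)}; "
                f"declared: {sorted(self.label_map)}"
            )

    def region(self, label: int) -> np.ndarray:
        """Boolean mask of one label."""
        return self.data == label

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def validate_against(self, volume: CTVolume) -> None:
        if self.data.shape != volume.data.shape:
            raise GridMismatchError(
                f"mask shape {self.data.shape} != volume shape {volume.data.shape}"
            )
        if not np.allclose(self.spacing, volume.spacing, atol=SPACING_ATOL_MM):
            raise GridMismatchError(
                f"mask spacing {self.spacing} != volume spacing {volume.spacing} "
                f"(tolerance {SPACING_ATOL_MM} mm)"
            )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def load_case(volume_path, mask_path, label_map: dict[int, str] | None = None):
    """Load a co-registered (CT volume, label mask) pair from NIfTI files.

    HU values are clamped to [-1024, 3071]; the pair is validated for grid
    compatibility (shape equal, spacing within 1e-3 mm).
    """
    volume_path, mask_path = Path(volume_path), Path(mask_path)
    vimg = nib.load(str(volume_path))
    mimg = nib.load(str(mask_path))
    vdata = np.asanyarray(vimg.dataobj)
    mdata = np.asanyarray(mimg.dataobj)
    if vdata.ndim != 3 or mdata.ndim != 3:
        raise ValueError(
            f"expected 3D volumes: {volume_path} is {vdata.ndim}D, "
            f"{mask_path} is {mdata.ndim}D"
        )
    vspacing = tuple(float(z) for z in vimg.header.get_zooms()[:3])
    mspacing = tuple(float(z) for z in mimg.header.get_zooms()[:3])
    vorigin = tuple(float(x) for x in vimg.affine[:3, 3])
    volume = CTVolume(vdata, vspacing, vorigin)
    mask = LabelMask(
        mdata, mspacing, vorigin,
        label_map=label_map or dict(DEFAULT_LABEL_MAP),
    )
    mask.validate_against(volume)
    return volume, mask


def save_case(volume: CTVolume, mask: LabelMask, out_dir, stem: str = "case"):
    """Write a validated pair as ``<stem>_ct.nii.gz`` / ``<stem>_mask.nii.gz``.

    Returns the two paths. HU data are stored as int16 (lossless after
    clamping and rounding to whole HU), masks as uint8.
    """
    mask.validate_against(volume)
    out_dir = Path(out_dir)
    vpath = out_dir / f"{stem}_ct.nii.gz"
    mpath = out_dir / f"{stem}_mask.nii.gz"
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        vimg = nib.Nifti1Image(
            np.rint(volume.data).astype(np.int16),
            _affine(volume.spacing, volume.origin),
        )
        vimg.header.set_zooms(volume.spacing)
        nib.save(vimg, str(vpath))
        mimg = nib.Nifti1Image(
            mask.data.astype(np.uint8), _affine(mask.spacing, mask.origin)
        )
        mimg.header.set_zooms(mask.spacing)
        nib.save(mimg, str(mpath))
    except OSError as exc:
        raise OSError(f"failed writing case under {out_dir}: {exc}") from exc
    return vpath, mpath


LABEL_COLUMNS = (
    "hyperdense_fluid",
    "pleural_thickening",
    "gas",
    "loculation",
    "complex",
)


class CaseTable:
    """Per-(case, side) feature and label rows backing the classification step.

    Thin wrapper over a :class:`pandas.DataFrame` enforcing the schema:
    ``case_id`` and ``side`` columns present, (case_id, side) unique, and no
    missing values in feature columns.
    """

    REQUIRED = ("case_id", "side")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"case table missing required columns {missing}")
        if df.duplicated(subset=["case_id", "side"]).any():
            raise SchemaError("(case_id, side) pairs must be unique")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, CaseTable) and self.df.equals(other.df)

    @property
    def feature_columns(self) -> list[str]:
        skip = set(self.REQUIRED) | set(LABEL_COLUMNS) | {"diagnosis"}
        return [
            c for c in self.df.columns
            if c not in skip and pd.api.types.is_numeric_dtype(self.df[c])
        ]

    def to_csv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        # 6 significant digits for floats; labels/ids are written exactly
        self.df.to_csv(path, index=False, float_format="%.6g")
        return path

    @classmethod
    def read_csv(cls, path) -> "CaseTable":
        df = pd.read_csv(path)
        return cls(df)

    @classmethod
    def from_records(cls, records: list[dict]) -> "CaseTable":
        return cls(pd.DataFrame.from_records(records))


def feature_table_io(table_or_path, path=None, direction: str = "write"):
    """Round-trip a :class:`CaseTable` through CSV.

    ``direction='write'`` takes (table, path) and returns the path;
    ``direction='read'`` takes a path and returns the table.
    """
    if direction == "write":
        if path is None:
            raise ValueError("write direction requires a path")
        return table_or_path.to_csv(path)
    if direction == "read":
        return CaseTable.read_csv(table_or_path)
    raise ValueError(f"direction must be 'read' or 'write', got {direction!r}")


def write_labels_json(records: list[dict], path) -> Path:
    """Write per-case label records as JSON (accepted alternative to CSV)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(records, indent=1))
    return path


def read_labels_json(path) -> list[dict]:
    return json.loads(Path(path).read_text())
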