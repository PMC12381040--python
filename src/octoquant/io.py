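"""On-disk data model: intensity stacks, ROI polygons, field manifests, cell tables.

A *field* is one imaged position: a DIC z-stack plus up to seven fluorescence
z-stacks, a set of manually drawn cell outlines (ROIs) on the mid-section
plane, and acquisition metadata.  Each channel lives in its own
single-channel multi-page TIFF; a YAML manifest links them.  ROIs are stored
as a JSON list of ``{cell_id, vertices}`` records; per-cell results go to CSV.

Readers never rescale intensities: what is in the file is what the analysis
sees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import LinearRing

__all__ = [
    "CHANNELS",
    "TREATMENT_NACL_MM",
    "Stack",
    "RoiPolygon",
    "FieldManifest",
    "CellRecord",
    "ValidationError",
    "read_stack",
    "write_stack",
    "read_rois",
    "write_rois",
    "read_manifest",
    "write_manifest",
    "write_cell_table",
    "read_cell_table",
]

#: Channel vocabulary: the label-free channel plus the stained organelles.
CHANNELS = (
    "DIC",
    "nucleus",
    "cell_membrane",
    "mitochondria",
    "endoplasmic_reticulum",
    "lysosome",
    "actin",
    "tubulin",
)

#: NaCl concentration (mM) defining each tonicity treatment.
TREATMENT_NACL_MM = {"hypertonic": 175, "isotonic": 137, "hypotonic": 75}

#: Region labels used in per-cell tables, in canonical column order.
REGIONS = (
    "whole",
    "oct1",
    "oct2",
    "oct3",
    "oct4",
    "oct5",
    "oct6",
    "oct7",
    "oct8",
    "apical",
    "basolateral",
    "x_prog",
    "x_reg",
    "y_prog",
    "y_reg",
)

_ALLOWED_DTYPES = ("uint8", "uint16", "float32")


class ValidationError(ValueError):
    """Input violates a documented invariant."""


@dataclass
class Stack:
    """One channel's z-stack: ``voxels[plane, row, col]`` plus voxel spacing.

    ``dz_um`` is the plane spacing, ``dxy_um`` the in-plane pixel size, both
    in micrometres.
    """

    voxels: np.ndarray
    channel_label: str
    dz_um: float = 0.4
    dxy_um: float = 0.1

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValidationError("stack must be 3D with at least one plane")
        if np.any(self.voxels < 0):
            raise ValidationError("stack intensities must be non-negative")
        if self.channel_label not in CHANNELS:
            raise ValidationError(f"unknown channel label {self.channel_label!r}")
        if not (self.dz_um > 0 and self.dxy_um > 0):
            raise ValidationError("voxel spacing must be positive")

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]


@dataclass
class RoiPolygon:
    """Manually drawn cell outline on the mid-section plane.

    Vertices are ordered ``(x, y)`` pixel coordinates, 0-based, x = column and
    y = row, placed at pixel centers.  The polygon must be simple
    (non-self-intersecting) and closed implicitly (last vertex joins first).
    """

    cell_id: str
    vertices: np.ndarray
    field_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("vertices must be an (n, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise ValidationError(
                f"ROI {self.cell_id!r} needs >= 3 vertices, got {len(self.vertices)}"
            )
        ring = LinearRing(self.vertices)
        if not ring.is_simple:
            raise ValidationError(f"ROI {self.cell_id!r} is self-intersecting")


@dataclass
class FieldManifest:
    """Links one field's channel TIFFs, ROI file and acquisition metadata."""

    field_id: str
    treatment: str
    nacl_mM: float
    stack_paths: dict[str, str]
    roi_path: str
    dz_um: float = 0.4
    dxy_um: float = 0.1

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENT_NACL_MM:
            raise ValidationError(f"unknown treatment {self.treatment!r}")
        expected = TREATMENT_NACL_MM[self.treatment]
        if float(self.nacl_mM) != float(expected):
            raise ValidationError(
                f"treatment {self.treatment!r} implies {expected} mM NaCl, "
                f"manifest says {self.nacl_mM}"
            )
        unknown = set(self.stack_paths) - set(CHANNELS)
        if unknown:
            raise ValidationError(f"unknown channels in manifest: {sorted(unknown)}")


@dataclass
class CellRecord:
    """Quantification of one cell on one channel.

    ``apv`` maps each region label from :data:`REGIONS` to its raw average
    pixel value; ``napv`` holds the field-normalized counterparts (filled by
    the normalization pass).
    """

    field_id: str
    cell_id: str
    channel_label: str
    circularity: float
    shape_class: str
    centroid: tuple[float, float, float]
    tpn: int
    apv: dict[str, float] = field(default_factory=dict)
    napv: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stacks


def read_stack(path, channel_label: str = "DIC", dz_um: float = 0.4, dxy_um: float = 0.1) -> Stack:
    """Read a multi-page TIFF into a :class:`Stack`, intensities bit-exact."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    voxels = tifffile.imread(path)
    if voxels.ndim == 2:  # single-page file -> one-plane stack
        voxels = voxels[None, :, :]
    if voxels.ndim != 3:
        raise ValidationError(f"{path}: expected a single-channel multi-page TIFF")
    return Stack(voxels=voxels, channel_label=channel_label, dz_um=dz_um, dxy_um=dxy_um)


def write_stack(stack: Stack, path) -> Path:
    path = Path(path)
    if str(stack.voxels.dtype) not in _ALLOWED_DTYPES:
        raise ValidationError(
            f"stack dtype {stack.voxels.dtype} not in {_ALLOWED_DTYPES}"
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.voxels, photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# ROIs


def read_rois(path, field_id: str = "") -> list[RoiPolygon]:
    """Read a JSON list of ``{cell_id, vertices}`` records.

    Raises on duplicate cell ids within the file and on degenerate polygons.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = json.loads(path.read_text())
    if not isinstance(records, list):
        raise ValidationError(f"{path}: expected a JSON list of ROI records")
    rois = []
    seen: set[str] = set()
    for rec in records:
        cid = rec["cell_id"]
        if cid in seen:
            raise ValidationError(f"duplicate cell_id {cid!r} in {path}")
        seen.add(cid)
        rois.append(RoiPolygon(cell_id=cid, vertices=np.asarray(rec["vertices"]), field_id=field_id))
    return rois


def write_rois(rois: list[RoiPolygon], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [
        {"cell_id": r.cell_id, "vertices": np.asarray(r.vertices, dtype=float).tolist()}
        for r in rois
    ]
    path.write_text(json.dumps(payload, indent=1))
    return path


# ---------------------------------------------------------------------------
# manifests


def read_manifest(path) -> FieldManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text())
    return FieldManifest(
        field_id=data["field_id"],
        treatment=data["treatment"],
        nacl_mM=data["nacl_mM"],
        stack_paths=dict(data["stack_paths"]),
        roi_path=data["roi_path"],
        dz_um=float(data.get("dz_um", 0.4)),
        dxy_um=float(data.get("dxy_um", 0.1)),
    )


def write_manifest(manifest: FieldManifest, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {
        "field_id": manifest.field_id,
        "treatment": manifest.treatment,
        "nacl_mM": manifest.nacl_mM,
        "stack_paths": dict(manifest.stack_paths),
        "roi_path": manifest.roi_path,
        "dz_um": manifest.dz_um,
        "dxy_um": manifest.dxy_um,
    }
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# cell tables

_SCALAR_COLS = [
    "field_id",
    "cell_id",
    "channel",
    "circularity",
    "shape_class",
    "centroid_x",
    "centroid_y",
    "centroid_z",
    "tpn",
]


def _record_row(rec: CellRecord) -> dict:
    row = {
        "field_id": rec.field_id,
        "cell_id": rec.cell_id,
        "channel": rec.channel_label,
        "circularity": rec.circularity,
        "shape_class": rec.shape_class,
        "centroid_x": rec.centroid[0],
        "centroid_y": rec.centroid[1],
        "centroid_z": rec.centroid[2],
        "tpn": rec.tpn,
    }
    for region in REGIONS:
        row[f"apv_{region}"] = rec.apv.get(region, np.nan)
        row[f"napv_{region}"] = rec.napv.get(region, np.nan)
    return row


def cell_table(records: list[CellRecord]) -> pd.DataFrame:
    """Assemble per-cell records into the canonical long table (cell x channel)."""
    if not records:
        raise ValidationError("no cell records to tabulate")
    per_cell_channels: dict[tuple[str, str], set[str]] = {}
    for rec in records:
        per_cell_channels.setdefault((rec.field_id, rec.cell_id), set()).add(rec.channel_label)
    channel_sets = {frozenset(v) for v in per_cell_channels.values()}
    if len(channel_sets) > 1:
        raise ValidationError("cells carry inconsistent channel sets")
    df = pd.DataFrame([_record_row(r) for r in records])
    cols = _SCALAR_COLS + [f"{kind}_{r}" for r in REGIONS for kind in ("apv", "napv")]
    return df[cols].sort_values(["field_id", "cell_id", "channel"]).reset_index(drop=True)


def write_cell_table(records: list[CellRecord], path) -> Path:
    """Write the per-cell CSV; values survive a round trip to 6 significant digits."""
    df = cell_table(records)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_cell_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path)
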