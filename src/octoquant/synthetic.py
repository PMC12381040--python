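"""Synthetic confocal-like z-stacks with known ground truth.

Generates fields of adherent-cell stand-ins so every pipeline stage can be
tested without microscope data.  Each cell is an ellipse (optionally with a
low-order Fourier boundary wobble, which is how the asymmetric, circularity
< 0.8 class is populated — a pure 2:1 ellipse alone has circularity ~0.84),
rasterized to a 2D mask that is replicated through the stack, exactly as the
analysis assumes.

Intensity model
---------------
``intensity(v) = base * pattern(v) * prod_axis(1 + k_axis * s_axis(v)) + noise``

where ``s_axis`` is the signed voxel coordinate relative to the cell center,
normalized by the cell's extent along that axis, and the noise is additive
Gaussian clipped at zero.  The user-facing gradient parameter ``g`` is the
*target half-contrast*: ``g_z = -0.2`` means the basolateral half-APV exceeds
the apical one by 20%.  Because the voxel grid is discrete (and the two
halves of an odd-plane stack are unequal), the ramp slope ``k`` is calibrated
per cell from the actual mean of ``s`` over each half, so the imposed
contrast is exact in expectation rather than approximate.  Patterns are 2D
(identical on every plane), which keeps the z-calibration exact for every
pattern.

Positive ``g`` brightens the progressive (x, y) / apical (z) half; negative
``g`` the regressive / basolateral half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt

from .io import (
    CHANNELS,
    TREATMENT_NACL_MM,
    FieldManifest,
    RoiPolygon,
    Stack,
    ValidationError,
    write_manifest,
    write_rois,
    write_stack,
)
from .morphology import CellMask, centroid as mask_centroid, rasterize_mask, total_pixel_number

__all__ = [
    "SyntheticCellSpec",
    "GroundTruth",
    "boundary_polygon",
    "generate_cell",
    "generate_field",
    "osmotic_transform",
    "OSMOTIC_AXIS_SCALE",
    "GRADIENT_PRESETS",
]

#: Linear-dimension scale factor applied by each treatment (cells shrink in
#: hypertonic and swell in hypotonic medium).
OSMOTIC_AXIS_SCALE = {"hypertonic": 0.9, "isotonic": 1.0, "hypotonic": 1.1}

#: Per-treatment, per-channel gradient presets emulating the dominant
#: basolateral polarity observed across organelles (g_z < 0 throughout, with
#: a nil tubulin in hypertonic/hypotonic as a no-polarity control).
GRADIENT_PRESETS = {
    "hypertonic": {
        "DIC": (0.0, 0.0, -0.02),
        "nucleus": (0.0, 0.0, -0.5),
        "cell_membrane": (0.0, 0.0, -0.3),
        "mitochondria": (0.0, 0.0, -0.4),
        "endoplasmic_reticulum": (0.0, 0.0, -0.3),
        "lysosome": (0.0, 0.0, -0.5),
        "actin": (0.0, 0.0, -0.3),
        "tubulin": (0.0, 0.0, 0.0),
    },
    "isotonic": {
        "DIC": (0.0, 0.0, -0.02),
        "nucleus": (0.0, 0.0, 0.3),
        "cell_membrane": (0.0, 0.0, -0.3),
        "mitochondria": (0.0, 0.0, -0.2),
        "endoplasmic_reticulum": (0.0, 0.0, -0.15),
        "lysosome": (0.0, 0.0, -0.4),
        "actin": (0.0, 0.0, -0.3),
        "tubulin": (0.0, 0.0, -0.2),
    },
    "hypotonic": {
        "DIC": (0.0, 0.0, -0.02),
        "nucleus": (0.0, -0.15, 0.0),
        "cell_membrane": (0.0, 0.0, -0.3),
        "mitochondria": (0.0, 0.0, -0.2),
        "endoplasmic_reticulum": (0.0, 0.15, -0.2),
        "lysosome": (0.0, 0.0, -0.4),
        "actin": (0.0, 0.0, 0.0),
        "tubulin": (0.0, 0.0, 0.0),
    },
}

_PATTERNS = ("uniform", "shell", "punctate", "central_blob")


@dataclass
class SyntheticCellSpec:
    """Ground-truth parameters of one generated cell.

    ``gradient`` is the target fractional half-contrast per axis (see module
    docstring for the sign convention).  ``channel_gradients`` optionally
    overrides it per channel.  ``wobble_amp``/``wobble_mode`` shape the
    Fourier boundary perturbation; amplitude 0 gives a pure ellipse.
    """

    cell_id: str
    a: float  # semi-axis along x, px
    b: float  # semi-axis along y, px
    center: tuple[float, float]
    n_planes: int = 21
    base_intensity: float = 100.0
    gradient: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel_gradients: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    pattern: str = "uniform"
    noise_sd: float = 0.0
    wobble_amp: float = 0.0
    wobble_mode: int = 5
    wobble_phase: float = 0.0
    angle: float = 0.0  # ellipse rotation, radians
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValidationError("semi-axes must be positive")
        if not self.base_intensity > 0:
            raise ValidationError("base intensity must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")
        for g in self.gradient:
            if not abs(g) < 1:
                raise ValidationError("|gradient| must be < 1 per axis")
        if self.pattern not in _PATTERNS:
            raise ValidationError(f"unknown pattern {self.pattern!r}")
        if self.n_planes < 1:
            raise ValidationError("n_planes must be >= 1")

    def gradient_for(self, channel: str) -> tuple[float, float, float]:
        return self.channel_gradients.get(channel, self.gradient)


@dataclass
class GroundTruth:
    """What the generator actually built, for recovery tests.

    Derivable quantities (TPN, centroid, shape class boundary effects) are
    measured from the generated mask, never assumed from the spec.
    """

    cells: dict[str, dict]
    adjacency: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "cells": self.cells,
            "adjacency": [list(e) for e in self.adjacency],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def boundary_polygon(spec: SyntheticCellSpec, n_vertices: int = 180) -> RoiPolygon:
    """Outline polygon of the (wobbled) ellipse, as the ROI the analysis sees."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    radial = 1.0 + spec.wobble_amp * np.cos(spec.wobble_mode * theta + spec.wobble_phase)
    x = spec.a * radial * np.cos(theta)
    y = spec.b * radial * np.sin(theta)
    ca, sa = np.cos(spec.angle), np.sin(spec.angle)
    xr = ca * x - sa * y + spec.center[0]
    yr = sa * x + ca * y + spec.center[1]
    return RoiPolygon(cell_id=spec.cell_id, vertices=np.column_stack([xr, yr]))


def _calibrated_slope(s: np.ndarray, g: float) -> float:
    """Ramp slope k such that the half-contrast of 1 + k*s equals g exactly.

    ``s`` holds the normalized signed coordinates of the mask voxels along one
    axis.  With sp/sr the mean of s over the progressive (s >= 0) and
    regressive halves, solving  (1 + k*sp)/(1 + k*sr) = 1 + g  (or its mirror
    for g < 0) gives the slope below; k = 0 when the gradient is nil.
    """
    if g == 0.0:
        return 0.0
    prog = s >= 0
    if not prog.any() or prog.all():
        raise ValidationError("cannot impose a gradient: one half is empty")
    sp = s[prog].mean()
    sr = s[~prog].mean()
    if g > 0:
        return g / (sp - (1.0 + g) * sr)
    return g / ((1.0 - g) * sp - sr)


def _pattern_weights(spec: SyntheticCellSpec, mask2d: np.ndarray, rng) -> np.ndarray:
    """2D per-pixel pattern weight (same on every plane), mean-positive."""
    if spec.pattern == "uniform":
        return np.ones(mask2d.shape)
    dist = distance_transform_edt(mask2d)  # distance to the boundary, px
    if spec.pattern == "shell":
        # membrane-like: bright 2-px rim, dim interior
        return np.where(dist <= 2.0, 1.0, 0.15)
    ys, xs = np.nonzero(mask2d)
    if spec.pattern == "central_blob":
        # nucleus-like: Gaussian blob at the cell center
        cx, cy = xs.mean(), ys.mean()
        sigma = max(spec.a, spec.b) / 2.0
        yy, xx = np.mgrid[0 : mask2d.shape[0], 0 : mask2d.shape[1]]
        return 0.1 + np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)))
    # punctate: lysosome/mitochondria-like Gaussian spots at random interior pixels
    n_spots = max(3, int(mask2d.sum() / 400))
    idx = rng.choice(len(xs), size=min(n_spots, len(xs)), replace=False)
    yy, xx = np.mgrid[0 : mask2d.shape[0], 0 : mask2d.shape[1]]
    w = np.full(mask2d.shape, 0.1)
    for i in idx:
        w += np.exp(-(((xx - xs[i]) ** 2 + (yy - ys[i]) ** 2) / (2 * 2.0**2)))
    return w


def generate_cell(
    spec: SyntheticCellSpec,
    frame_shape: tuple[int, int] = (512, 512),
    channels: tuple[str, ...] = ("DIC",),
    dz_um: float = 0.4,
    dxy_um: float = 0.1,
) -> tuple[dict[str, Stack], CellMask, RoiPolygon, dict]:
    """Render one cell into per-channel stacks; deterministic given the spec seed.

    Returns ``(stacks, mask, roi, truth)`` where ``truth`` records the
    measured mask properties alongside the imposed gradients.  Voxels outside
    the mask are zero; the stack dtype is float32 so imposed contrasts are not
    quantized away.
    """
    rows, cols = frame_shape
    max_r = max(spec.a, spec.b) * (1.0 + spec.wobble_amp)
    cx0, cy0 = spec.center
    if not (max_r <= cx0 <= cols - 1 - max_r and max_r <= cy0 <= rows - 1 - max_r):
        raise ValidationError(f"cell {spec.cell_id!r} does not fit inside the frame")
    unknown = set(channels) - set(CHANNELS)
    if unknown:
        raise ValidationError(f"unknown channels {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    roi = boundary_polygon(spec)
    mask = rasterize_mask(roi, frame_shape, spec.n_planes)
    cx, cy, cz = mask_centroid(mask)

    ys, xs = np.nonzero(mask.mask2d)
    zs = np.arange(spec.n_planes)
    # normalized signed coordinates of mask voxels, per axis
    ext_x = max(xs.max() - xs.min(), 1)
    ext_y = max(ys.max() - ys.min(), 1)
    s_x = (xs - cx) / ext_x
    s_y = (ys - cy) / ext_y
    s_z = (zs - cz) / max(spec.n_planes, 1)

    pattern2d = _pattern_weights(spec, mask.mask2d, rng)[ys, xs]
    stacks: dict[str, Stack] = {}
    for channel in channels:
        gx, gy, gz = spec.gradient_for(channel)
        kx = _calibrated_slope(s_x, gx)
        ky = _calibrated_slope(s_y, gy)
        kz = _calibrated_slope(s_z, gz)
        ramp_xy = (1.0 + kx * s_x) * (1.0 + ky * s_y)  # per mask pixel
        ramp_z = 1.0 + kz * s_z  # per plane
        vox = np.zeros((spec.n_planes, rows, cols), dtype=np.float32)
        signal = spec.base_intensity * pattern2d * ramp_xy
        for z in range(spec.n_planes):
            plane = signal * ramp_z[z]
            if spec.noise_sd > 0:
                plane = plane + rng.normal(0.0, spec.noise_sd, size=plane.shape)
            vox[z, ys, xs] = np.clip(plane, 0.0, None)
        stacks[channel] = Stack(voxels=vox, channel_label=channel, dz_um=dz_um, dxy_um=dxy_um)

    truth = {
        "cell_id": spec.cell_id,
        "true_shape_class": "symmetric" if spec.a == spec.b and spec.wobble_amp <= 0.05 else "asymmetric",
        "centroid": [cx, cy, cz],
        "tpn": total_pixel_number(mask),
        "gradients": {ch: list(spec.gradient_for(ch)) for ch in channels},
        "pattern": spec.pattern,
    }
    return stacks, mask, roi, truth


def osmotic_transform(
    spec: SyntheticCellSpec,
    treatment: str,
    axis_scale: dict[str, float] | None = None,
    gradient_presets: dict[str, dict[str, tuple]] | None = None,
    channels: tuple[str, ...] = ("DIC",),
) -> SyntheticCellSpec:
    """Apply a treatment to a cell spec: scale its axes and set channel gradients.

    Hypertonic shrinks linear dimensions by 10% and hypotonic swells them by
    10% by default (isotonic is the identity on shape); the per-channel
    gradient preset for the treatment imposes the corresponding polarity
    pattern.
    """
    if treatment not in TREATMENT_NACL_MM:
        raise ValidationError(f"unknown treatment {treatment!r}")
    scale = (axis_scale or OSMOTIC_AXIS_SCALE)[treatment]
    presets = gradient_presets or GRADIENT_PRESETS
    channel_gradients = {
        ch: tuple(presets[treatment][ch]) for ch in channels if ch in presets[treatment]
    }
    return replace(
        spec,
        a=spec.a * scale,
        b=spec.b * scale,
        channel_gradients={**spec.channel_gradients, **channel_gradients},
    )


def _random_cell_spec(cell_id, rng, asymmetric, radius, n_planes, base, noise_sd):
    if asymmetric:
        ratio = rng.uniform(2.0, 2.6)
        b = radius / np.sqrt(ratio)  # keep area ~ pi * radius^2
        return SyntheticCellSpec(
            cell_id=cell_id,
            a=b * ratio,
            b=b,
            center=(0.0, 0.0),
            n_planes=n_planes,
            base_intensity=base,
            noise_sd=noise_sd,
            wobble_amp=rng.uniform(0.10, 0.14),
            wobble_mode=int(rng.integers(5, 8)),
            wobble_phase=rng.uniform(0, 2 * np.pi),
            angle=rng.uniform(0, np.pi),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return SyntheticCellSpec(
        cell_id=cell_id,
        a=radius,
        b=radius,
        center=(0.0, 0.0),
        n_planes=n_planes,
        base_intensity=base,
        noise_sd=noise_sd,
        wobble_amp=rng.uniform(0.0, 0.03),
        wobble_mode=4,
        wobble_phase=rng.uniform(0, 2 * np.pi),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _place_sparse(specs, frame_shape, rng, margin=4.0):
    rows, cols = frame_shape
    placed = []
    for spec in specs:
        r = max(spec.a, spec.b) * (1 + spec.wobble_amp)
        for _ in range(2000):
            cx = rng.uniform(r + 1, cols - 2 - r)
            cy = rng.uniform(r + 1, rows - 2 - r)
            ok = all(
                np.hypot(cx - p.center[0], cy - p.center[1])
                > r + max(p.a, p.b) * (1 + p.wobble_amp) + margin
                for p in placed
            )
            if ok:
                placed.append(replace(spec, center=(cx, cy)))
                break
        else:
            raise ValidationError(
                f"cannot place {len(specs)} non-touching cells in frame {frame_shape}"
            )
    return placed, []


def _inner_radius(spec: SyntheticCellSpec) -> float:
    """Radius the boundary is guaranteed to reach in every direction."""
    return min(spec.a, spec.b) * (1.0 - spec.wobble_amp)


def _place_touching(specs, frame_shape, rng):
    """Lay cells out in left-to-right chains; consecutive cells overlap slightly.

    Centers are spaced at 95% of the summed guaranteed inner radii, so
    consecutive masks are certain to be in contact regardless of wobble phase;
    non-consecutive cells stay well separated.
    """
    rows, cols = frame_shape
    placed: list[SyntheticCellSpec] = []
    adjacency: list[tuple[str, str]] = []
    x = y = None
    row_height = 0.0
    prev = None
    for spec in specs:
        r = max(spec.a, spec.b) * (1 + spec.wobble_amp)
        if x is None or x + 2 * r > cols - 2:
            y = (r + 2) if y is None else y + row_height + 2 * r + 6
            x = r + 2
            row_height = 0.0
            prev = None
        else:
            x = x + (_inner_radius(prev) + _inner_radius(spec)) * 0.95
        if y + r > rows - 2:
            raise ValidationError("frame too small for the requested touching layout")
        placed.append(replace(spec, center=(x, y)))
        if prev is not None:
            adjacency.append((prev.cell_id, spec.cell_id))
        prev = placed[-1]
        row_height = max(row_height, r)
    return placed, adjacency


def rosette_specs(
    n_neighbors: int,
    cell_radius: float = 22.0,
    n_planes: int = 9,
    frame_shape: tuple[int, int] = (256, 256),
    base_intensity: float = 100.0,
    seed: int = 0,
) -> tuple[list[SyntheticCellSpec], list[tuple[str, str]]]:
    """A central circular cell with ``n_neighbors`` touching petals around it.

    Construction for maximum-neighbor-count scenarios (up to 6 petals fit
    without petal-petal contact at equal radii... petals closer than 60
    degrees apart would touch each other, so n_neighbors <= 5 keeps the
    designed adjacency star-shaped).
    """
    if not 1 <= n_neighbors <= 5:
        raise ValidationError("rosette supports 1..5 neighbors")
    rows, cols = frame_shape
    cx, cy = (cols - 1) / 2.0, (rows - 1) / 2.0
    rng = np.random.default_rng(seed)
    center = SyntheticCellSpec(
        cell_id="center",
        a=cell_radius,
        b=cell_radius,
        center=(cx, cy),
        n_planes=n_planes,
        base_intensity=base_intensity,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    specs = [center]
    adjacency = []
    dist = 2 * cell_radius * 0.95  # guaranteed overlap with the center
    for i in range(n_neighbors):
        ang = 2 * np.pi * i / max(n_neighbors, 3)
        petal = SyntheticCellSpec(
            cell_id=f"petal{i}",
            a=cell_radius,
            b=cell_radius,
            center=(cx + dist * np.cos(ang), cy + dist * np.sin(ang)),
            n_planes=n_planes,
            base_intensity=base_intensity,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        specs.append(petal)
        adjacency.append(("center", petal.cell_id))
    return specs, adjacency


def generate_field(
    n_cells: int,
    shape_mix: float = 0.3,
    packing: str = "sparse",
    treatment: str = "isotonic",
    seed: int = 0,
    out_dir=None,
    channels: tuple[str, ...] = ("DIC",),
    frame_shape: tuple[int, int] = (512, 512),
    n_planes: int = 21,
    cell_radius: float = 30.0,
    base_intensity: float = 100.0,
    noise_sd: float = 5.0,
    field_id: str | None = None,
    dz_um: float = 0.4,
    dxy_um: float = 0.1,
):
    """Generate a whole field; optionally write it in the formats the readers expect.

    ``shape_mix`` is the probability a cell is drawn from the asymmetric class.
    ``packing='sparse'`` places cells with no contacts; ``'touching'`` lays
    them out in chains of touching cells with known adjacency.  The treatment
    scales cell size and imposes the per-channel gradient presets via
    :func:`osmotic_transform`.

    Returns ``(manifest, stacks, rois, masks, truth)``; when ``out_dir`` is
    given, TIFFs, ROI JSON, a YAML manifest and a ground-truth JSON are
    written there and the manifest paths point at them.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    if not 0.0 <= shape_mix <= 1.0:
        raise ValidationError("shape_mix must be in [0, 1]")
    if packing not in ("sparse", "touching"):
        raise ValidationError(f"unknown packing {packing!r}")
    rng = np.random.default_rng(seed)
    field_id = field_id or f"{treatment}_f{seed}"
    base_specs = []
    for i in range(n_cells):
        asym = bool(rng.random() < shape_mix)
        spec = _random_cell_spec(
            f"c{i:03d}", rng, asym, cell_radius, n_planes, base_intensity, noise_sd
        )
        base_specs.append(
            osmotic_transform(spec, treatment, channels=channels)
        )
    if packing == "sparse":
        placed, adjacency = _place_sparse(base_specs, frame_shape, rng)
    else:
        placed, adjacency = _place_touching(base_specs, frame_shape, rng)

    field_vox = {
        ch: np.zeros((n_planes, *frame_shape), dtype=np.float32) for ch in channels
    }
    rois, masks = [], []
    truth_cells: dict[str, dict] = {}
    for spec in placed:
        stacks, mask, roi, truth = generate_cell(
            spec, frame_shape, channels=channels, dz_um=dz_um, dxy_um=dxy_um
        )
        for ch in channels:
            np.maximum(field_vox[ch], stacks[ch].voxels, out=field_vox[ch])
        rois.append(roi)
        masks.append(mask)
        truth_cells[spec.cell_id] = truth
    stacks = {
        ch: Stack(voxels=field_vox[ch], channel_label=ch, dz_um=dz_um, dxy_um=dxy_um)
        for ch in channels
    }
    truth = GroundTruth(cells=truth_cells, adjacency=adjacency)

    if out_dir is None:
        manifest = FieldManifest(
            field_id=field_id,
            treatment=treatment,
            nacl_mM=TREATMENT_NACL_MM[treatment],
            stack_paths={ch: f"{field_id}_{ch}.tif" for ch in channels},
            roi_path=f"{field_id}_rois.json",
            dz_um=dz_um,
            dxy_um=dxy_um,
        )
        return manifest, stacks, rois, masks, truth

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack_paths = {}
    for ch in channels:
        p = out_dir / f"{field_id}_{ch}.tif"
        write_stack(stacks[ch], p)
        stack_paths[ch] = p.name
    roi_path = out_dir / f"{field_id}_rois.json"
    write_rois(rois, roi_path)
    manifest = FieldManifest(
        field_id=field_id,
        treatment=treatment,
        nacl_mM=TREATMENT_NACL_MM[treatment],
        stack_paths=stack_paths,
        roi_path=roi_path.name,
        dz_um=dz_um,
        dxy_um=dxy_um,
    )
    write_manifest(manifest, out_dir / f"{field_id}_manifest.yaml")
    truth.to_json(out_dir / f"{field_id}_truth.json")
    return manifest, stacks, rois, masks, truth
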