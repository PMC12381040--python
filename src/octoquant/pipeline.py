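"""Field -> cell -> metrics -> population orchestration.

`quantify_field` turns one field (stacks + ROIs) into per-cell records:
morphology, octant/half voxel partitions, raw APVs per region and channel,
then the per-field/per-channel normalization that equates the highest octant
APV to 1.  `aggregate_populations` pools records over (treatment,
shape_class, channel), makes the per-axis polarity calls, builds octant NAPV
histograms, flags contributing octants and assembles the signed
percent-difference heatmap matrix.  `run_pipeline` drives the whole thing
from a config (reading manifests or simulating fields) and writes the CSV /
PNG / JSON outputs; identical config + seed reproduces the CSVs byte for
byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics
from .io import (
    CellRecord,
    FieldManifest,
    ValidationError,
    cell_table,
    read_manifest,
    read_rois,
    read_stack,
)
from .morphology import (
    centroid as mask_centroid,
    circularity,
    classify_shape,
    rasterize_mask,
    total_pixel_number,
)
from .neighborhood import contact_graph, neighbor_census
from .partition import axis_halves, octant_labels
from .synthetic import generate_field

logger = logging.getLogger("octoquant")

__all__ = ["PipelineConfig", "PopulationReport", "quantify_field", "aggregate_populations", "run_pipeline", "render_heatmap"]

_OCT_REGIONS = [f"oct{k}" for k in range(1, 9)]
_HALF_REGIONS = {
    "z": ("apical", "basolateral"),
    "x": ("x_prog", "x_reg"),
    "y": ("y_prog", "y_reg"),
}
_CSV_FLOAT = "%.9g"


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, serializable to/from YAML.

    Exactly one of ``manifests`` (paths to field manifests) or ``simulate``
    (keyword arguments for :func:`octoquant.synthetic.generate_field`, plus an
    optional ``treatments`` list and ``n_fields`` per treatment) must be set.
    """

    manifests: list[str] = field(default_factory=list)
    simulate: dict = field(default_factory=dict)
    circularity_threshold: float = 0.8
    alpha: float = 0.05
    bin_width: float = 0.1
    overlap_theta: float = 0.8
    contact_tolerance_px: int = 1
    z_orientation: str = "high"
    histogram_mode: str = "sum"
    holm_correction: bool = False
    dz_um: float | None = None
    dxy_um: float | None = None
    out_dir: str = "octoquant_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.circularity_threshold <= 1:
            raise ValidationError("circularity threshold must be in (0, 1]")
        if not 0 < self.overlap_theta <= 1:
            raise ValidationError("overlap theta must be in (0, 1]")
        if self.contact_tolerance_px < 0:
            raise ValidationError("contact tolerance must be >= 0")
        if self.z_orientation not in ("high", "low"):
            raise ValidationError("z_orientation must be 'high' or 'low'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PopulationReport:
    cells: pd.DataFrame
    polarity: pd.DataFrame
    census: pd.DataFrame
    contributing: pd.DataFrame
    overlap: pd.DataFrame
    heatmap: pd.DataFrame
    tpn_summary: pd.DataFrame
    metadata: dict


# ---------------------------------------------------------------------------
# per-field quantification


def load_field(manifest_path):
    """Read a manifest and everything it points to."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    stacks = {
        ch: read_stack(base / p, channel_label=ch, dz_um=manifest.dz_um, dxy_um=manifest.dxy_um)
        for ch, p in manifest.stack_paths.items()
    }
    rois = read_rois(base / manifest.roi_path, field_id=manifest.field_id)
    return manifest, stacks, rois


def quantify_field(
    manifest: FieldManifest,
    stacks: dict,
    rois: list,
    config: PipelineConfig | None = None,
):
    """Quantify every cell of one field on every channel.

    Returns ``(records, masks, shape_classes)``.  Cells whose ROI cannot be
    rasterized are skipped with a log entry; the per-field/per-channel
    normalization (highest octant APV -> 1) fills each record's ``napv``.
    """
    config = config or PipelineConfig()
    if not stacks:
        raise ValidationError(f"field {manifest.field_id!r}: no channels")
    ref = next(iter(stacks.values()))
    n_planes, frame = ref.n_planes, ref.frame_shape
    for ch, st in stacks.items():
        if st.voxels.shape != (n_planes, *frame):
            raise ValidationError(f"channel {ch!r} shape differs from the field's")

    records: list[CellRecord] = []
    masks, shape_classes = [], {}
    for roi in rois:
        try:
            mask = rasterize_mask(roi, frame, n_planes)
        except ValidationError as err:
            logger.warning("field %s: skipping cell %s (%s)", manifest.field_id, roi.cell_id, err)
            continue
        circ = circularity(roi)
        sclass = classify_shape(circ, config.circularity_threshold)
        cen = mask_centroid(mask)
        tpn = total_pixel_number(mask)
        labeling = octant_labels(mask, cen, z_orientation=config.z_orientation)
        halves = {ax: axis_halves(mask, cen, ax, z_orientation=config.z_orientation) for ax in "xyz"}
        masks.append(mask)
        shape_classes[roi.cell_id] = sclass
        for ch, stack in stacks.items():
            apv = {"whole": metrics.region_apv(stack, mask.mask3d)}
            for k in range(1, 9):
                apv[f"oct{k}"] = metrics.region_apv(stack, labeling.region_mask(k))
            for ax, (pname, rname) in _HALF_REGIONS.items():
                apv[pname] = metrics.region_apv(stack, halves[ax].progressive)
                apv[rname] = metrics.region_apv(stack, halves[ax].regressive)
            records.append(
                CellRecord(
                    field_id=manifest.field_id,
                    cell_id=roi.cell_id,
                    channel_label=ch,
                    circularity=circ,
                    shape_class=sclass,
                    centroid=cen,
                    tpn=tpn,
                    apv=apv,
                )
            )
    if not records:
        logger.warning("field %s: zero valid cells, skipped", manifest.field_id)
        return [], masks, shape_classes

    # normalization scope: one field, one channel; octant APVs set the scale
    for ch in stacks:
        ch_records = [r for r in records if r.channel_label == ch]
        top = max(r.apv[reg] for r in ch_records for reg in _OCT_REGIONS)
        if top == 0:
            raise ValidationError(f"field {manifest.field_id!r} channel {ch!r} is all zero")
        for r in ch_records:
            r.napv = {reg: v / top for reg, v in r.apv.items()}
    logger.info("field %s: %d cells, %d channels", manifest.field_id, len(shape_classes), len(stacks))
    return records, masks, shape_classes


# ---------------------------------------------------------------------------
# population aggregation


def _holm(pvals: list[float], alpha: float) -> list[bool]:
    """Holm step-down: returns per-test rejection decisions."""
    order = np.argsort(pvals)
    m = len(pvals)
    reject = [False] * m
    for rank, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def aggregate_populations(records: list[CellRecord], treatments: dict[str, str], config: PipelineConfig):
    """Pool per-cell records into population tables.

    ``treatments`` maps field_id -> treatment label.  Populations are keyed
    (treatment, shape_class, channel); each contributes one polarity call per
    axis, octant NAPV histograms with contributing-octant flags, octant
    overlap-vs-rest values and one signed heatmap entry per axis.
    """
    df = cell_table(records)
    df["treatment"] = df["field_id"].map(treatments)
    polarity_rows, contrib_rows, overlap_rows, heat_rows, tpn_rows = [], [], [], [], []
    for (treat, sclass, ch), grp in df.groupby(["treatment", "shape_class", "channel"]):
        pop = (treat, sclass, ch)
        if len(grp) < 2:
            logger.warning("population %s has < 2 cells; skipped", pop)
            continue
        tpn_per_cell = grp.drop_duplicates("cell_id")["tpn"]
        tpn_rows.append(
            {
                "treatment": treat,
                "shape_class": sclass,
                "channel": ch,
                "n_cells": len(tpn_per_cell),
                "tpn_mean": tpn_per_cell.mean(),
                "tpn_se": tpn_per_cell.std(ddof=1) / np.sqrt(len(tpn_per_cell)),
            }
        )
        for axis in "zyx":
            pname, rname = _HALF_REGIONS[axis]
            call = metrics.call_polarity(
                grp[f"napv_{pname}"].to_numpy(),
                grp[f"napv_{rname}"].to_numpy(),
                axis=axis,
                population=pop,
                alpha=config.alpha,
            )
            signed = call.magnitude_pct if call.mean_progressive >= call.mean_regressive else -call.magnitude_pct
            polarity_rows.append(
                {
                    "treatment": treat,
                    "shape_class": sclass,
                    "channel": ch,
                    "axis": axis,
                    "direction": call.direction,
                    "magnitude_pct": call.magnitude_pct,
                    "signed_pct": signed,
                    "p_value": call.p_value,
                    "t_statistic": call.t_statistic,
                    "n_cells": call.n_cells,
                    "mean_progressive": call.mean_progressive,
                    "mean_regressive": call.mean_regressive,
                }
            )
            heat_rows.append(
                {
                    "row": f"{treat}/{sclass}",
                    "column": f"{ch}/{axis}",
                    "signed_pct": signed,
                }
            )
        hists = {
            k: metrics.apv_histogram(
                grp[f"napv_oct{k}"].to_numpy(),
                bin_width=config.bin_width,
                region=f"oct{k}",
                mode=config.histogram_mode,
            )
            for k in range(1, 9)
        }
        contributing = metrics.contributing_octants(hists, theta=config.overlap_theta)
        contrib_rows.append(
            {
                "treatment": treat,
                "shape_class": sclass,
                "channel": ch,
                "contributing_octants": ",".join(map(str, contributing)),
                "theta": config.overlap_theta,
            }
        )
        for k in range(1, 9):
            others = [hists[j] for j in range(1, 9) if j != k]
            w = np.array([h.n_cells for h in others], dtype=float)
            pooled = metrics.ApvHistogram(
                region="rest",
                bin_edges=hists[k].bin_edges,
                freq=sum(wi * h.freq for wi, h in zip(w, others)) / w.sum(),
                n_cells=int(w.sum()),
            )
            overlap_rows.append(
                {
                    "treatment": treat,
                    "shape_class": sclass,
                    "channel": ch,
                    "octant": k,
                    "overlap_vs_rest": metrics.overlap_area(hists[k], pooled),
                }
            )
    polarity = pd.DataFrame(polarity_rows)
    if config.holm_correction and len(polarity):
        reject = _holm(polarity["p_value"].tolist(), config.alpha)
        polarity["holm_significant"] = reject
        nil = ~np.asarray(reject)
        polarity.loc[nil, "direction"] = "nil"
    heat = (
        pd.DataFrame(heat_rows)
        .pivot(index="row", columns="column", values="signed_pct")
        .sort_index(axis=0)
        .sort_index(axis=1)
        if heat_rows
        else pd.DataFrame()
    )
    return (
        df,
        polarity.sort_values(["treatment", "shape_class", "channel", "axis"]).reset_index(drop=True),
        pd.DataFrame(contrib_rows).sort_values(["treatment", "shape_class", "channel"]).reset_index(drop=True),
        pd.DataFrame(overlap_rows).sort_values(["treatment", "shape_class", "channel", "octant"]).reset_index(drop=True),
        heat,
        pd.DataFrame(tpn_rows).sort_values(["treatment", "shape_class", "channel"]).reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# full runs


def _simulated_fields(config: PipelineConfig):
    sim = dict(config.simulate)
    treatments = sim.pop("treatments", ["isotonic"])
    n_fields = int(sim.pop("n_fields", 1))
    fields = []
    rng = np.random.default_rng(config.seed)
    for treat in treatments:
        for i in range(n_fields):
            seed = int(rng.integers(0, 2**31 - 1))
            manifest, stacks, rois, masks, truth = generate_field(
                treatment=treat, seed=seed, field_id=f"{treat}_f{i}", **sim
            )
            fields.append((manifest, stacks, rois))
    return fields


def run_pipeline(config: PipelineConfig) -> PopulationReport:
    """Execute the full workflow and write all output files.

    Outputs under ``config.out_dir``: cells.csv, polarity.csv, census.csv,
    contributing_octants.csv, overlap.csv, heatmap_matrix.csv, tpn_summary.csv,
    heatmap.png and run_metadata.json.  Deterministic given config + seed.
    """
    if bool(config.manifests) == bool(config.simulate):
        raise ValidationError("config must set exactly one of manifests / simulate")
    if config.manifests:
        fields = [load_field(p) for p in config.manifests]
    else:
        fields = _simulated_fields(config)

    all_records: list[CellRecord] = []
    treatments: dict[str, str] = {}
    census_frames = []
    for manifest, stacks, rois in fields:
        records, masks, shape_classes = quantify_field(manifest, stacks, rois, config)
        if not records:
            continue
        all_records.extend(records)
        treatments[manifest.field_id] = manifest.treatment
        graph = contact_graph(
            masks, shape_classes, tolerance_px=config.contact_tolerance_px, field_id=manifest.field_id
        )
        census = neighbor_census(graph)
        summary = census.summary.copy()
        summary.insert(0, "treatment", manifest.treatment)
        summary.insert(0, "field_id", manifest.field_id)
        census_frames.append(summary)
    if not all_records:
        raise ValidationError("no valid cells in any field")

    cells, polarity, contributing, overlap, heat, tpn_summary = aggregate_populations(
        all_records, treatments, config
    )
    census = pd.concat(census_frames, ignore_index=True)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells.to_csv(out / "cells.csv", index=False, float_format=_CSV_FLOAT)
    polarity.to_csv(out / "polarity.csv", index=False, float_format=_CSV_FLOAT)
    census.to_csv(out / "census.csv", index=False, float_format=_CSV_FLOAT)
    contributing.to_csv(out / "contributing_octants.csv", index=False, float_format=_CSV_FLOAT)
    overlap.to_csv(out / "overlap.csv", index=False, float_format=_CSV_FLOAT)
    heat.to_csv(out / "heatmap_matrix.csv", float_format=_CSV_FLOAT)
    tpn_summary.to_csv(out / "tpn_summary.csv", index=False, float_format=_CSV_FLOAT)
    metadata = {
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "n_fields": len(fields),
        "n_cells": int(cells.drop_duplicates(["field_id", "cell_id"]).shape[0]),
    }
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=1, sort_keys=True))
    report = PopulationReport(
        cells=cells,
        polarity=polarity,
        census=census,
        contributing=contributing,
        overlap=overlap,
        heatmap=heat,
        tpn_summary=tpn_summary,
        metadata=metadata,
    )
    if len(heat):
        render_heatmap(report, out / "heatmap.png")
    return report


def render_heatmap(report: PopulationReport, path) -> Path:
    """Render the signed percent-difference matrix (basolateral negative, apical
    positive) as an image; the CSV twin is exactly ``report.heatmap``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.heatmap.empty:
        raise ValidationError("empty report: nothing to render")
    mat = report.heatmap
    fig, ax = plt.subplots(
        figsize=(1.2 + 0.55 * mat.shape[1], 1.2 + 0.5 * mat.shape[0])
    )
    vmax = max(abs(np.nanmin(mat.values)), abs(np.nanmax(mat.values)), 1e-9)
    im = ax.imshow(mat.values, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="signed % difference (apical/progressive > 0)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
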