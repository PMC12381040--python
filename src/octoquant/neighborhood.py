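"""Cell-contact graph and neighbor census of a field.

Two cells are neighbors when their boundaries are in contact.  On rasterized
mid-section masks the tightest digital analogue is adopted: cell i touches
cell j when mask_i dilated by ``tolerance_px`` pixels (default 1) intersects
mask_j.  Cells clipped by the frame border have incompletely observed
neighborhoods and are excluded from the census by default (they still appear
as graph nodes, flagged).

The census mirrors the pie-chart layout used to summarize neighborhoods: per
focal shape class, the proportions of asymmetric-neighbor links,
symmetric-neighbor links and isolated cells, plus the per-cell distribution
of neighbor counts by neighbor class and the maximum observed counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from .io import ValidationError
from .morphology import CellMask

__all__ = ["ContactGraph", "NeighborCensus", "contact_graph", "neighbor_census"]


@dataclass
class ContactGraph:
    """Undirected contact graph: nodes carry shape_class, edges are unordered pairs."""

    field_id: str
    nodes: dict[str, str]  # cell_id -> shape_class
    edges: set[frozenset]
    clipped: set[str] = field(default_factory=set)  # cells touching the frame border

    def neighbors(self, cell_id: str) -> list[str]:
        return sorted(
            next(iter(e - {cell_id}))
            for e in self.edges
            if cell_id in e
        )

    def degree(self, cell_id: str) -> int:
        return sum(1 for e in self.edges if cell_id in e)


@dataclass
class NeighborCensus:
    """Per-focal-class neighbor tabulation (long format) plus summary fractions."""

    field_id: str
    table: pd.DataFrame  # cell_id, shape_class, n_asymmetric, n_symmetric
    summary: pd.DataFrame  # focal_class, category, fraction / max counts


def _touches_border(mask2d: np.ndarray) -> bool:
    return bool(
        mask2d[0, :].any() or mask2d[-1, :].any() or mask2d[:, 0].any() or mask2d[:, -1].any()
    )


def contact_graph(
    masks: list[CellMask],
    shape_classes: dict[str, str],
    tolerance_px: int = 1,
    field_id: str = "",
) -> ContactGraph:
    """Build the contact graph from mid-section masks on a shared frame.

    An edge joins cells whose masks come within ``tolerance_px`` pixels
    (Chebyshev) of each other.  ROIs that already overlap at tolerance 0 are
    reported with a warning but still form an edge.
    """
    if tolerance_px < 0:
        raise ValidationError("tolerance must be >= 0")
    frames = {m.mask2d.shape for m in masks}
    if len(frames) > 1:
        raise ValidationError("all masks must share one frame")
    ids = [m.cell_id for m in masks]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate cell ids in field")
    dilated = []
    for m in masks:
        d = m.mask2d
        if tolerance_px:
            # full 3x3 structure: Chebyshev tolerance, diagonal contacts count
            d = binary_dilation(m.mask2d, structure=np.ones((3, 3), bool), iterations=tolerance_px)
        dilated.append(d)
    edges: set[frozenset] = set()
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if np.any(dilated[i] & masks[j].mask2d):
                if np.any(masks[i].mask2d & masks[j].mask2d):
                    warnings.warn(
                        f"ROIs {ids[i]!r} and {ids[j]!r} overlap; treating as contact",
                        stacklevel=2,
                    )
                edges.add(frozenset((ids[i], ids[j])))
    nodes = {}
    for cid in ids:
        if cid not in shape_classes:
            raise ValidationError(f"cell {cid!r} has no shape class")
        nodes[cid] = shape_classes[cid]
    clipped = {m.cell_id for m in masks if _touches_border(m.mask2d)}
    return ContactGraph(field_id=field_id, nodes=nodes, edges=edges, clipped=clipped)


def neighbor_census(graph: ContactGraph, include_clipped: bool = False) -> NeighborCensus:
    """Tabulate neighbor counts by shape class for each (non-clipped) focal cell.

    The summary gives, per focal class, the pie fractions over
    {asymmetric-neighbor links, symmetric-neighbor links, isolated cells}
    (which sum to 1) and the maximum observed neighbor count of each class.
    """
    focal_ids = sorted(
        cid for cid in graph.nodes if include_clipped or cid not in graph.clipped
    )
    if not focal_ids:
        raise ValidationError("no focal cells to census")
    rows = []
    for cid in focal_ids:
        nbrs = graph.neighbors(cid)
        rows.append(
            {
                "cell_id": cid,
                "shape_class": graph.nodes[cid],
                "n_asymmetric": sum(graph.nodes[n] == "asymmetric" for n in nbrs),
                "n_symmetric": sum(graph.nodes[n] == "symmetric" for n in nbrs),
            }
        )
    table = pd.DataFrame(rows)
    summaries = []
    for focal, grp in table.groupby("shape_class"):
        a_links = int(grp["n_asymmetric"].sum())
        s_links = int(grp["n_symmetric"].sum())
        isolated = int(((grp["n_asymmetric"] + grp["n_symmetric"]) == 0).sum())
        total = a_links + s_links + isolated
        for cat, val in (
            ("asymmetric_neighbor_links", a_links),
            ("symmetric_neighbor_links", s_links),
            ("isolated_cells", isolated),
        ):
            summaries.append(
                {
                    "focal_class": focal,
                    "category": cat,
                    "count": val,
                    "fraction": val / total if total else np.nan,
                }
            )
        summaries.append(
            {
                "focal_class": focal,
                "category": "max_asymmetric_neighbors",
                "count": int(grp["n_asymmetric"].max()),
                "fraction": np.nan,
            }
        )
        summaries.append(
            {
                "focal_class": focal,
                "category": "max_symmetric_neighbors",
                "count": int(grp["n_symmetric"].max()),
                "fraction": np.nan,
            }
        )
    return NeighborCensus(
        field_id=graph.field_id, table=table, summary=pd.DataFrame(summaries)
    )
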