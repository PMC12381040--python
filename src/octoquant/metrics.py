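"""Intensity metrics: APVs, field normalization, polarity calls, frequency
distributions and overlap (uniformity) measures.

The average pixel value (APV) of a region is the arithmetic mean intensity
over its voxels.  To cancel acquisition settings (laser power, gain, PMT
voltage), APVs are normalized per field *and* per channel: the highest octant
APV among all cells of that field/channel is equated to 1 and everything else
scales accordingly (NAPV).  Polarity along an axis is a statistically
significant difference (two-tailed unpaired Student's t, p < 0.05) between
the per-cell NAPVs of the two halves; its magnitude is the percent difference
of the population mean half-NAPVs.  Population uniformity is measured by the
common area under two sum-to-1 frequency distributions of octant NAPVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Stack, ValidationError
from .stats import ttest_two_tailed

__all__ = [
    "RegionApv",
    "PolarityCall",
    "ApvHistogram",
    "region_apv",
    "normalize_field",
    "percent_difference",
    "fold_change",
    "call_polarity",
    "apv_histogram",
    "overlap_area",
    "contributing_octants",
]

#: Direction labels per axis: (progressive-side name, regressive-side name).
AXIS_DIRECTIONS = {
    "z": ("apical", "basolateral"),
    "x": ("x_progressive", "x_regressive"),
    "y": ("y_progressive", "y_regressive"),
}


@dataclass
class RegionApv:
    cell_id: str
    channel_label: str
    region: str
    apv: float
    napv: float | None = None


@dataclass
class PolarityCall:
    """Outcome of the half-vs-half comparison for one population and axis.

    ``direction`` is 'nil' when the t-test is not significant at ``alpha``;
    the magnitude (percent difference of the greater over the lesser mean
    half-NAPV) is reported either way.
    """

    population: tuple
    axis: str
    direction: str
    magnitude_pct: float
    p_value: float
    t_statistic: float
    n_cells: int
    mean_progressive: float
    mean_regressive: float


@dataclass
class ApvHistogram:
    region: str
    bin_edges: np.ndarray
    freq: np.ndarray
    n_cells: int


def region_apv(stack: Stack, voxel_set: np.ndarray) -> float:
    """Mean intensity over a boolean voxel set of the stack's shape."""
    voxel_set = np.asarray(voxel_set, dtype=bool)
    if voxel_set.shape != stack.voxels.shape:
        raise ValidationError("voxel set shape does not match the stack")
    n = voxel_set.sum()
    if n == 0:
        raise ValidationError("region APV undefined for an empty region")
    return float(stack.voxels[voxel_set].mean(dtype=np.float64))


def normalize_field(apvs):
    """Divide APVs by their maximum: the field's highest octant APV maps to 1.

    Accepts an array (returns an array) or a dict (returns a dict with the
    same keys).  All inputs must share one normalization scope — one field,
    one channel.
    """
    if isinstance(apvs, dict):
        keys = list(apvs)
        values = np.asarray([apvs[k] for k in keys], dtype=float)
        out = normalize_field(values)
        return {k: float(v) for k, v in zip(keys, out)}
    values = np.asarray(apvs, dtype=float)
    if values.size == 0 or np.any(values < 0):
        raise ValidationError("APVs must be a non-empty, non-negative collection")
    top = values.max()
    if top == 0:
        raise ValidationError("cannot normalize an all-zero field")
    return values / top


def percent_difference(a: float, b: float) -> float:
    """100 * (a - b) / b: how much denser ``a`` is than the reference ``b``."""
    if not b > 0:
        raise ValidationError("reference value must be positive")
    return 100.0 * (a - b) / b


def fold_change(a: float, b: float) -> float:
    """a / b; equals 1 + percent_difference(a, b)/100."""
    if not b > 0:
        raise ValidationError("reference value must be positive")
    return a / b


def call_polarity(
    progressive,
    regressive,
    axis: str,
    population: tuple = (),
    alpha: float = 0.05,
) -> PolarityCall:
    """Call polarity along ``axis`` from per-cell half-NAPVs of a population.

    ``progressive``/``regressive`` are the per-cell NAPVs of the two halves
    (apical/basolateral for z).  The two samples are compared with the
    two-tailed unpaired equal-variance t-test; when p < alpha the direction is
    the half with the greater mean, otherwise 'nil'.  Magnitude is always the
    percent difference of the greater population mean over the lesser.
    """
    if axis not in AXIS_DIRECTIONS:
        raise ValidationError(f"unknown axis {axis!r}")
    prog = np.asarray(progressive, dtype=float)
    reg = np.asarray(regressive, dtype=float)
    if len(prog) < 2 or len(reg) < 2:
        raise ValidationError("polarity call needs >= 2 cells per half sample")
    t, p = ttest_two_tailed(prog, reg)
    mp, mr = prog.mean(), reg.mean()
    hi, lo = max(mp, mr), min(mp, mr)
    magnitude = percent_difference(hi, lo) if lo > 0 else float("inf")
    prog_name, reg_name = AXIS_DIRECTIONS[axis]
    if p < alpha and mp != mr:
        direction = prog_name if mp > mr else reg_name
    else:
        direction = "nil"
    return PolarityCall(
        population=population,
        axis=axis,
        direction=direction,
        magnitude_pct=float(magnitude),
        p_value=p,
        t_statistic=t,
        n_cells=len(prog),
        mean_progressive=float(mp),
        mean_regressive=float(mr),
    )


def apv_histogram(
    napvs, bin_width: float = 0.1, region: str = "", mode: str = "sum"
) -> ApvHistogram:
    """Frequency-normalized distribution of NAPVs over [0, 1].

    ``bin_width`` must divide 1 evenly.  ``mode='sum'`` (default) divides
    counts by the total so frequencies sum to 1 — the convention under which
    the common-area overlap is bounded by 1.  ``mode='max'`` divides by the
    tallest bin instead.
    """
    values = np.asarray(napvs, dtype=float)
    if values.size == 0:
        raise ValidationError("empty population")
    if np.any(values < 0) or np.any(values > 1):
        raise ValidationError("NAPVs must lie in [0, 1]")
    n_bins = 1.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValidationError("bin_width must divide 1 evenly")
    edges = np.linspace(0.0, 1.0, int(round(n_bins)) + 1)
    counts, _ = np.histogram(values, bins=edges)  # top edge inclusive
    if mode == "sum":
        freq = counts / counts.sum()
    elif mode == "max":
        freq = counts / counts.max()
    else:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    return ApvHistogram(region=region, bin_edges=edges, freq=freq, n_cells=int(values.size))


def overlap_area(h1: ApvHistogram, h2: ApvHistogram) -> float:
    """Common area under two binned distributions: sum of bin-wise minima.

    Symmetric, in [0, 1]; equals 1 iff the histograms are identical and 0 iff
    their supports are disjoint.  For sum-to-1 histograms this is
    1 - total-variation distance.
    """
    if h1.bin_edges.shape != h2.bin_edges.shape or not np.allclose(
        h1.bin_edges, h2.bin_edges
    ):
        raise ValidationError("histograms must share bin edges")
    return float(np.minimum(h1.freq, h2.freq).sum())


def contributing_octants(
    histograms: dict[int, ApvHistogram], theta: float = 0.8
) -> list[int]:
    """Octants whose NAPV distribution deviates from the pooled rest.

    Octant ``o`` contributes when the common area between its histogram and
    the cell-count-weighted pool of the other seven falls below ``theta``.
    The threshold is a free parameter of the analysis (default 0.8) and should
    be reported alongside any result.
    """
    if sorted(histograms) != list(range(1, 9)):
        raise ValidationError("need histograms for all octants 1..8")
    edges = histograms[1].bin_edges
    out = []
    for o in range(1, 9):
        others = [histograms[k] for k in range(1, 9) if k != o]
        weights = np.array([h.n_cells for h in others], dtype=float)
        pooled_freq = sum(w * h.freq for w, h in zip(weights, others)) / weights.sum()
        pooled = ApvHistogram(
            region=f"pool_excl_{o}",
            bin_edges=edges,
            freq=pooled_freq,
            n_cells=int(weights.sum()),
        )
        if overlap_area(histograms[o], pooled) < theta:
            out.append(o)
    return out
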