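"""Height-heterogeneity indices over transect clips of a canopy height model.

The height variation hypothesis (HVH) predicts that grassland patches with
more vertical structure host more flowering-plant and pollinator species.
Its operational statistic is a scalar height-heterogeneity (HH) value
computed over the CHM pixels of a sampling transect. Four indices are
provided:

* ``rao_q`` — Rao's quadratic entropy with uniform pixel weights and the
  1-D Euclidean (absolute) distance between pixel heights:
  ``Q = (1/N^2) * sum_{i,j} |x_i - x_j|``. With these choices Q is the
  mean absolute pairwise difference of the heights (the Gini mean
  difference with ordered-pair normalization).
* ``coefficient_of_variation`` — 100 * SD / mean.
* ``berger_parker`` — dominance of the modal height class, n_max / N.
* ``simpson_d`` — concentration sum p_i^2 over height classes (1 = fully
  homogeneous; note this is the dominance form, not its complement).

Berger–Parker and Simpson's D act on categorical abundances, so continuous
heights are first discretized into fixed-width bins (default 1 cm);
without binning virtually every float pixel is unique and both indices
degenerate to 1/N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import shapely

__all__ = [
    "TransectGeometry",
    "ValueSample",
    "BinnedSample",
    "HeterogeneityMeasure",
    "EmptySampleError",
    "UndefinedStatisticError",
    "INDEX_NAMES",
    "extract_transect_values",
    "rao_q",
    "coefficient_of_variation",
    "bin_values",
    "berger_parker",
    "simpson_d",
    "compute_hh",
]

INDEX_NAMES = ("rao_q", "cv", "berger_parker", "simpson_d")


class EmptySampleError(ValueError):
    """No valid raster cells fall inside the requested geometry."""


class UndefinedStatisticError(ValueError):
    """The statistic is undefined on this sample (e.g. CV with mean <= 0)."""


@dataclass(frozen=True)
class TransectGeometry:
    """A rectangular field transect defined by its center line and width.

    Default field design: a 150 m x 1 m strip, divided into three equal
    50 m sections along its length.
    """

    transect_id: str
    start: tuple[float, float]
    end: tuple[float, float]
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("transect width must be positive")
        if self.length <= 0:
            raise ValueError("transect length must be positive")

    @property
    def length(self) -> float:
        dx = self.end[0] - self.start[0]
        dy = self.end[1] - self.start[1]
        return float(np.hypot(dx, dy))

    def polygon(self) -> shapely.Polygon:
        """The transect rectangle (possibly rotated) as a shapely polygon."""
        line = shapely.LineString([self.start, self.end])
        return line.buffer(self.width / 2.0, cap_style="flat")

    def sections(self, n: int = 3) -> list["TransectGeometry"]:
        """Split into ``n`` equal-length sub-transects along the center line."""
        sx, sy = self.start
        ex, ey = self.end
        out = []
        for k in range(n):
            t0, t1 = k / n, (k + 1) / n
            out.append(
                TransectGeometry(
                    transect_id=f"{self.transect_id}_s{k + 1}",
                    start=(sx + t0 * (ex - sx), sy + t0 * (ey - sy)),
                    end=(sx + t1 * (ex - sx), sy + t1 * (ey - sy)),
                    width=self.width,
                )
            )
        return out


@dataclass(frozen=True)
class ValueSample:
    """Finite CHM heights extracted from raster cells for one transect."""

    values: np.ndarray
    source: tuple[str, float] | None = None  # (transect_id, resolution)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64).ravel()
        if arr.size == 0:
            raise EmptySampleError("value sample is empty")
        if not np.all(np.isfinite(arr)):
            raise ValueError("value sample contains non-finite entries")
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class BinnedSample:
    """Category counts after fixed-width binning of a ValueSample."""

    counts: np.ndarray  # counts per occupied bin, order irrelevant
    bin_width: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64).ravel()
        if arr.size == 0 or np.any(arr <= 0):
            raise ValueError("binned sample must have positive counts")
        object.__setattr__(self, "counts", arr)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_max(self) -> int:
        return int(self.counts.max())


@dataclass(frozen=True)
class HeterogeneityMeasure:
    """One (transect, index, resolution) -> HH value record."""

    transect_id: str
    index_name: str
    resolution: float
    value: float
    bin_width: float | None = None
    n_cells: int = 0


def extract_transect_values(raster, transect: TransectGeometry) -> ValueSample:
    """Values of all non-nodata cells whose centers fall inside the transect.

    Membership is decided by the cell CENTER against the (possibly rotated)
    transect rectangle; a center exactly on the boundary counts as inside.
    Cells are returned in row-major raster order.
    """
    poly = transect.polygon()
    xmin, ymin, xmax, ymax = poly.bounds
    xs, ys = raster.cell_centers()
    ci = np.nonzero((xs >= xmin) & (xs <= xmax))[0]
    ri = np.nonzero((ys >= ymin) & (ys <= ymax))[0]
    if ci.size == 0 or ri.size == 0:
        raise EmptySampleError(
            f"no cell centers inside transect {transect.transect_id}"
        )
    gx, gy = np.meshgrid(xs[ci], ys[ri])
    inside = shapely.intersects_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
    sub = raster.values[np.ix_(ri, ci)]
    vals = sub[inside & np.isfinite(sub)]
    if vals.size == 0:
        raise EmptySampleError(
            f"no valid (non-nodata) cells inside transect {transect.transect_id}"
        )
    return ValueSample(vals, source=(transect.transect_id, raster.cell_size))


def rao_q(sample: ValueSample) -> float:
    """Rao's Q with uniform weights and absolute-difference distance.

    Computed via the sorted identity
    ``sum_{i<j} (x_(j) - x_(i)) = sum_k (2k - N - 1) x_(k)`` (k 1-based),
    doubled for ordered pairs and divided by N^2 — O(N log N) instead of
    the O(N^2) double sum. A single value has no pairs, so Q = 0.
    """
    x = np.sort(sample.values)
    n = x.size
    if n == 1:
        return 0.0
    k = np.arange(1, n + 1, dtype=np.float64)
    total = np.sum((2.0 * k - n - 1.0) * x)
    return float(2.0 * total / (n * n))


def rao_q_generalized(sample: ValueSample, distance: str = "euclidean") -> float:
    """Rao's Q under a chosen pairwise distance (O(N^2); diagnostic use).

    ``distance='euclidean'`` matches :func:`rao_q`; ``'half_squared'`` uses
    d_ij = (x_i - x_j)^2 / 2, under which Q collapses exactly to the
    population variance of the sample.
    """
    x = sample.values
    diff = x[:, None] - x[None, :]
    if distance == "euclidean":
        d = np.abs(diff)
    elif distance == "half_squared":
        d = 0.5 * diff**2
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return float(d.sum() / (x.size**2))


def coefficient_of_variation(sample: ValueSample) -> float:
    """CV = 100 * SD / mean, with the sample (N-1) standard deviation."""
    if sample.n < 2:
        raise UndefinedStatisticError("CV requires at least 2 values")
    mean = float(np.mean(sample.values))
    if mean <= 0:
        raise UndefinedStatisticError(f"CV undefined for non-positive mean ({mean:g})")
    sd = float(np.std(sample.values, ddof=1))
    return 100.0 * sd / mean


def bin_values(sample: ValueSample, bin_width: float) -> BinnedSample:
    """Discretize heights into fixed-width classes: category of x is floor(x / w)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    cats = np.floor(sample.values / bin_width).astype(np.int64)
    _, counts = np.unique(cats, return_counts=True)
    return BinnedSample(counts=counts, bin_width=bin_width)


def berger_parker(binned: BinnedSample) -> float:
    """Berger–Parker dominance: relative abundance of the modal class."""
    return binned.n_max / binned.n


def simpson_d(binned: BinnedSample, complement: bool = False) -> float:
    """Simpson concentration D = sum p_i^2 (or 1 - D with ``complement``).

    D is reported in its dominance form: 1 means all pixels share one
    height class; the minimum 1/(number of classes) is reached at a uniform
    class distribution.
    """
    p = binned.counts / binned.n
    d = float(np.sum(p * p))
    return 1.0 - d if complement else d


def compute_hh(
    chm,
    transect: TransectGeometry,
    index_name: str,
    bin_width: float | None = 0.01,
    simpson_complement: bool = False,
) -> HeterogeneityMeasure:
    """Extract the transect's CHM cells and evaluate one heterogeneity index.

    ``bin_width`` is required for the abundance-based indices
    (berger_parker, simpson_d) and ignored for rao_q and cv, which operate
    on the raw continuous heights.
    """
    if index_name not in INDEX_NAMES:
        raise ValueError(f"unknown index {index_name!r}; expected one of {INDEX_NAMES}")
    sample = extract_transect_values(chm, transect)
    used_bin: float | None = None
    if index_name == "rao_q":
        value = rao_q(sample)
    elif index_name == "cv":
        value = coefficient_of_variation(sample)
    else:
        if bin_width is None:
            raise ValueError(f"{index_name} requires a bin_width")
        binned = bin_values(sample, bin_width)
        used_bin = bin_width
        if index_name == "berger_parker":
            value = berger_parker(binned)
        else:
            value = simpson_d(binned, complement=simpson_complement)
    return HeterogeneityMeasure(
        transect_id=transect.transect_id,
        index_name=index_name,
        resolution=chm.cell_size,
        value=value,
        bin_width=used_bin,
        n_cells=sample.n,
    )


def compute_hh_table(
    chm,
    transects: Iterable[TransectGeometry],
    indices: Iterable[str] = INDEX_NAMES,
    bin_width: float = 0.01,
    per_section: bool = False,
) -> list[HeterogeneityMeasure]:
    """All requested indices for all transects (optionally per 50 m section)."""
    out = []
    for tr in transects:
        targets = tr.sections() if per_section else [tr]
        for t in targets:
            for idx in indices:
                out.append(compute_hh(chm, t, idx, bin_width=bin_width))
    return out
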