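"""Bright-field spheroid morphometry.

Segments one spheroid per well image and derives the size/shape metrics used
to follow spheroid growth: minimum Feret diameter ``d`` (used as the
diameter), segmented area ``A``, sphere volume ``V = (4/3)*pi*(d/2)**3`` and
circularity ``C = pi*(d/2)**2 / A`` (1 = perfect circle, -> 0 = elongated).
Quality control is an FDR-based robust outlier screen (ROUT, Q = 1% by
default) on any single measurement, plus flags for wells where more than one
object survives filtering (the "two or more spheroids per well" failure
mode).

The segmentation pipeline mirrors a CellProfiler-style object identification:
invert the bright-field image, Otsu-threshold the inverted intensities, fill
interior holes, delete speckles below 10 px equivalent-circle diameter
(debris and stray cells), and keep the largest remaining component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.stats import t as t_dist
from skimage.segmentation import find_boundaries


class SegmentationError(RuntimeError):
    """No object survived thresholding and speckle filtering."""


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two populated bins; no threshold exists."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BrightfieldImage:
    """A single-well bright-field image plus acquisition metadata.

    Parameters
    ----------
    pixels : 2-D ndarray
        Grayscale intensities (integer or float dtype).
    scale_um_per_px : float
        Microscope scale. Pixel measurements are converted with it: length
        in um = px * scale, area in um^2 = px^2 * scale^2.
    well_id : str
        Plate coordinate (e.g. ``"B2"``); spheroids are tracked across
        timepoints by well position.
    timepoint_days : int
        Days in culture at acquisition.
    batch_id : str
        Culture batch / cell line label.
    """

    pixels: np.ndarray
    scale_um_per_px: float = 1.0
    well_id: str = ""
    timepoint_days: int = 0
    batch_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise ValueError("image intensities must be finite")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale_um_per_px must be positive")


@dataclass
class SegmentationResult:
    mask: np.ndarray                 # boolean, all surviving objects
    n_objects_after_filter: int
    primary_object: np.ndarray       # boolean, largest object only
    overlay: np.ndarray              # RGB uint8, primary outline on input
    multi_object_flag: bool
    image: BrightfieldImage


@dataclass
class SpheroidMeasurement:
    """Per-spheroid morphometry record.

    ``d`` is the minimum Feret diameter in um, ``r = d/2``, ``A`` the
    segmented area in um^2, ``V = (4/3) pi r^3`` the derived sphere volume in
    um^3 and ``C = pi r^2 / A`` the circularity ratio.
    """

    batch_id: str
    well_id: str
    timepoint_days: int
    d_px: float
    A_px: float
    d: float
    r: float
    A: float
    V: float
    C: float
    n_objects: int
    multi_object_flag: bool
    outlier_flag: bool = False


@dataclass(frozen=True)
class OutlierConfig:
    """ROUT screening parameters: Q is the FDR level (fraction)."""

    Q: float = 0.01
    min_n: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.Q < 1:
            raise ValueError("Q must be in (0, 1)")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def invert_image(img: BrightfieldImage) -> BrightfieldImage:
    """Invert intensities so the dark spheroid becomes the bright foreground.

    Integer images invert against the dtype's representable maximum
    (``max_representable - pixel``); float images against their own maximum.
    Applying the operation twice restores the input.
    """
    px = img.pixels
    if np.issubdtype(px.dtype, np.integer):
        inverted = np.iinfo(px.dtype).max - px
    else:
        inverted = px.max() - px
    return replace(img, pixels=inverted)


def image_histogram(pixels: np.ndarray, n_bins: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram over the image's representable intensity range.

    Integer images are binned over [0, dtype max]; float images are min-max
    scaled first. Returns ``(counts, bin_edges)``.
    """
    px = np.asarray(pixels)
    if np.issubdtype(px.dtype, np.integer):
        lo, hi = 0.0, float(np.iinfo(px.dtype).max)
    else:
        lo, hi = float(px.min()), float(px.max())
        if hi == lo:
            hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(px, bins=edges)
    return counts, edges


def otsu_threshold(counts: np.ndarray) -> int:
    """Otsu threshold of a 256-bin histogram.

    Returns the bin index ``t`` maximizing the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2`` for the split {bins <= t} vs {bins > t};
    ties resolve to the lowest maximizing index.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("histogram must be 1-D")
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("need at least two populated bins")

    bins = np.arange(counts.size)
    w0 = np.cumsum(counts)                      # mass of class {<= t}
    w1 = w0[-1] - w0
    m0 = np.cumsum(counts * bins)
    m1 = m0[-1] - m0
    valid = (w0 > 0) & (w1 > 0)
    var_between = np.zeros_like(w0)
    var_between[valid] = w0[valid] * w1[valid] * (
        m0[valid] / w0[valid] - m1[valid] / w1[valid]
    ) ** 2
    return int(np.argmax(var_between))          # argmax returns lowest tie


def remove_speckles(
    mask: np.ndarray, min_diameter_px: float = 10.0
) -> tuple[np.ndarray, int]:
    """Delete connected components smaller than a diameter cutoff.

    A component's size is its equivalent-circle diameter
    ``2*sqrt(area/pi)``; components strictly below ``min_diameter_px`` are
    removed (cell debris, stray cells). Returns the filtered mask and the
    number of removed components.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask.copy(), 0
    areas = np.bincount(labels.ravel())[1:]
    eq_diam = 2.0 * np.sqrt(areas / np.pi)
    small = np.flatnonzero(eq_diam < min_diameter_px) + 1
    out = mask.copy()
    if small.size:
        out[np.isin(labels, small)] = False
    return out, int(small.size)


def segment_spheroid(
    img: BrightfieldImage, min_speckle_diameter_px: float = 10.0
) -> SegmentationResult:
    """Identify the primary spheroid object in a bright-field image.

    Pipeline: invert -> Otsu binarize (foreground = above threshold on the
    inverted image) -> fill interior holes -> remove sub-10 px speckles ->
    keep the largest component (equal-area tie: lowest label). A
    multi-object flag is raised when more than one component survives the
    speckle filter, which encodes the split-spheroid failure mode.
    """
    inv = invert_image(img)
    counts, edges = image_histogram(inv.pixels)
    t = otsu_threshold(counts)
    # foreground = bins strictly above t, i.e. intensity above the upper
    # edge of bin t
    fg = inv.pixels.astype(float) > edges[t + 1]
    fg = ndimage.binary_fill_holes(fg)
    fg, _ = remove_speckles(fg, min_speckle_diameter_px)

    labels, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationError(
            f"no object survived filtering (well {img.well_id!r})"
        )
    areas = np.bincount(labels.ravel())[1:]
    primary_label = int(np.argmax(areas)) + 1    # lowest label on ties
    primary = labels == primary_label

    overlay = _render_overlay(img.pixels, primary)
    return SegmentationResult(
        mask=fg,
        n_objects_after_filter=int(n),
        primary_object=primary,
        overlay=overlay,
        multi_object_flag=n > 1,
        image=img,
    )


def _render_overlay(pixels: np.ndarray, primary: np.ndarray) -> np.ndarray:
    """Outline of the primary object drawn in red on the input image."""
    px = pixels.astype(float)
    lo, hi = px.min(), px.max()
    gray = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
    rgb = np.stack([gray, gray, gray], axis=-1)
    outline = find_boundaries(primary, mode="outer")
    rgb[outline] = [1.0, 0.0, 0.0]
    return (rgb * 255).astype(np.uint8)


def _corner_hull_points(mask: np.ndarray) -> np.ndarray:
    """Corner points of boundary pixels: the exact convex-hull generator set
    of the union-of-unit-squares object a binary mask represents."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    boundary = mask & ~ndimage.binary_erosion(mask)
    rr, cc = np.nonzero(boundary)
    centers = np.column_stack([cc, rr]).astype(float)   # (x, y)
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    return (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 2)


def feret_diameters(mask: np.ndarray) -> tuple[float, float]:
    """(min, max) Feret (caliper) diameters of a binary object, in px.

    Treats each pixel as a unit square; the minimum caliper width of the
    convex hull is attained flush with a hull edge, so rotating calipers
    over hull-edge normals is exact. The maximum is the largest pairwise
    distance between hull vertices.
    """
    pts = _corner_hull_points(mask)
    if len(np.unique(pts, axis=0)) < 3:
        # single pixel: unit square
        return 1.0, float(np.sqrt(2.0))
    hull = ConvexHull(pts)
    v = pts[hull.vertices]                       # counterclockwise
    edges = np.roll(v, -1, axis=0) - v
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 0
    normals = np.column_stack([-edges[keep, 1], edges[keep, 0]]) / lengths[keep, None]
    proj = v @ normals.T                         # vertices x edge-normals
    widths = proj.max(axis=0) - proj.min(axis=0)
    d_min = float(widths.min())
    diffs = v[:, None, :] - v[None, :, :]
    d_max = float(np.sqrt((diffs ** 2).sum(axis=-1).max()))
    return d_min, d_max


def min_feret_diameter(mask: np.ndarray) -> float:
    """Minimum Feret (caliper) diameter of a binary object in pixels."""
    return feret_diameters(mask)[0]


def measure_spheroid(
    seg: SegmentationResult, scale_um_per_px: float | None = None
) -> SpheroidMeasurement:
    """Derive d, r, A, V, C from a segmentation's primary object.

    d_px is the minimum Feret diameter, A_px the pixel count; both convert
    by the microscope scale. Volume assumes a sphere of radius d/2 and
    circularity compares the circle of that radius against the measured
    area.
    """
    img = seg.image
    scale = img.scale_um_per_px if scale_um_per_px is None else scale_um_per_px
    if scale <= 0:
        raise ValueError("scale must be positive")
    if not seg.primary_object.any():
        raise ValueError("primary object is empty")
    d_px = min_feret_diameter(seg.primary_object)
    a_px = float(seg.primary_object.sum())
    d = d_px * scale
    a = a_px * scale ** 2
    r = d / 2.0
    return SpheroidMeasurement(
        batch_id=img.batch_id,
        well_id=img.well_id,
        timepoint_days=img.timepoint_days,
        d_px=d_px,
        A_px=a_px,
        d=d,
        r=r,
        A=a,
        V=(4.0 / 3.0) * np.pi * r ** 3,
        C=np.pi * r ** 2 / a,
        n_objects=seg.n_objects_after_filter,
        multi_object_flag=seg.multi_object_flag,
    )


def rout_outlier_screen(
    values: np.ndarray, cfg: OutlierConfig = OutlierConfig()
) -> np.ndarray:
    """Flag outliers in one measurement with the ROUT procedure, constant model.

    Robust location is the sample median; the robust residual scale (RSDR)
    is the 68.27th percentile of |residuals| scaled by N/(N-1). Points are
    ranked by |residual| descending and tested sequentially: point i (1-based)
    is an outlier when its two-tailed t P-value (df = N-1) falls below
    alpha_i = Q*(N-i+1)/N; testing stops at the first non-rejection. Q is
    the target false-discovery rate.

    Returns a boolean flag per value. Samples smaller than ``cfg.min_n``
    are not screened (all flags False, warning emitted).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    flags = np.zeros(n, dtype=bool)
    if n < cfg.min_n:
        warnings.warn(
            f"n={n} < min_n={cfg.min_n}: outlier screening skipped",
            stacklevel=2,
        )
        return flags

    resid = values - np.median(values)
    abs_resid = np.abs(resid)
    rsdr = np.percentile(abs_resid, 68.27) * n / (n - 1)
    if rsdr == 0:
        flags[abs_resid > 0] = True
        return flags

    order = np.argsort(-abs_resid, kind="stable")
    p = 2.0 * t_dist.sf(abs_resid[order] / rsdr, df=n - 1)
    for i, idx in enumerate(order, start=1):
        alpha_i = cfg.Q * (n - i + 1) / n
        if p[i - 1] < alpha_i:
            flags[idx] = True
        else:
            break
    return flags


def pair_timepoints(
    records_t1: pd.DataFrame, records_t2: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pair spheroid measurements across two timepoints by plate position.

    Inner join on (batch_id, well_id); wells flagged as outliers or
    multi-object at either timepoint, or missing from one table, are
    excluded. Returns the paired table (columns suffixed _t1/_t2) and
    exclusion counts.

    Raises
    ------
    ValueError
        If the two tables share no (batch_id, well_id) keys at all.
    """
    keys = ["batch_id", "well_id"]
    merged = records_t1.merge(records_t2, on=keys, suffixes=("_t1", "_t2"))
    if merged.empty:
        raise ValueError("no wells are present at both timepoints")

    bad = (
        merged["outlier_flag_t1"] | merged["outlier_flag_t2"]
        | merged["multi_object_flag_t1"] | merged["multi_object_flag_t2"]
    )
    counts = {
        "paired": int((~bad).sum()),
        "excluded_outlier": int(
            (merged["outlier_flag_t1"] | merged["outlier_flag_t2"]).sum()
        ),
        "excluded_multi_object": int(
            (merged["multi_object_flag_t1"] | merged["multi_object_flag_t2"]).sum()
        ),
        "unmatched_t1": int(len(records_t1) - len(merged)),
        "unmatched_t2": int(len(records_t2) - len(merged)),
    }
    return merged.loc[~bad].reset_index(drop=True), counts


def measurements_to_frame(measurements: list[SpheroidMeasurement]) -> pd.DataFrame:
    """Tabulate measurement records with the standard output columns."""
    return pd.DataFrame(
        [
            {
                "batch_id": m.batch_id,
                "well_id": m.well_id,
                "timepoint_days": m.timepoint_days,
                "d_px": m.d_px,
                "A_px": m.A_px,
                "d_um": m.d,
                "A_um2": m.A,
                "V_um3": m.V,
                "circularity": m.C,
                "n_objects": m.n_objects,
                "multi_object_flag": m.multi_object_flag,
                "outlier_flag": m.outlier_flag,
            }
            for m in measurements
        ]
    )
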