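"""Brightfield array morphometry: organoid segmentation and size statistics.

Organoids grown in microwell arrays appear as dark quasi-circular disks on
a bright background in stitched brightfield mosaics. Segmentation follows a
background-invariant recipe: median smoothing, normalization by a
large-kernel Gaussian estimate of the illumination field, Otsu thresholding
of the inverted image, hole filling, connected components, and per-object
quality control (size range, circularity, border contact).

Sizes are reported as area-equivalent diameters, ``2 sqrt(A / pi)`` scaled
by the pixel size — robust to boundary roughness and equal to the diameter
for near-circular objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import DataError

__all__ = [
    "SegmentationParams",
    "OrganoidDetection",
    "SizeSummary",
    "segment_brightfield",
    "summarize_sizes",
    "detections_to_frame",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the brightfield segmentation recipe."""

    median_size_px: int = 3
    background_sigma_um: float = 400.0
    min_diameter_um: float = 50.0
    max_diameter_um: float = 450.0
    min_circularity: float = 0.6


@dataclass
class OrganoidDetection:
    """One segmented organoid-like object in a brightfield array image.

    ``qc_flags`` collects the reasons an object is excluded from size
    statistics: ``border`` (touches the image edge), ``size`` (equivalent
    diameter outside the accepted range), ``circularity`` (merged or
    irregular object). Circularity is ``4 pi A / P^2`` capped at 1.05 for
    discretization effects.
    """

    id: int
    centroid_x: float
    centroid_y: float
    area_px2: float
    equivalent_diameter_um: float
    circularity: float
    well_row: int | None = None
    well_col: int | None = None
    qc_flags: tuple = ()

    @property
    def passes_qc(self) -> bool:
        return len(self.qc_flags) == 0


@dataclass
class SizeSummary:
    """Per-experiment and cross-experiment organoid size statistics.

    ``per_experiment`` is indexed by experiment id with columns
    n / mean_um / sd_um / cv_pct / median_um / min_um / max_um. The
    cross-experiment spread metric is
    ``100 * (max experiment mean - min experiment mean) / mean of means``.
    """

    per_experiment: pd.DataFrame
    grand_mean_um: float
    inter_experiment_variation_pct: float
    n_total: int


def _background_field(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Large-scale illumination field: Gaussian blur computed on a decimated
    copy (the field is smooth by construction, so decimation is lossless)."""
    stride = max(1, int(sigma_px // 16))
    if stride == 1:
        return ndimage.gaussian_filter(image, sigma=sigma_px)
    small = image[::stride, ::stride]
    bg_small = ndimage.gaussian_filter(small, sigma=sigma_px / stride)
    zoom = (image.shape[0] / bg_small.shape[0], image.shape[1] / bg_small.shape[1])
    return ndimage.zoom(bg_small, zoom, order=1, mode="nearest", grid_mode=True)


def segment_brightfield(
    image: np.ndarray,
    pixel_size_um: float,
    params: SegmentationParams | None = None,
    well_grid: tuple | None = None,
) -> list:
    """Detect organoids in a 2-D brightfield array image.

    Parameters
    ----------
    image : 2-D array
        Single-channel brightfield image (bright background, dark organoids).
    pixel_size_um : float
        Lateral pixel size in µm.
    params : SegmentationParams, optional
    well_grid : (origin_yx_px, pitch_px), optional
        When given, each detection is assigned the nearest microwell grid
        node; detections further than half a pitch keep ``None`` indices.

    Returns
    -------
    list of :class:`OrganoidDetection`, border-touching and out-of-spec
    objects flagged (not removed).
    """
    params = params or SegmentationParams()
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise DataError("brightfield image must be 2-D")
    if pixel_size_um <= 0:
        raise DataError("pixel_size_um must be > 0")
    if image.size == 0 or not np.isfinite(image).all():
        return []

    med = ndimage.median_filter(image, size=params.median_size_px)
    bg = _background_field(med, params.background_sigma_um / pixel_size_um)
    norm = med / np.maximum(bg, 1e-12)
    inv = 1.0 - norm
    # degenerate (flat / empty) image: no organoid-depth dips to threshold
    if float(inv.max()) < 0.1:
        return []
    thr = threshold_otsu(inv)
    mask = inv > max(thr, 0.1)
    mask = ndimage.binary_fill_holes(mask)

    min_area_px = np.pi * (params.min_diameter_um / 2.0) ** 2 / pixel_size_um**2
    max_area_px = np.pi * (params.max_diameter_um / 2.0) ** 2 / pixel_size_um**2
    labels = label(mask)
    detections = []
    h, w = image.shape
    for i, region in enumerate(regionprops(labels)):
        if region.area < min_area_px / 4:
            continue  # speckle
        flags = []
        minr, minc, maxr, maxc = region.bbox
        if minr == 0 or minc == 0 or maxr == h or maxc == w:
            flags.append("border")
        if not (min_area_px <= region.area <= max_area_px):
            flags.append("size")
        perim = max(region.perimeter_crofton, 1e-9)
        circularity = min(4.0 * np.pi * region.area / perim**2, 1.05)
        if circularity < params.min_circularity:
            flags.append("circularity")
        cy, cx = region.centroid
        well_row = well_col = None
        if well_grid is not None:
            (oy, ox), pitch = well_grid
            r = (cy - oy) / pitch
            c = (cx - ox) / pitch
            rr, cc = round(r), round(c)
            if np.hypot(r - rr, c - cc) <= 0.5:
                well_row, well_col = int(rr), int(cc)
        detections.append(
            OrganoidDetection(
                id=len(detections),
                centroid_x=float(cx),
                centroid_y=float(cy),
                area_px2=float(region.area),
                equivalent_diameter_um=2.0 * np.sqrt(region.area / np.pi) * pixel_size_um,
                circularity=float(circularity),
                well_row=well_row,
                well_col=well_col,
                qc_flags=tuple(flags),
            )
        )
    return detections


def detections_to_frame(detections) -> pd.DataFrame:
    """Detections as a tidy table (one row per object)."""
    return pd.DataFrame(
        [
            {
                "organoid_id": d.id,
                "well_row": d.well_row,
                "well_col": d.well_col,
                "centroid_x_px": d.centroid_x,
                "centroid_y_px": d.centroid_y,
                "area_px2": d.area_px2,
                "equivalent_diameter_um": d.equivalent_diameter_um,
                "circularity": d.circularity,
                "qc_flags": ";".join(d.qc_flags),
            }
            for d in detections
        ]
    )


def _diameters(group) -> np.ndarray:
    vals = []
    for item in group:
        if isinstance(item, OrganoidDetection):
            if item.passes_qc:
                vals.append(item.equivalent_diameter_um)
        else:
            vals.append(float(item))
    return np.asarray(vals, dtype=float)


def summarize_sizes(groups: dict) -> SizeSummary:
    """Size-homogeneity statistics per experiment and across experiments.

    ``groups`` maps experiment ids to sequences of
    :class:`OrganoidDetection` (QC-failing detections are excluded) or to
    raw diameter arrays in µm. SDs use the n-1 denominator. Raises
    :class:`DataError` naming any experiment left without passing
    detections.
    """
    rows = {}
    for exp, group in groups.items():
        d = _diameters(group)
        if d.size == 0:
            raise DataError(f"experiment {exp!r} has no QC-passing detections")
        sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
        mean = float(np.mean(d))
        rows[exp] = {
            "n": int(d.size),
            "mean_um": mean,
            "sd_um": sd,
            "cv_pct": 100.0 * sd / mean if mean > 0 else np.nan,
            "median_um": float(np.median(d)),
            "min_um": float(d.min()),
            "max_um": float(d.max()),
        }
    per_exp = pd.DataFrame.from_dict(rows, orient="index")
    per_exp.index.name = "experiment"
    means = per_exp["mean_um"].to_numpy()
    grand = float(means.mean())
    spread = 100.0 * (means.max() - means.min()) / grand if grand > 0 else np.nan
    return SizeSummary(
        per_experiment=per_exp,
        grand_mean_um=grand,
        inter_experiment_variation_pct=float(spread),
        n_total=int(per_exp["n"].sum()),
    )
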