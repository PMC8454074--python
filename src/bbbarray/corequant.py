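"""Confocal core-intensity quantification for organoid transport assays.

Implements the measurement chain used for permeability and transcytosis
readouts: locate the organoid bottom in a z-stack, select the core window
(by default 25 µm above the bottom, 3.5 µm deep), maximum-intensity project
it, segment the organoid cross-section on the nuclei channel, shrink the
mask concentrically to 75% of its area, and report the mean tracer
intensity inside that core ROI. Rectangular line profiles across organoids
are provided for layer-localization figures.

Coordinates are 0-based pixel indices; z index 0 is the slice nearest the
coverslip. Intensities are raw (no background subtraction): background is
assessed via non-treated control organoids downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from .errors import AnalysisError, ConfigurationError, DataError

__all__ = [
    "ConfocalStack",
    "CoreROI",
    "CoreMeasurement",
    "LineProfile",
    "find_organoid_bottom",
    "select_core_substack",
    "project_max",
    "segment_cross_section",
    "shrink_to_fraction",
    "measure_core",
    "line_profile",
    "measure_stack",
    "DEFAULT_CHANNEL_NAMES",
]

#: OME channel names written/expected by default, keyed by role.
DEFAULT_CHANNEL_NAMES = {"nuclei": "DAPI", "endothelial": "PGP", "tracer": "TRACER"}


@dataclass
class ConfocalStack:
    """Multichannel confocal voxel grid with channel roles and voxel sizes.

    ``data`` has axes (channel, z, y, x); ``channel_roles`` maps role names
    (``nuclei``, ``endothelial``, ``tracer``) to channel indices. At least
    one tracer channel is required.
    """

    data: np.ndarray
    channel_roles: dict
    voxel_size_xy_um: float
    z_step_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DataError("stack data must have axes (channel, z, y, x)")
        if "tracer" not in self.channel_roles:
            raise DataError("a channel with role 'tracer' is required")
        n_ch = self.data.shape[0]
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < n_ch:
                raise DataError(f"channel index {idx} for role {role!r} out of range")
        if self.voxel_size_xy_um <= 0 or self.z_step_um <= 0:
            raise DataError("voxel sizes must be > 0")

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channel_roles:
            raise DataError(f"no channel with role {role!r}")
        return self.data[self.channel_roles[role]]

    def to_tiff(self, path: str | Path) -> None:
        """Write as OME-TIFF with channel names in the metadata."""
        role_by_idx = {v: k for k, v in self.channel_roles.items()}
        names = [
            DEFAULT_CHANNEL_NAMES.get(role_by_idx.get(i, ""), f"C{i}")
            for i in range(self.data.shape[0])
        ]
        tifffile.imwrite(
            str(path),
            self.data.astype(np.float32),
            ome=True,
            metadata={
                "axes": "CZYX",
                "Channel": {"Name": names},
                "PhysicalSizeX": self.voxel_size_xy_um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": self.voxel_size_xy_um,
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZ": self.z_step_um,
                "PhysicalSizeZUnit": "µm",
            },
        )

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        channel_names: dict | None = None,
        voxel_size_xy_um: float | None = None,
        z_step_um: float | None = None,
        metadata: dict | None = None,
    ) -> "ConfocalStack":
        """Read an OME-TIFF stack, resolving channel roles from OME names.

        ``channel_names`` maps roles to OME channel names (defaults to
        ``DEFAULT_CHANNEL_NAMES``); a sidecar YAML map produced by
        :func:`load_channel_map` can be passed instead.
        """
        channel_names = dict(channel_names or DEFAULT_CHANNEL_NAMES)
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
            names, px, pz = _parse_ome(tf)
        data = _to_czyx(data, axes)
        roles = {}
        for role, wanted in channel_names.items():
            for i, nm in enumerate(names):
                if nm == wanted:
                    roles[role] = i
        if "tracer" not in roles:
            raise DataError(
                f"could not resolve a tracer channel in {path} "
                f"(channel names found: {names})"
            )
        return cls(
            data=data,
            channel_roles=roles,
            voxel_size_xy_um=voxel_size_xy_um or px or 1.0,
            z_step_um=z_step_um or pz or 1.0,
            metadata=metadata or {},
        )


def _to_czyx(data: np.ndarray, axes: str) -> np.ndarray:
    axes = axes.upper()
    if data.ndim == 3:  # single channel
        data = data[None]
        axes = "C" + axes
    order = [axes.index(a) for a in "CZYX" if a in axes]
    if len(order) != 4:
        raise DataError(f"cannot interpret TIFF axes {axes!r} as CZYX")
    return np.transpose(data, order)


def _parse_ome(tf) -> tuple:
    names: list = []
    px = pz = None
    if tf.ome_metadata:
        meta = tifffile.xml2dict(tf.ome_metadata)
        try:
            pixels = meta["OME"]["Image"]["Pixels"]
            chans = pixels.get("Channel", [])
            if isinstance(chans, dict):
                chans = [chans]
            names = [c.get("Name", f"C{i}") for i, c in enumerate(chans)]
            px = pixels.get("PhysicalSizeX")
            pz = pixels.get("PhysicalSizeZ")
        except (KeyError, TypeError):
            pass
    return names, px, pz


def load_channel_map(path: str | Path) -> dict:
    """Load a sidecar YAML file mapping channel roles to OME channel names."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise DataError(f"channel map {path} must be a mapping of role -> name")
    return {str(k): str(v) for k, v in data.items()}


@dataclass
class CoreROI:
    """Full cross-section mask with its concentric core mask."""

    full_mask: np.ndarray
    core_mask: np.ndarray
    achieved_fraction: float
    depth_window_um: tuple | None = None

    def __post_init__(self) -> None:
        if np.any(self.core_mask & ~self.full_mask):
            raise AnalysisError("core mask must be contained in the full mask")


@dataclass
class CoreMeasurement:
    """Mean tracer intensity inside one organoid's core ROI."""

    organoid_id: object
    condition: str
    dose_nM: float
    time_min: float
    knockout: str
    core_mean: float
    core_area_px2: int
    achieved_fraction: float
    depth_window_um: tuple | None = None


@dataclass
class LineProfile:
    """Per-channel mean intensity along the width of a rectangular ROI."""

    distances_um: np.ndarray
    profiles: dict


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _foreground_threshold(volume: np.ndarray) -> float:
    """Global Otsu threshold, validated against pure-noise inputs.

    Raises :class:`AnalysisError` when the split does not separate a bright
    structure from background (foreground mean less than four background
    SDs above the background mean).
    """
    vmin, vmax = float(volume.min()), float(volume.max())
    if not np.isfinite(vmin) or vmax - vmin <= 1e-9:
        raise AnalysisError("no organoid found: image has no contrast")
    thr = threshold_otsu(volume)
    fg = volume > thr
    if not fg.any() or fg.all():
        raise AnalysisError("no organoid found: degenerate threshold")
    bg_mean = float(volume[~fg].mean())
    bg_sd = float(volume[~fg].std())
    fg_mean = float(volume[fg].mean())
    if fg_mean < bg_mean + 4.0 * bg_sd:
        raise AnalysisError("no organoid found: no foreground above background")
    return float(thr)


def find_organoid_bottom(stack: ConfocalStack, reference: str | None = None) -> int:
    """Index of the lowest z-slice where the organoid is present.

    The reference channel (endothelial if available, else nuclei) is
    smoothed, thresholded globally (Otsu), and the bottom is the lowest
    slice whose foreground area exceeds 10% of the maximum per-slice
    foreground area.
    """
    if reference is None:
        reference = "endothelial" if "endothelial" in stack.channel_roles else "nuclei"
    vol = stack.channel(reference).astype(np.float32)
    sig_xy = max(1.0, 1.0 / stack.voxel_size_xy_um)
    smooth = ndimage.gaussian_filter(vol, sigma=(1.0, sig_xy, sig_xy))
    thr = _foreground_threshold(smooth)
    areas = (smooth > thr).sum(axis=(1, 2))
    max_area = int(areas.max())
    if max_area == 0:
        raise AnalysisError("no organoid found: empty foreground")
    candidates = np.nonzero(areas >= 0.10 * max_area)[0]
    return int(candidates[0])


def select_core_substack(
    stack: ConfocalStack,
    bottom_index: int,
    offset_um: float = 25.0,
    span_um: float = 3.5,
) -> ConfocalStack:
    """Slices whose depth above the bottom slice lies in [offset, offset+span]."""
    dz = stack.z_step_um
    depths = (np.arange(stack.n_slices) - bottom_index) * dz
    eps = 1e-9
    keep = (depths >= offset_um - eps) & (depths <= offset_um + span_um + eps)
    available = depths[-1]
    if not keep.any() or available + eps < offset_um + span_um:
        raise ConfigurationError(
            f"stack too shallow: core window needs {offset_um + span_um:.1f} µm "
            f"above the bottom slice but only {max(available, 0):.1f} µm available"
        )
    meta = dict(stack.metadata)
    meta["depth_window_um"] = (offset_um, offset_um + span_um)
    return ConfocalStack(
        data=stack.data[:, keep],
        channel_roles=dict(stack.channel_roles),
        voxel_size_xy_um=stack.voxel_size_xy_um,
        z_step_um=dz,
        metadata=meta,
    )


def project_max(substack):
    """Maximum-intensity projection over z.

    Accepts a (z, y, x) array (returns a 2-D array) or a
    :class:`ConfocalStack` (returns a dict role -> 2-D array).
    """
    if isinstance(substack, ConfocalStack):
        return {role: substack.channel(role).max(axis=0) for role in substack.channel_roles}
    arr = np.asarray(substack)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise DataError("substack must be a non-empty (z, y, x) array")
    return arr.max(axis=0)


def segment_cross_section(
    mip: np.ndarray,
    pixel_size_um: float,
    min_diameter_um: float = 50.0,
) -> np.ndarray:
    """Segment the organoid cross-section from a (nuclei) MIP.

    Gaussian smooth -> Otsu -> fill holes -> keep largest component ->
    morphological closing. Raises :class:`AnalysisError` when no component
    reaches the minimum area (a disk of ``min_diameter_um``).
    """
    mip = np.asarray(mip, dtype=np.float32)
    if mip.ndim != 2:
        raise DataError("MIP must be 2-D")
    sigma = 2.0 / pixel_size_um
    smooth = ndimage.gaussian_filter(mip, sigma=sigma)
    thr = _foreground_threshold(smooth)
    mask = ndimage.binary_fill_holes(smooth > thr)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise AnalysisError("no organoid found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = labels == largest
    min_area = np.pi * (min_diameter_um / 2.0) ** 2 / pixel_size_um**2
    if mask.sum() < min_area:
        raise AnalysisError(
            f"no organoid found: largest component {int(mask.sum())} px below "
            f"minimum area {min_area:.0f} px"
        )
    mask = closing(mask, disk(2))
    return ndimage.binary_fill_holes(mask)


def shrink_to_fraction(full_mask: np.ndarray, fraction: float = 0.75) -> CoreROI:
    """Concentric core ROI covering ``fraction`` of the full mask area.

    The core is the set of pixels whose Euclidean distance to the
    background exceeds a level chosen over the distance transform's value
    distribution to minimize the deviation from the target area fraction.
    The construction is concentric and shape-following by design.
    """
    full_mask = np.asarray(full_mask, dtype=bool)
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    area = int(full_mask.sum())
    if area <= 100:
        raise AnalysisError(f"mask too small to shrink ({area} px; need > 100 px)")
    if fraction == 1.0:
        return CoreROI(full_mask, full_mask.copy(), 1.0)
    dt = ndimage.distance_transform_edt(full_mask)
    vals = np.sort(dt[full_mask])  # ascending
    # thresholding at vals[i] keeps the (area - i) pixels with dt >= vals[i];
    # restrict to distinct values so achieved counts are realizable
    distinct = np.ones(area, dtype=bool)
    distinct[1:] = vals[1:] > vals[:-1]
    idx = np.nonzero(distinct)[0]
    achieved = (area - idx) / area
    best = idx[np.argmin(np.abs(achieved - fraction))]
    level = vals[best]
    core = dt >= level
    achieved_fraction = core.sum() / area
    if abs(achieved_fraction - fraction) > 0.05:
        raise AnalysisError(
            f"mask cannot realize area fraction {fraction:.2f} "
            f"(best achievable {achieved_fraction:.2f})"
        )
    return CoreROI(full_mask, core, float(achieved_fraction))


def measure_core(
    tracer_mip: np.ndarray,
    roi: CoreROI,
    organoid_id=0,
    condition: str = "",
    dose_nM: float = float("nan"),
    time_min: float = float("nan"),
    knockout: str = "",
) -> CoreMeasurement:
    """Mean tracer intensity of the MIP inside the core ROI (raw, no
    background subtraction)."""
    tracer_mip = np.asarray(tracer_mip)
    if tracer_mip.shape != roi.core_mask.shape:
        raise DataError("image and ROI mask shapes differ")
    if not roi.core_mask.any():
        raise AnalysisError("empty core mask")
    return CoreMeasurement(
        organoid_id=organoid_id,
        condition=condition,
        dose_nM=dose_nM,
        time_min=time_min,
        knockout=knockout,
        core_mean=float(tracer_mip[roi.core_mask].mean()),
        core_area_px2=int(roi.core_mask.sum()),
        achieved_fraction=roi.achieved_fraction,
        depth_window_um=roi.depth_window_um,
    )


def line_profile(images, roi, pixel_size_um: float) -> LineProfile:
    """Mean intensity per x-column of a rectangular ROI, left to right.

    ``images`` is a 2-D array or a dict name -> 2-D array; ``roi`` is
    ``(x0, y0, width, height)`` in 0-based pixels with half-open intervals.
    Distances are µm from the left edge of the ROI.
    """
    if not isinstance(images, dict):
        images = {"intensity": images}
    x0, y0, w, h = (int(v) for v in roi)
    if w < 2 or h < 1:
        raise DataError("degenerate ROI: width must be >= 2 px, height >= 1 px")
    profiles = {}
    for name, img in images.items():
        img = np.asarray(img)
        if img.ndim != 2:
            raise DataError("line profile images must be 2-D")
        if x0 < 0 or y0 < 0 or x0 + w > img.shape[1] or y0 + h > img.shape[0]:
            raise DataError("ROI out of image bounds")
        profiles[name] = img[y0 : y0 + h, x0 : x0 + w].mean(axis=0)
    distances = np.arange(w, dtype=float) * pixel_size_um
    return LineProfile(distances_um=distances, profiles=profiles)


def measure_stack(
    stack: ConfocalStack,
    offset_um: float = 25.0,
    span_um: float = 3.5,
    fraction: float = 0.75,
    organoid_id=0,
) -> CoreMeasurement:
    """Full per-organoid pipeline: bottom, core window, MIP, segmentation,
    75%-area ROI, mean tracer intensity.

    Bottom finding prefers the endothelial channel and falls back to the
    nuclei channel when the endothelial marker is absent or empty (no-BEC
    controls).
    """
    try:
        bottom = find_organoid_bottom(stack)
    except AnalysisError:
        if "nuclei" not in stack.channel_roles:
            raise
        bottom = find_organoid_bottom(stack, reference="nuclei")
    sub = select_core_substack(stack, bottom, offset_um=offset_um, span_um=span_um)
    seg_role = "nuclei" if "nuclei" in sub.channel_roles else "tracer"
    mip_seg = project_max(sub.channel(seg_role))
    full = segment_cross_section(mip_seg, sub.voxel_size_xy_um)
    roi = shrink_to_fraction(full, fraction=fraction)
    roi.depth_window_um = (offset_um, offset_um + span_um)
    mip_tracer = project_max(sub.channel("tracer"))
    meta = stack.metadata
    return measure_core(
        mip_tracer,
        roi,
        organoid_id=organoid_id,
        condition=str(meta.get("condition", "")),
        dose_nM=float(meta.get("dose_nM", float("nan"))),
        time_min=float(meta.get("time_min", float("nan"))),
        knockout=str(meta.get("knockout", "")),
    )
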