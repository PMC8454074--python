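"""Synthetic blood-brain-barrier organoid assay generator.

Simulates the two image modalities the analysis pipeline consumes:

* 2-D brightfield microwell-array images (dark organoid disks with a bright
  halo on a bright array background) for size/homogeneity morphometry, and
* 3-channel confocal z-stacks (nuclei / endothelial marker / tracer) of
  single glass-mounted organoids for core-intensity transport assays.

A forward transport model generates the expected tracer level in the
organoid core for each assay condition:

* tracers excluded by the endothelial barrier (FITC-dextrans, non-targeting
  IgG, species-mismatched shuttle) stay at the autofluorescence baseline,
* paracellular tracers (free FITC; any tracer when no endothelial cells are
  present) add a constant leak amplitude, and
* receptor-targeted shuttles accumulate with one-phase association
  kinetics, ``I(t) = B + alpha * dose * (1 - exp(-k t))``.

Every generator output is a pure function of its configuration and seed;
ground-truth tables record the noise-free core level of each rendered
organoid so downstream measurements can be validated against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, stats

from .errors import ConfigurationError

__all__ = [
    "TransportParams",
    "OrganoidGeometry",
    "SimulationConfig",
    "Condition",
    "GROUND_TRUTH_COLUMNS",
    "forward_core_intensity",
    "render_confocal_stack",
    "render_brightfield_array",
    "sample_diameters",
    "simulate_core_measurements",
    "default_transport_params",
]

#: Condition kinds understood by the forward model.
KINDS = ("excluded", "paracellular", "shuttle")

GROUND_TRUTH_COLUMNS = [
    "organoid_id",
    "well_row",
    "well_col",
    "true_diameter_um",
    "condition",
    "dose_nM",
    "time_min",
    "true_core_mean",
    "background_mean",
]


@dataclass(frozen=True)
class TransportParams:
    """Forward-model parameters for one tracer/condition.

    baseline
        Core autofluorescence level (AU), present in every organoid.
    leak_amplitude
        Paracellular contribution reaching the core (AU), e.g. free FITC.
    alpha
        Dose coefficient of receptor-mediated accumulation (AU per nM).
    k_rate
        One-phase association rate (per minute).
    rim_amplitude
        Tracer signal bound/adsorbed at the organoid surface shell (AU).
    punctate
        Render half of the receptor-mediated core signal as puncta
        (vesicular appearance) without changing the core mean.
    puncta_density
        Puncta per µm^3 of core volume when ``punctate`` is set.
    """

    baseline: float = 10.0
    leak_amplitude: float = 0.0
    alpha: float = 0.0
    k_rate: float = 0.05
    rim_amplitude: float = 0.0
    punctate: bool = False
    puncta_density: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.leak_amplitude < 0 or self.alpha < 0:
            raise ConfigurationError("intensities and dose coefficients must be >= 0")
        if self.alpha > 0 and self.k_rate <= 0:
            raise ConfigurationError("k_rate must be > 0 when alpha > 0")
        if self.puncta_density < 0:
            raise ConfigurationError("puncta_density must be >= 0")


@dataclass(frozen=True)
class OrganoidGeometry:
    """Physical shape of one mounted organoid.

    Mounted organoids are modelled as oblate spheroids: the axial semi-axis
    is ``flattening`` times the lateral radius (glass slide + coverslip
    compression). The endothelial layer is a shell of constant relative
    thickness; everything inside the shell is the organoid interior where
    transported tracer distributes.
    """

    true_diameter: float = 235.0  # µm
    flattening: float = 0.5
    shell_thickness: float = 6.0  # µm
    core_radius_fraction: float = 0.7  # astrocyte-rich core (labelling only)

    def __post_init__(self) -> None:
        if self.true_diameter <= 0:
            raise ConfigurationError("true_diameter must be > 0")
        if not 0 < self.flattening <= 1:
            raise ConfigurationError("flattening must be in (0, 1]")
        if not 0 < self.shell_thickness < self.true_diameter / 2:
            raise ConfigurationError("shell_thickness must be < radius")
        if not 0 < self.core_radius_fraction < 1:
            raise ConfigurationError("core_radius_fraction must be in (0, 1)")

    @property
    def radius(self) -> float:
        return self.true_diameter / 2.0

    @property
    def axial_semiaxis(self) -> float:
        return self.radius * self.flattening


@dataclass(frozen=True)
class Condition:
    """Descriptor of one assay condition attached to rendered stacks."""

    name: str
    kind: str = "excluded"
    dose_nM: float = 0.0
    time_min: float = 240.0
    knockout: str = ""
    no_bec: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown condition kind {self.kind!r}")
        if self.dose_nM < 0 or self.time_min < 0:
            raise ConfigurationError("dose and time must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative description of a synthetic assay.

    Array geometry defaults follow the microwell plates used to grow the
    organoids (600 µm cavities; 700 µm centre-to-centre pitch leaves a
    100 µm wall). Organoid diameters are drawn from a truncated normal
    centred at 235 µm with SD 25 µm (truncated at ±3 SD), which centres the
    220-250 µm mean band and the 23-27 µm intra-experiment SD band the
    platform is expected to produce.
    """

    # brightfield array geometry
    n_rows: int = 4
    n_cols: int = 4
    well_pitch_um: float = 700.0
    occupancy: float = 0.95
    # organoid morphology
    diameter_mean_um: float = 235.0
    diameter_sd_um: float = 25.0
    diameter_trunc_sd: float = 3.0
    flattening: float = 0.5
    shell_thickness_um: float = 6.0
    core_radius_fraction: float = 0.7
    # brightfield optics
    pixel_size_um: float = 2.0
    # confocal optics
    voxel_xy_um: float = 1.6
    z_step_um: float = 1.0
    stack_shape: tuple = (36, 224, 224)  # (nz, ny, nx)
    bottom_margin_um: float = 1.0
    blur_sigma_um: float = 1.0
    z_blur_factor: float = 2.0
    # noise
    poisson_gain: float = 1.0
    read_noise_sd: float = 1.5
    # per-organoid biological variability of transported signal (relative SD)
    biological_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "well_pitch_um",
            "diameter_mean_um",
            "diameter_sd_um",
            "pixel_size_um",
            "voxel_xy_um",
            "z_step_um",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0 <= self.occupancy <= 1:
            raise ConfigurationError("occupancy must be in [0, 1]")
        max_diam = self.diameter_mean_um + self.diameter_trunc_sd * self.diameter_sd_um
        if self.well_pitch_um < max_diam:
            raise ConfigurationError(
                f"well pitch {self.well_pitch_um} µm smaller than the largest "
                f"possible organoid diameter {max_diam:.0f} µm"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stack_shape"] = list(self.stack_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "stack_shape" in d:
            d["stack_shape"] = tuple(d["stack_shape"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def geometry(self, diameter_um: float) -> OrganoidGeometry:
        return OrganoidGeometry(
            true_diameter=diameter_um,
            flattening=self.flattening,
            shell_thickness=self.shell_thickness_um,
            core_radius_fraction=self.core_radius_fraction,
        )


# ---------------------------------------------------------------------------
# forward transport model
# ---------------------------------------------------------------------------

def forward_core_intensity(t, dose, params: TransportParams, condition_kind: str):
    """Expected (noise-free) tracer level in the organoid core.

    Parameters
    ----------
    t : scalar or array
        Incubation time in minutes.
    dose : scalar or array
        Tracer dose in nM.
    params : TransportParams
    condition_kind : {"excluded", "paracellular", "shuttle"}

    Returns
    -------
    Core intensity in AU, same shape as the broadcast of ``t`` and ``dose``.
    """
    if condition_kind not in KINDS:
        raise ConfigurationError(f"unknown condition kind {condition_kind!r}")
    t = np.asarray(t, dtype=float)
    dose = np.asarray(dose, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    if condition_kind == "excluded":
        out = np.broadcast_to(params.baseline, np.broadcast_shapes(t.shape, dose.shape)).copy()
    elif condition_kind == "paracellular":
        out = np.full(
            np.broadcast_shapes(t.shape, dose.shape),
            params.baseline + params.leak_amplitude,
        )
    else:  # shuttle
        out = params.baseline + params.alpha * dose * (1.0 - np.exp(-params.k_rate * t))
    if out.ndim == 0:
        return float(out)
    return out


def default_transport_params(condition_name: str) -> TransportParams:
    """Reference transport parameters for the standard assay conditions.

    Intensity scale: baseline autofluorescence 10 AU; a saturating 100 nM
    shuttle dose contributes 100 AU (alpha = 1 AU/nM); k = 0.05 /min puts
    95%-of-plateau near 60 min. Surface (rim) amplitudes reflect how each
    tracer decorates the endothelial shell.
    """
    table = {
        "non_treated": TransportParams(),
        "dextran": TransportParams(rim_amplitude=30.0),
        "free_fitc": TransportParams(leak_amplitude=60.0, rim_amplitude=30.0),
        "igg": TransportParams(rim_amplitude=5.0),
        "mouse_shuttle": TransportParams(rim_amplitude=5.0),
        "human_shuttle": TransportParams(
            alpha=1.0, k_rate=0.05, rim_amplitude=150.0, punctate=True
        ),
        # shuttle on TFRC-knockout endothelium: no receptor, no binding
        "shuttle_tfrc_ko": TransportParams(rim_amplitude=5.0),
        # shuttle on CLTC-knockout endothelium: binds the receptor but is
        # not internalized
        "shuttle_cltc_ko": TransportParams(rim_amplitude=150.0),
        # tracer reaching the core freely when no endothelial cells are present
        "no_bec": TransportParams(leak_amplitude=80.0, rim_amplitude=10.0),
    }
    if condition_name not in table:
        raise KeyError(
            f"no default transport parameters for {condition_name!r}; "
            f"known: {sorted(table)}"
        )
    return table[condition_name]


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def sample_diameters(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw organoid diameters (µm) from the truncated-normal morphology model."""
    a = -config.diameter_trunc_sd
    b = config.diameter_trunc_sd
    z = stats.truncnorm.rvs(a, b, size=n, random_state=rng)
    return config.diameter_mean_um + config.diameter_sd_um * z


def simulate_core_measurements(
    params: TransportParams,
    kind: str,
    times,
    doses,
    n_per_point: int,
    noise_cv: float = 0.1,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Measurement-level simulation of per-organoid core intensities.

    For each (time, dose) pair the noise-free level comes from the forward
    model and each organoid gets an independent multiplicative error with
    relative SD ``noise_cv`` (values clipped at zero). This is the
    lightweight counterpart of full image rendering used for kinetics and
    dose-response studies where only the measured core means matter.
    """
    rng = np.random.default_rng(rng)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    doses = np.atleast_1d(np.asarray(doses, dtype=float))
    if times.size != doses.size:
        if times.size == 1:
            times = np.full_like(doses, times[0])
        elif doses.size == 1:
            doses = np.full_like(times, doses[0])
        else:
            raise ValueError("times and doses must broadcast")
    rows = []
    oid = 0
    for t, d in zip(times, doses):
        level = forward_core_intensity(t, d, params, kind)
        vals = level * (1.0 + noise_cv * rng.standard_normal(n_per_point))
        vals = np.clip(vals, 0.0, None)
        for v in vals:
            rows.append(
                {"organoid_id": oid, "time_min": t, "dose_nM": d, "core_mean": v}
            )
            oid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# confocal stack rendering
# ---------------------------------------------------------------------------

def _apply_noise(img: np.ndarray, gain: float, read_sd: float, rng) -> np.ndarray:
    """Poisson shot noise with configurable gain plus Gaussian read noise.

    Shot noise is sampled exactly where expected counts are low (< 25, where
    discreteness matters) and by the variance-matched normal approximation
    elsewhere — the standard mixed Poisson-Gaussian simulation used for
    fluorescence microscopy.
    """
    out = np.asarray(img, dtype=np.float32)
    if gain > 0:
        lam = np.maximum(out, 0.0) / gain
        z = rng.standard_normal(out.shape, dtype=np.float32)
        shot = lam + np.sqrt(lam) * z
        small = (lam > 0) & (lam < 25.0)
        shot[small] = rng.poisson(lam[small].astype(np.float64))
        shot[lam == 0] = 0.0
        out = shot * np.float32(gain)
    if read_sd > 0:
        out = out + read_sd * rng.standard_normal(out.shape, dtype=np.float32)
    return np.maximum(out, 0.0).astype(np.float32)


def render_confocal_stack(
    geometry: OrganoidGeometry,
    params: TransportParams,
    condition: Condition,
    config: SimulationConfig,
    seed,
):
    """Render one 3-channel confocal z-stack of a mounted organoid.

    Returns ``(stack, truth_row)`` where ``stack`` is a
    :class:`bbbarray.corequant.ConfocalStack` and ``truth_row`` is a dict
    following :data:`GROUND_TRUTH_COLUMNS`. The truth row records the
    noise-free core tracer level actually painted into the interior
    (including the per-organoid biological factor).

    Channels: nuclei (diffuse cytoplasmic haze over the whole cross-section
    plus scattered nuclear blobs), endothelial marker (surface shell, empty
    for no-BEC organoids), tracer (exterior ~0, rim signal in the shell,
    core signal at the forward-model level, optionally rendered as puncta).
    """
    from .corequant import ConfocalStack  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    nz, ny, nx = config.stack_shape
    dz, dxy = config.z_step_um, config.voxel_xy_um
    depth_um = nz * dz
    # the analysis needs the core window (25 + 3.5 µm) above the organoid bottom
    required = config.bottom_margin_um + 28.5
    if required > depth_um:
        raise ConfigurationError(
            f"stack depth {depth_um:.1f} µm cannot contain the organoid bottom "
            f"plus the core window (needs >= {required:.1f} µm)"
        )

    R = geometry.radius
    c = geometry.axial_semiaxis
    if R * 2 > min(ny, nx) * dxy:
        raise ConfigurationError(
            f"organoid diameter {2 * R:.0f} µm exceeds the lateral field "
            f"{min(ny, nx) * dxy:.0f} µm"
        )
    z0 = config.bottom_margin_um
    zc = z0 + c

    z = (np.arange(nz, dtype=np.float32) + 0.5) * dz
    y = (np.arange(ny, dtype=np.float32) - (ny - 1) / 2.0) * dxy
    x = (np.arange(nx, dtype=np.float32) - (nx - 1) / 2.0) * dxy
    r2_lat = (y[:, None] ** 2 + x[None, :] ** 2) / R**2
    m2 = r2_lat[None, :, :] + (((z - zc) / c) ** 2)[:, None, None]

    tau = geometry.shell_thickness / R
    inside = m2 <= 1.0
    interior = m2 <= (1.0 - tau) ** 2
    shell = inside & ~interior

    # per-organoid biological factor: autofluorescence, staining efficiency
    # and transport all vary organoid-to-organoid, so the factor scales the
    # whole tracer field (same multiplicative-error model as the
    # measurement-level simulator)
    f = max(0.0, 1.0 + config.biological_cv * rng.standard_normal())
    level = forward_core_intensity(condition.time_min, condition.dose_nM, params, condition.kind)
    core_level = f * level
    signal = f * (level - params.baseline)

    nuclei = np.zeros((nz, ny, nx), dtype=np.float32)
    endo = np.zeros_like(nuclei)
    tracer = np.zeros_like(nuclei)

    # nuclei channel: haze + blobs (cells above the imaged depth are not seen)
    nuclei[inside] = 60.0
    n_cells = 1000
    pts = _sample_ellipsoid(n_cells, R, c, rng)  # (n, 3) in µm, organoid frame
    iz, iy, ix = _to_indices(pts, zc, dz, dxy, (nz, ny, nx))
    np.add.at(nuclei, (iz, iy, ix), 250.0)

    if not condition.no_bec:
        endo[shell] = 120.0

    tracer[inside] = f * params.baseline
    tracer[shell] += f * params.rim_amplitude
    diffuse = signal
    if params.punctate and signal > 0:
        # split diffuse/puncta 50/50; puncta are uniform in the interior with
        # per-spot amplitude chosen so the expected deposited intensity per
        # voxel equals the punctate half of the signal (core mean preserved)
        diffuse = 0.5 * signal
        full_interior_vol = 4.0 / 3.0 * np.pi * (R * (1 - tau)) ** 2 * (c * (1 - tau))
        n_spots = max(1, int(round(params.puncta_density * full_interior_vol)))
        spots = _sample_ellipsoid(n_spots, R * (1 - tau), c * (1 - tau), rng)
        sz, sy, sx = _to_indices(spots, zc, dz, dxy, (nz, ny, nx))
        if sz.size:
            # exact in-stack mass conservation: the punctate half of the
            # signal, integrated over the imaged interior, sits in the spots
            amplitude = 0.5 * signal * float(interior.sum()) / sz.size
            np.add.at(tracer, (sz, sy, sx), amplitude)
        else:
            diffuse = signal
    tracer[interior] += diffuse

    sig_xy = config.blur_sigma_um / dxy
    sig_z = config.blur_sigma_um * config.z_blur_factor / dz
    sigmas = (sig_z, sig_xy, sig_xy)
    for ch in (nuclei, endo, tracer):
        ndimage.gaussian_filter(ch, sigma=sigmas, output=ch, truncate=2.5)

    data = np.stack(
        [
            _apply_noise(nuclei, config.poisson_gain, config.read_noise_sd, rng),
            _apply_noise(endo, config.poisson_gain, config.read_noise_sd, rng),
            _apply_noise(tracer, config.poisson_gain, config.read_noise_sd, rng),
        ]
    )

    stack = ConfocalStack(
        data=data,
        channel_roles={"nuclei": 0, "endothelial": 1, "tracer": 2},
        voxel_size_xy_um=dxy,
        z_step_um=dz,
        metadata={
            "condition": condition.name,
            "kind": condition.kind,
            "dose_nM": condition.dose_nM,
            "time_min": condition.time_min,
            "knockout": condition.knockout,
            "no_bec": condition.no_bec,
            "true_diameter_um": geometry.true_diameter,
            "bottom_margin_um": z0,
        },
    )
    truth = {
        "organoid_id": 0,
        "well_row": np.nan,
        "well_col": np.nan,
        "true_diameter_um": geometry.true_diameter,
        "condition": condition.name,
        "dose_nM": condition.dose_nM,
        "time_min": condition.time_min,
        "true_core_mean": core_level,
        "background_mean": params.baseline,
    }
    return stack, truth


def _to_indices(pts: np.ndarray, zc: float, dz: float, dxy: float, shape: tuple):
    """Voxel indices of organoid-frame points; points outside the stack are
    dropped (structures above the imaged depth are simply not acquired)."""
    nz, ny, nx = shape
    iz = np.round((pts[:, 0] + zc) / dz - 0.5).astype(int)
    iy = np.round(pts[:, 1] / dxy + (ny - 1) / 2.0).astype(int)
    ix = np.round(pts[:, 2] / dxy + (nx - 1) / 2.0).astype(int)
    keep = (iz >= 0) & (iz < nz) & (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
    return iz[keep], iy[keep], ix[keep]


def _sample_ellipsoid(n: int, a: float, c: float, rng) -> np.ndarray:
    """Uniform points inside an oblate spheroid; columns (z, y, x) in µm."""
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-1, 1, size=(2 * (n - got) + 8, 3))
        keep = (cand**2).sum(axis=1) <= 1.0
        cand = cand[keep][: n - got]
        pts[got : got + cand.shape[0]] = cand
        got += cand.shape[0]
    pts[:, 0] *= c
    pts[:, 1] *= a
    pts[:, 2] *= a
    return pts


# ---------------------------------------------------------------------------
# brightfield array rendering
# ---------------------------------------------------------------------------

def render_brightfield_array(config: SimulationConfig, seed, noise: bool = True):
    """Render one stitched brightfield array image plus its ground truth.

    Organoids are dark quasi-circular disks with a thin bright halo sitting
    in a microwell grid; a gentle multiplicative illumination gradient and
    per-well vignetting emulate stitched wide-field acquisition. Returns
    ``(image, truth)`` with ``image`` float32 and ``truth`` a DataFrame with
    :data:`GROUND_TRUTH_COLUMNS`.
    """
    rng = np.random.default_rng(seed)
    px = config.pixel_size_um
    pitch_px = config.well_pitch_um / px
    H = int(round(config.n_rows * pitch_px))
    W = int(round(config.n_cols * pitch_px))
    yy = np.arange(H, dtype=np.float32)
    xx = np.arange(W, dtype=np.float32)

    bg_level = 1000.0
    # smooth illumination gradient across the stitched mosaic (+-4%)
    gy = 1.0 + 0.04 * (yy / max(H - 1, 1) - 0.5)
    gx = 1.0 + 0.04 * (xx / max(W - 1, 1) - 0.5)
    image = bg_level * gy[:, None] * gx[None, :]

    well_r_px = (600.0 / 2.0) / px  # cavity radius
    rows = []
    oid = 0
    edge = 1.5  # px, anti-aliasing half-width of the organoid boundary
    for r in range(config.n_rows):
        for cidx in range(config.n_cols):
            cy = (r + 0.5) * pitch_px
            cx = (cidx + 0.5) * pitch_px
            # faint well vignette (removed by background normalization)
            _add_well_shading(image, cy, cx, well_r_px, bg_level)
            if rng.uniform() > config.occupancy:
                continue
            diam = float(sample_diameters(1, config, rng)[0])
            R_px = diam / 2.0 / px
            max_off = max(0.0, (well_r_px - R_px) * 0.4)
            oy = cy + rng.uniform(-max_off, max_off)
            ox = cx + rng.uniform(-max_off, max_off)
            _add_organoid_disk(image, oy, ox, R_px, edge, bg_level)
            rows.append(
                {
                    "organoid_id": oid,
                    "well_row": r,
                    "well_col": cidx,
                    "true_diameter_um": diam,
                    "condition": "brightfield",
                    "dose_nM": np.nan,
                    "time_min": np.nan,
                    "true_core_mean": np.nan,
                    "background_mean": bg_level,
                }
            )
            oid += 1
    image = image.astype(np.float32)
    if noise:
        image = _apply_noise(image, gain=4.0, read_sd=4.0, rng=rng)
    truth = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    return image, truth


def _local_window(image, cy, cx, half):
    y0 = max(0, int(cy - half))
    y1 = min(image.shape[0], int(cy + half) + 1)
    x0 = max(0, int(cx - half))
    x1 = min(image.shape[1], int(cx + half) + 1)
    yy = np.arange(y0, y1, dtype=np.float32)
    xx = np.arange(x0, x1, dtype=np.float32)
    rr = np.hypot(yy[:, None] - cy, xx[None, :] - cx)
    return (slice(y0, y1), slice(x0, x1)), rr


def _add_well_shading(image, cy, cx, well_r_px, bg_level):
    sl, rr = _local_window(image, cy, cx, well_r_px * 1.3)
    rim = np.exp(-0.5 * ((rr - well_r_px) / (well_r_px * 0.08)) ** 2)
    image[sl] -= 0.02 * bg_level * rim


def _add_organoid_disk(image, cy, cx, R_px, edge, bg_level):
    sl, rr = _local_window(image, cy, cx, R_px + 8 * edge)
    coverage = np.clip((R_px - rr) / edge + 0.5, 0.0, 1.0)
    image[sl] -= 0.5 * bg_level * coverage
    halo = np.exp(-0.5 * ((rr - (R_px + 2.0)) / 2.0) ** 2)
    image[sl] += 0.12 * bg_level * halo * (coverage < 0.5)
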