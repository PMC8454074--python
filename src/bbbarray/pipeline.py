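"""End-to-end assay orchestration over simulated or user-supplied images.

Four assays compose the lower-level modules:

* ``size_qc`` — brightfield array morphometry across independent
  experiments (diameter mean/SD/CV, cross-experiment reproducibility),
* ``permeability`` — dextran-exclusion assay: core tracer means across
  tracer conditions, Friedman test blocked by experiment over
  non-treated + dextrans, Kruskal-Wallis/Dunn across all conditions,
* ``transcytosis`` — antibody constructs vs non-treated control (ANOVA +
  Dunnett) plus one-phase association time-course and linear dose-response
  fits with 95% confidence bands and steady-state timing,
* ``knockout`` — endothelial knockout lines vs scrambled control (ANOVA +
  Dunnett), run separately for non-targeting IgG and the targeting shuttle.

In simulate mode the construct comparison, permeability and knockout
measurements come from fully rendered confocal stacks pushed through the
complete image-analysis chain; time-course and dose-response fits consume
measurement-level simulations of per-organoid core intensities (the fitted
quantities are the measured core means themselves, so rendering adds
nothing but runtime). All outputs are deterministic functions of
(config, seed) and every reported number is traceable to a written CSV row.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arraymorph import segment_brightfield, summarize_sizes, detections_to_frame
from .corequant import measure_stack
from .errors import ConfigurationError, DataError
from .groupstats import anova_dunnett, friedman_test, kruskal_dunn, boxplot_summary
from .simdata import (
    Condition,
    SimulationConfig,
    default_transport_params,
    render_brightfield_array,
    render_confocal_stack,
    sample_diameters,
    simulate_core_measurements,
)
from .transport_fit import confidence_band, fit_association, fit_linear, time_to_steady_state

__all__ = ["AssayConfig", "AssayReport", "run_assay", "DEFAULTS"]

ASSAYS = ("size_qc", "permeability", "transcytosis", "knockout")

#: Default scale of each simulated assay (organoids per condition and
#: number of independent experiments), mirroring the reference assays.
DEFAULTS = {
    "size_qc": {"n_experiments": 3, "organoids_per_experiment": 324},
    "permeability": {"n_experiments": 4, "organoids_per_condition": 50},
    "transcytosis": {"n_experiments": 3, "organoids_per_condition": 60},
    "knockout": {"n_experiments": 3, "organoids_per_condition": 50},
}

TIME_COURSE_MIN = (15.0, 30.0, 60.0, 120.0, 240.0, 360.0)
DOSES_NM = (0.0, 12.5, 25.0, 50.0, 100.0, 200.0)
REFERENCE_DOSE_NM = 100.0


@dataclass
class AssayConfig:
    """Configuration of one end-to-end assay run."""

    assay: str
    mode: str = "simulate"
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_experiments: int | None = None
    organoids_per_condition: int | None = None
    organoids_per_experiment: int | None = None
    # analysis parameters
    offset_um: float = 25.0
    span_um: float = 3.5
    fraction: float = 0.75
    alpha: float = 0.05
    # image mode
    manifest: str | None = None
    # measurement-level kinetics scale
    kinetics_n_per_point: int = 50

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ConfigurationError(f"unknown assay {self.assay!r}; choose from {ASSAYS}")
        if self.mode not in ("simulate", "images"):
            raise ConfigurationError("mode must be 'simulate' or 'images'")
        if self.mode == "images" and not self.manifest:
            raise ConfigurationError("image mode requires a manifest CSV")
        defaults = DEFAULTS[self.assay]
        for name in ("n_experiments", "organoids_per_condition", "organoids_per_experiment"):
            if getattr(self, name) is None and name in defaults:
                setattr(self, name, defaults[name])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        return d


@dataclass
class AssayReport:
    """Tables produced by one assay run plus its provenance block."""

    measurements: pd.DataFrame
    statistics: pd.DataFrame
    fits: pd.DataFrame | None
    bands: pd.DataFrame | None
    summary: dict
    provenance: dict

    def save(self, out_dir: str | Path, force: bool = False) -> None:
        """Write all tables and the provenance JSON into ``out_dir``.

        Refuses to overwrite existing outputs unless ``force`` is set;
        writes are atomic (tmp file + rename).
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "measurements.csv": self.measurements,
            "statistics.csv": self.statistics,
        }
        if self.fits is not None:
            files["fits.csv"] = self.fits
        if self.bands is not None:
            files["bands.csv"] = self.bands
        for name in list(files) + ["provenance.json"]:
            if (out / name).exists() and not force:
                raise DataError(f"refusing to overwrite existing {out / name} (use force)")
        for name, frame in files.items():
            tmp = out / (name + ".tmp")
            frame.to_csv(tmp, index=False)
            tmp.replace(out / name)
        tmp = out / "provenance.json.tmp"
        tmp.write_text(json.dumps(self.provenance, indent=2, sort_keys=True, default=str))
        tmp.replace(out / "provenance.json")


def _provenance(config: AssayConfig) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "software": f"bbbarray {__version__}",
    }


def _child_seed(*keys) -> np.random.SeedSequence:
    return np.random.SeedSequence(list(int(k) for k in keys))


# ---------------------------------------------------------------------------
# condition tables
# ---------------------------------------------------------------------------

def permeability_conditions() -> list:
    conds = [Condition("non_treated", "excluded")]
    for kda in (3, 4, 40, 70):
        conds.append(Condition(f"dextran_{kda}kDa", "excluded", time_min=240.0))
    conds.append(Condition("free_fitc", "paracellular", time_min=240.0))
    return conds


def transcytosis_conditions() -> list:
    return [
        Condition("non_treated", "excluded"),
        Condition("igg", "excluded", dose_nM=REFERENCE_DOSE_NM, time_min=240.0),
        Condition("mouse_shuttle", "excluded", dose_nM=REFERENCE_DOSE_NM, time_min=240.0),
        Condition("human_shuttle", "shuttle", dose_nM=REFERENCE_DOSE_NM, time_min=240.0),
    ]


def knockout_conditions() -> list:
    conds = []
    for ko in ("scrambled", "TFRC", "CLTC", "CAV1"):
        conds.append(
            Condition(f"igg_{ko}", "excluded", dose_nM=REFERENCE_DOSE_NM, time_min=240.0, knockout=ko)
        )
        kind = "excluded" if ko in ("TFRC", "CLTC") else "shuttle"
        conds.append(
            Condition(
                f"shuttle_{ko}", kind, dose_nM=REFERENCE_DOSE_NM, time_min=240.0, knockout=ko
            )
        )
    return conds


def _params_for(condition: Condition):
    name = condition.name
    if name.startswith("dextran"):
        return default_transport_params("dextran")
    if name.startswith("igg"):
        return default_transport_params("igg")
    if name.startswith("shuttle_"):
        ko = condition.knockout
        if ko == "TFRC":
            return default_transport_params("shuttle_tfrc_ko")
        if ko == "CLTC":
            return default_transport_params("shuttle_cltc_ko")
        return default_transport_params("human_shuttle")
    return default_transport_params(name)


# ---------------------------------------------------------------------------
# measurement generation
# ---------------------------------------------------------------------------

def _simulate_condition_measurements(config: AssayConfig, conditions: list) -> pd.DataFrame:
    """Render one stack per organoid and run the full corequant chain."""
    sim = config.sim
    rows = []
    n_per = config.organoids_per_condition
    per_exp = _split_counts(n_per, config.n_experiments)
    oid = 0
    for ci, cond in enumerate(conditions):
        params = _params_for(cond)
        for exp in range(config.n_experiments):
            # shared experiment factor: day-to-day staining/illumination drift
            exp_rng = np.random.default_rng(_child_seed(config.seed, 1000 + exp))
            exp_factor = float(np.exp(0.05 * exp_rng.standard_normal()))
            for i in range(per_exp[exp]):
                rng_seed = _child_seed(config.seed, ci, exp, i)
                rng = np.random.default_rng(rng_seed)
                diam = float(sample_diameters(1, sim, rng)[0])
                geometry = sim.geometry(diam)
                stack, truth = render_confocal_stack(
                    geometry, params, cond, sim, seed=rng_seed.spawn(1)[0]
                )
                stack.data[stack.channel_roles["tracer"]] *= exp_factor
                meas = measure_stack(
                    stack,
                    offset_um=config.offset_um,
                    span_um=config.span_um,
                    fraction=config.fraction,
                    organoid_id=oid,
                )
                rows.append(
                    {
                        "organoid_id": oid,
                        "experiment": exp,
                        "condition": cond.name,
                        "knockout": cond.knockout,
                        "dose_nM": cond.dose_nM,
                        "time_min": cond.time_min,
                        "core_mean": meas.core_mean,
                        "core_area_px2": meas.core_area_px2,
                        "achieved_fraction": meas.achieved_fraction,
                        "true_core_mean": truth["true_core_mean"],
                        "true_diameter_um": diam,
                    }
                )
                oid += 1
    return pd.DataFrame(rows)


def _split_counts(total: int, parts: int) -> list:
    base = total // parts
    counts = [base] * parts
    for i in range(total - base * parts):
        counts[i] += 1
    return counts


def _boxplot_frame(measurements: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for cond, grp in measurements.groupby("condition", sort=False):
        s = boxplot_summary(grp["core_mean"].to_numpy())
        rows.append(
            {
                "condition": cond,
                "n": s.n,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "p5": s.p5,
                "p95": s.p95,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# assays
# ---------------------------------------------------------------------------

def run_size_qc(config: AssayConfig) -> AssayReport:
    sim = config.sim
    per_image = sim.n_rows * sim.n_cols
    n_images = max(1, int(np.ceil(config.organoids_per_experiment / max(per_image * sim.occupancy, 1))))
    all_rows = []
    groups = {}
    for exp in range(config.n_experiments):
        detections = []
        for img_idx in range(n_images):
            image, truth = render_brightfield_array(
                sim, seed=_child_seed(config.seed, exp, img_idx)
            )
            dets = segment_brightfield(image, sim.pixel_size_um)
            frame = detections_to_frame(dets)
            frame.insert(0, "experiment", exp)
            frame.insert(1, "image", img_idx)
            all_rows.append(frame)
            detections.extend(dets)
        groups[f"exp{exp}"] = detections
    summary = summarize_sizes(groups)
    measurements = pd.concat(all_rows, ignore_index=True)
    stats_frame = summary.per_experiment.reset_index()
    return AssayReport(
        measurements=measurements,
        statistics=stats_frame,
        fits=None,
        bands=None,
        summary={
            "grand_mean_um": summary.grand_mean_um,
            "inter_experiment_variation_pct": summary.inter_experiment_variation_pct,
            "n_total": summary.n_total,
        },
        provenance=_provenance(config),
    )


def run_permeability(config: AssayConfig) -> AssayReport:
    conditions = permeability_conditions()
    meas = _simulate_condition_measurements(config, conditions)
    # Friedman over non-treated + dextrans, blocked by experiment means
    dex = meas[meas["condition"] != "free_fitc"]
    block_matrix = dex.pivot_table(
        index="experiment", columns="condition", values="core_mean", aggfunc="mean"
    )
    fr = friedman_test(block_matrix)
    kw = kruskal_dunn(meas, value_col="core_mean", group_col="condition", alpha=config.alpha)
    stats_frame = pd.concat([fr.to_frame(), kw.to_frame()], ignore_index=True)
    summary = {
        "friedman_p": fr.pvalue,
        "dextran_significant": bool(fr.pvalue < config.alpha),
        "boxplots": _boxplot_frame(meas).to_dict("records"),
    }
    return AssayReport(meas, stats_frame, None, None, summary, _provenance(config))


def run_transcytosis(config: AssayConfig) -> AssayReport:
    conditions = transcytosis_conditions()
    meas = _simulate_condition_measurements(config, conditions)
    dn = anova_dunnett(
        meas,
        control="non_treated",
        value_col="core_mean",
        group_col="condition",
        alpha=config.alpha,
        seed=config.seed,
    )
    shuttle = default_transport_params("human_shuttle")
    tc = simulate_core_measurements(
        shuttle,
        "shuttle",
        times=TIME_COURSE_MIN,
        doses=REFERENCE_DOSE_NM,
        n_per_point=config.kinetics_n_per_point,
        noise_cv=config.sim.biological_cv,
        rng=np.random.default_rng(_child_seed(config.seed, 7001)),
    )
    tc.insert(0, "dataset", "time_course")
    assoc = fit_association(tc["time_min"], tc["core_mean"])
    t_grid = np.linspace(0, max(TIME_COURSE_MIN), 73)
    assoc_band = confidence_band(assoc, t_grid)
    dr = simulate_core_measurements(
        shuttle,
        "shuttle",
        times=240.0,
        doses=DOSES_NM,
        n_per_point=config.kinetics_n_per_point,
        noise_cv=config.sim.biological_cv,
        rng=np.random.default_rng(_child_seed(config.seed, 7002)),
    )
    dr.insert(0, "dataset", "dose_response")
    lin = fit_linear(dr["dose_nM"], dr["core_mean"])
    d_grid = np.linspace(0, max(DOSES_NM), 41)
    lin_band = confidence_band(lin, d_grid)
    t95 = time_to_steady_state(assoc, 0.95)

    fits = pd.DataFrame(
        [
            {"model": "association", "parameter": "baseline", "estimate": assoc.baseline,
             "se": float(np.sqrt(assoc.cov[0, 0]))},
            {"model": "association", "parameter": "amplitude", "estimate": assoc.amplitude,
             "se": float(np.sqrt(assoc.cov[1, 1]))},
            {"model": "association", "parameter": "k_per_min", "estimate": assoc.k,
             "se": float(np.sqrt(assoc.cov[2, 2]))},
            {"model": "association", "parameter": "t95_min", "estimate": t95, "se": np.nan},
            {"model": "linear", "parameter": "slope_au_per_nM", "estimate": lin.slope,
             "se": float(np.sqrt(lin.cov[0, 0]))},
            {"model": "linear", "parameter": "intercept_au", "estimate": lin.intercept,
             "se": float(np.sqrt(lin.cov[1, 1]))},
        ]
    )
    bands = pd.concat(
        [
            pd.DataFrame(
                {"model": "association", "grid": assoc_band.grid, "fit": assoc_band.fitted,
                 "lower": assoc_band.lower, "upper": assoc_band.upper}
            ),
            pd.DataFrame(
                {"model": "linear", "grid": lin_band.grid, "fit": lin_band.fitted,
                 "lower": lin_band.lower, "upper": lin_band.upper}
            ),
        ],
        ignore_index=True,
    )
    kin = pd.concat([tc, dr], ignore_index=True)
    kin = kin.rename(columns={"organoid_id": "kinetics_point_id"})
    measurements = pd.concat([meas, kin], ignore_index=True)
    summary = {
        "dunnett": dn.comparisons.to_dict("records"),
        "t95_min": t95,
        "k_per_min": assoc.k,
        "slope_au_per_nM": lin.slope,
        "boxplots": _boxplot_frame(meas).to_dict("records"),
    }
    return AssayReport(measurements, dn.to_frame(), fits, bands, summary, _provenance(config))


def run_knockout(config: AssayConfig) -> AssayReport:
    conditions = knockout_conditions()
    meas = _simulate_condition_measurements(config, conditions)
    frames = []
    decisions = {}
    for tracer in ("igg", "shuttle"):
        sub = meas[meas["condition"].str.startswith(tracer)].copy()
        sub["condition"] = sub["knockout"]
        res = anova_dunnett(
            sub,
            control="scrambled",
            value_col="core_mean",
            group_col="condition",
            alpha=config.alpha,
            seed=config.seed,
        )
        frame = res.to_frame()
        frame.insert(0, "tracer", tracer)
        frames.append(frame)
        decisions[tracer] = res.comparisons.to_dict("records")
    stats_frame = pd.concat(frames, ignore_index=True)
    summary = {"dunnett": decisions, "boxplots": _boxplot_frame(meas).to_dict("records")}
    return AssayReport(meas, stats_frame, None, None, summary, _provenance(config))


def run_assay(config: AssayConfig) -> AssayReport:
    """Dispatch an assay configuration to its runner (simulate mode)."""
    if config.mode != "simulate":
        raise ConfigurationError(
            "image mode is driven through the CLI measure commands; "
            "run_assay orchestrates simulate mode"
        )
    runner = {
        "size_qc": run_size_qc,
        "permeability": run_permeability,
        "transcytosis": run_transcytosis,
        "knockout": run_knockout,
    }[config.assay]
    return runner(config)
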