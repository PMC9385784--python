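"""End-to-end orchestration: simulate -> quantify -> calibrate -> analyze -> report.

``run_pipeline`` drives one of three input modes:

``synthetic``
    Generate life-cycle-stage scenes from presets (or custom component
    lists), either as intensity tables (``route="table"``) or as rendered
    images pushed through segmentation (``route="image"``).
``tables``
    A per-nucleus CSV with an ``is_standard`` column: calibrate and analyze.
``images``
    DAPI TIFFs plus a standard-identification rule (a standards label mask,
    a separate standards-only image, or an IOD gate).

Every run writes its resolved configuration -- including each default that
was filled in -- so the design decisions in effect are always on record.
"""

from __future__ import annotations

import copy
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .calibrate import CalibrationStandard, fit_standard, to_picograms
from .ploidy import peak_class_mean, build_frequency_distribution
from .quant import (
    compute_nrs,
    estimate_background,
    mark_standards,
    measure_nuclei,
    measurements_to_frame,
    segment_nuclei,
)
from .report import size_content_correlation, summarize_stage
from .synthetic import (
    ComponentSpec,
    StagePreset,
    SyntheticSceneSpec,
    gen_intensity_table,
    render_scene,
    stage_presets,
    suggest_shape,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "load_config",
    "run_pipeline",
    "quantify_image",
    "stage_scene_spec",
    "recover_stage",
]


class ConfigError(ValueError):
    pass


_DEFAULTS: dict = {
    "mode": "synthetic",
    "route": "table",
    "seed": 0,
    "stages": [
        "zoospores_released",
        "zoospores_unreleased",
        "male_gametophytes",
        "female_gametophytes",
        "sporophytes_embryonic",
        "meristoderm",
        "cortex_medulla",
    ],
    "class_width": 0.1,
    "reference_stage": "zoospores_released",
    "reference_1C": None,
    "standard_pg": 2.4,
    "n_standard": 50,
    "gain": 5000.0,
    "noise_sd": 2.0,
    "plus_fraction": 0.02,
    "plus_plus_fraction": 0.10,
    "plus_threshold": 0.05,
    "decouple_male": True,
    "plots": True,
    "outdir": "dapicyto_out",
    "segmentation": {
        "min_area": 20,
        "max_area": None,
        "threshold_method": "otsu",
        "split_touching": False,
    },
    "measurements_csv": None,
    "images": None,
    "allow_cross_image": False,
}

_MODES = ("synthetic", "tables", "images")
_ROUTES = ("table", "image")


def load_config(source) -> dict:
    """Load and validate a run configuration (dict, YAML or JSON path)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigError(f"{source}: config must be a mapping")
    elif isinstance(source, dict):
        raw = source
    else:
        raise ConfigError("config must be a dict or a path to YAML/JSON")

    cfg = copy.deepcopy(_DEFAULTS)
    for key, value in raw.items():
        if key not in _DEFAULTS:
            raise ConfigError(f"config.{key}: unknown key")
        if key == "segmentation":
            if not isinstance(value, dict):
                raise ConfigError("config.segmentation: must be a mapping")
            for k2 in value:
                if k2 not in _DEFAULTS["segmentation"]:
                    raise ConfigError(f"config.segmentation.{k2}: unknown key")
            cfg["segmentation"].update(value)
        else:
            cfg[key] = value

    if cfg["mode"] not in _MODES:
        raise ConfigError(f"config.mode: must be one of {_MODES}")
    if cfg["route"] not in _ROUTES:
        raise ConfigError(f"config.route: must be one of {_ROUTES}")
    if cfg["mode"] == "synthetic":
        presets = stage_presets()
        for i, st in enumerate(cfg["stages"]):
            if isinstance(st, str):
                if st not in presets:
                    raise ConfigError(
                        f"config.stages[{i}]: unknown stage {st!r}; "
                        f"available: {sorted(presets)}"
                    )
            elif isinstance(st, dict):
                for req in ("label", "mean_pg", "cv", "n"):
                    if req not in st:
                        raise ConfigError(f"config.stages[{i}].{req}: required")
            else:
                raise ConfigError(f"config.stages[{i}]: must be a name or mapping")
    if cfg["mode"] == "tables" and not cfg["measurements_csv"]:
        raise ConfigError("config.measurements_csv: required in tables mode")
    if cfg["mode"] == "images" and not cfg["images"]:
        raise ConfigError("config.images: required in images mode")
    return cfg


def _stage_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % (2**31))


def _resolve_preset(entry, cfg) -> StagePreset:
    if isinstance(entry, str):
        return stage_presets(cfg["plus_fraction"], cfg["plus_plus_fraction"])[entry]
    comp = ComponentSpec(
        label=entry["label"],
        mean_pg=float(entry["mean_pg"]),
        cv=float(entry["cv"]),
        n=int(entry["n"]),
        size_scale=float(entry.get("size_scale", 1.0)),
    )
    return StagePreset(
        label=entry["label"],
        components=(comp,),
        mean_pg=comp.mean_pg,
        sd_pg=comp.mean_pg * comp.cv,
        cv=comp.cv,
        n_total=comp.n,
        decoupled=bool(entry.get("decoupled", False)),
    )


def stage_scene_spec(preset: StagePreset, cfg: dict, seed: int) -> SyntheticSceneSpec:
    """Build the scene spec for one stage under a run configuration."""
    decoupled = (preset.label,) if (preset.decoupled and cfg["decouple_male"]) else ()
    spec = SyntheticSceneSpec(
        components=list(preset.components),
        n_standard=int(cfg["n_standard"]),
        standard_pg=float(cfg["standard_pg"]),
        gain=float(cfg["gain"]),
        noise_sd=float(cfg["noise_sd"]),
        decoupled_labels=decoupled,
        seed=seed,
    )
    spec.image_shape = suggest_shape(spec)
    return spec


def _background_radius(spec: SyntheticSceneSpec) -> int:
    areas = [
        spec.area_per_pg * c.size_scale * c.mean_pg ** spec.coupling_exponent
        for c in spec.components
    ]
    areas.append(spec.area_per_pg * spec.standard_pg ** spec.coupling_exponent)
    r_max = max(np.sqrt(np.asarray(areas) / np.pi))
    return int(np.ceil(2.5 * r_max))


def quantify_image(
    image: np.ndarray,
    background_radius: int,
    standards_mask: np.ndarray | None = None,
    seg_params: dict | None = None,
    pixel_size: float = 1.0,
):
    """Background-correct, segment and measure one image.

    Returns ``(measurements, label_mask, background)``; if a standards mask
    is given, matching measurements are flagged ``is_standard``.
    """
    seg_params = dict(seg_params or {})
    background = estimate_background(image, radius=background_radius)
    mask = segment_nuclei(image, background, **seg_params)
    measurements = measure_nuclei(image, background, mask, pixel_size=pixel_size)
    if standards_mask is not None:
        mark_standards(measurements, mask, standards_mask)
    return measurements, mask, background


def _run_stage_synthetic(preset: StagePreset, cfg: dict, seed: int) -> tuple[pd.DataFrame, CalibrationStandard]:
    """One stage end to end; returns per-nucleus records (samples + standards)."""
    spec = stage_scene_spec(preset, cfg, seed)
    if cfg["route"] == "table":
        table = gen_intensity_table(spec)
        std = table[table["is_standard"]]
        cal = fit_standard(std["intensity"].to_numpy(), standard_pg=spec.standard_pg)
        ref_area = float(std["area"].mean())
        records = table.rename(columns={"intensity": "iod"}).copy()
        records["nrs"] = records["area"] / ref_area
        records["pg"] = to_picograms(records["iod"].to_numpy(), cal)
    else:
        image, gt = render_scene(spec)
        measurements, mask, _ = quantify_image(
            image,
            background_radius=_background_radius(spec),
            standards_mask=gt.standard_mask,
            seg_params=cfg["segmentation"],
        )
        if not any(m.is_standard for m in measurements):
            raise ConfigError(
                f"stage {preset.label!r}: no standard nuclei recovered from the image"
            )
        compute_nrs(measurements)
        cal = fit_standard(measurements, standard_pg=spec.standard_pg)
        records = measurements_to_frame(measurements)
        records["pg"] = to_picograms(records["iod"].to_numpy(), cal)
    records["stage"] = preset.label
    return records, cal


def recover_stage(stage: str, route: str = "table", seed: int = 0, config: dict | None = None):
    """Simulate one stage and recover its peak-class DNA-content estimate.

    Runs the stage end to end (intensity table or rendered image through
    segmentation, then calibration against the simulated standards and the
    peak-class rule).  Returns ``(estimate, samples, calibration)`` where
    ``samples`` is the per-nucleus record frame (standards excluded).
    """
    cfg = load_config({**(config or {}), "stages": [stage], "route": route, "seed": seed})
    preset = _resolve_preset(stage, cfg)
    records, cal = _run_stage_synthetic(preset, cfg, _stage_seed(seed, 0))
    samples = records[~records["is_standard"].astype(bool)]
    dist = build_frequency_distribution(samples["pg"].to_numpy(), cfg["class_width"])
    return peak_class_mean(dist), samples, cal


def _run_tables_mode(cfg: dict) -> tuple[pd.DataFrame, dict[str, CalibrationStandard]]:
    df = dio.load_table(cfg["measurements_csv"])
    if "stage" not in df.columns and "label" in df.columns:
        df = df.rename(columns={"label": "stage"})
    if "iod" not in df.columns and "intensity" in df.columns:
        df = df.rename(columns={"intensity": "iod"})
    if "pg" in df.columns:
        if "nrs" not in df.columns:
            df["nrs"] = float("nan")
        if "is_standard" not in df.columns:
            df["is_standard"] = False
        return df, {}
    for col in ("stage", "iod", "is_standard"):
        if col not in df.columns:
            raise ConfigError(f"measurements CSV: missing column {col!r}")
    std = df[df["is_standard"].astype(bool)]
    cal = fit_standard(std["iod"].to_numpy(), standard_pg=float(cfg["standard_pg"]))
    df = df.copy()
    df["pg"] = to_picograms(df["iod"].to_numpy(), cal)
    if "nrs" not in df.columns:
        if "area" in df.columns and len(std):
            df["nrs"] = df["area"] / float(std["area"].mean())
        else:
            df["nrs"] = float("nan")
    return df, {"all": cal}


def _run_images_mode(cfg: dict) -> tuple[pd.DataFrame, dict[str, CalibrationStandard]]:
    frames = []
    cals: dict[str, CalibrationStandard] = {}
    shared_cal: CalibrationStandard | None = None
    for i, entry in enumerate(cfg["images"]):
        for req in ("path", "stage"):
            if req not in entry:
                raise ConfigError(f"config.images[{i}].{req}: required")
        image = dio.load_image(entry["path"])
        radius = int(entry.get("background_radius", 50))
        rule = entry.get("standards", {})
        standards_mask = None
        if rule.get("method") == "mask":
            standards_mask = dio.load_mask(rule["path"]) > 0
        measurements, mask, _ = quantify_image(
            image, radius, standards_mask=standards_mask, seg_params=cfg["segmentation"]
        )
        if rule.get("method") == "intensity_gate":
            lo, hi = float(rule["low"]), float(rule["high"])
            for m in measurements:
                m.is_standard = lo <= m.iod <= hi
        elif rule.get("method") == "separate_image":
            if not cfg["allow_cross_image"]:
                raise ConfigError(
                    f"config.images[{i}]: separate-image standards require "
                    "allow_cross_image: true (fluorometric comparability across "
                    "exposures is an explicit assumption)"
                )
            logger.warning(
                "images[%d]: calibrating against a separate standards image; "
                "assuming identical staining and exposure", i
            )
            std_img = dio.load_image(rule["path"])
            std_meas, _, _ = quantify_image(
                std_img, radius, seg_params=cfg["segmentation"]
            )
            shared_cal = fit_standard(
                [m.iod for m in std_meas] or [0.0], standard_pg=float(cfg["standard_pg"])
            )
        if any(m.is_standard for m in measurements):
            cal = fit_standard(measurements, standard_pg=float(cfg["standard_pg"]))
        elif shared_cal is not None:
            cal = shared_cal
        else:
            raise ConfigError(
                f"config.images[{i}]: no standard nuclei identified "
                "(provide a standards mask, gate or image)"
            )
        try:
            compute_nrs(measurements)
        except ValueError:
            compute_nrs(measurements, reference_area=float(np.mean([m.area for m in measurements])))
        rec = measurements_to_frame(measurements)
        rec["pg"] = to_picograms(rec["iod"].to_numpy(), cal)
        rec["stage"] = entry["stage"]
        frames.append(rec)
        cals[f"{entry['stage']}[{i}]"] = cal
    return pd.concat(frames, ignore_index=True), cals


def run_pipeline(config, outdir: str | Path | None = None) -> Path:
    """Run the full pipeline and write all artifacts; returns the output dir."""
    cfg = load_config(config)
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("dapicyto")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("resolved configuration: %s", cfg)
        cals: dict[str, CalibrationStandard] = {}
        if cfg["mode"] == "synthetic":
            frames = []
            for i, entry in enumerate(cfg["stages"]):
                preset = _resolve_preset(entry, cfg)
                rec, cal = _run_stage_synthetic(preset, cfg, _stage_seed(cfg["seed"], i))
                frames.append(rec)
                cals[preset.label] = cal
            records = pd.concat(frames, ignore_index=True)
        elif cfg["mode"] == "tables":
            records, cals = _run_tables_mode(cfg)
        else:
            records, cals = _run_images_mode(cfg)

        samples = records[~records["is_standard"].astype(bool)].copy()
        if samples.empty:
            raise ConfigError("no sample nuclei (everything flagged as standard)")

        # 1C reference: explicit value, else the reference stage's peak-class mean
        if cfg["reference_1C"] is not None:
            ref = float(cfg["reference_1C"])
        else:
            ref_stage = cfg["reference_stage"]
            stages_present = list(samples["stage"].unique())
            if ref_stage in stages_present:
                ref_pg = samples.loc[samples["stage"] == ref_stage, "pg"]
                ref = peak_class_mean(
                    build_frequency_distribution(ref_pg, cfg["class_width"])
                ).mean_pg
            else:
                first = stages_present[0]
                logger.warning(
                    "reference stage %r absent; using first stage %r as 1C reference",
                    ref_stage, first,
                )
                ref = peak_class_mean(
                    build_frequency_distribution(
                        samples.loc[samples["stage"] == first, "pg"], cfg["class_width"]
                    )
                ).mean_pg

        summaries = []
        dists = {}
        ests = {}
        for stage, grp in samples.groupby("stage", sort=False):
            s = summarize_stage(
                grp,
                stage,
                class_width=cfg["class_width"],
                reference_1C=ref,
                plus_threshold=cfg["plus_threshold"],
            )
            summaries.append(s)
            dists[stage] = s.distribution
            ests[stage] = peak_class_mean(s.distribution)
            s.distribution.to_frame().to_csv(out / f"histogram_{stage}.csv", index=False)

        summary_rows = pd.DataFrame([s.to_row() for s in summaries])
        summary_rows.to_csv(out / "summary.csv", index=False)
        dio.save_json(
            [
                {
                    k: v
                    for k, v in vars(s).items()
                    if k != "distribution" and not isinstance(v, pd.DataFrame)
                }
                for s in summaries
            ],
            out / "summaries.json",
        )
        dio.save_table(records, out / "measurements.csv")
        dio.save_json(
            {k: {**{kk: vv for kk, vv in vars(c).items() if kk != "iods"}, "n": c.n}
             for k, c in cals.items()},
            out / "calibration.json",
        )

        if samples["nrs"].notna().sum() >= 3 and samples["nrs"].std() > 0:
            corr = size_content_correlation(samples)
            dio.save_json(corr.to_dict(), out / "correlation.json")
        else:
            corr = None
            logger.info("no usable nrs values; correlation report skipped")

        dio.save_json({k: (v if not isinstance(v, tuple) else list(v)) for k, v in cfg.items()},
                      out / "config_resolved.json")

        if cfg["plots"]:
            from .plotting import plot_histogram_panels, plot_size_content

            plot_histogram_panels(dists, out / "histograms.png", estimates=ests)
            if corr is not None:
                plot_size_content(samples, out / "size_vs_content.png")
        return out
    finally:
        root.removeHandler(handler)
        handler.close()
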