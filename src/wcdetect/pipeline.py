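"""End-to-end orchestration: simulate → clean → extract → features → classify.

``run_pipeline`` drives the whole chain from a structured configuration
(see :func:`demo_config` for a complete example) and records every stage
count in a :class:`~wcdetect.io.RunManifest`.  The intermediate entry
points (:func:`process_survey`, :func:`features_from_survey`,
:func:`train_from_table`) are what the CLI subcommands call.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import classify, echogram, extract, io, metrics, seafloor, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "demo_config",
    "assign_operator_labels",
    "process_survey",
    "features_from_survey",
    "train_from_table",
    "run_pipeline",
]

#: processing defaults (dB offsets are relative to the background level)
DEFAULT_PROCESSING = {
    # glare pings are hot across the *whole* valid range (fraction ~1.0);
    # pings holding a full-column target plus the outer-beam seafloor band
    # legitimately reach ~0.94, so the cut sits above that
    "bad_ping_frac_threshold": 0.98,
    "bad_ping_sv_offset": 15.0,
    "bottom_window_pings": 5,
    "bottom_min_peak_offset": 30.0,
    "surface_sv_offset": 8.0,
    "surface_line_offset": 0.5,
    "surface_line_max": 12.0,
    "near_field": 4.0,
    "tin_offset": 2.0,
    "tin_sounding_stride": 5,
    "detection_sv_offset": 10.0,
    "min_height": 1.0,
    "min_width": 1.0,
    "track_max_distance": 5.0,
    "track_max_ping_gap": 1,
}

DEFAULT_ML = {
    "label_fraction": 0.15,
    "knn_k": 5,
    "test_fraction": 0.3,
    "cv_folds": 5,
}


def demo_config(seed: int = 0, pings_per_transect: int = 100) -> dict:
    """A complete labelled demo scene: all four target classes over ~500 pings.

    Geometry follows the instrument defaults (dual 75.1° fans, 512 beams,
    2.6 Hz, 0.64 m bins) over a 77 m-deep, 200 m-square site with five
    transects: a four-legged platform at the centre, gas seeps in one
    corner, drifting fish schools, shallow noise patches, plus sidelobe
    arcs, a 3 m entrained-air surface layer and a little bad-ping glare.
    """
    targets = [
        # drifting fish schools (horizontal speed < 5 m/s)
        {"klass": "FISH", "anchor": [15.0, 40.0, 55.0], "dims": [8.0, 6.0, 5.0],
         "sv_offset": 15.0, "velocity": [0.5, 0.2, 0.0]},
        {"klass": "FISH", "anchor": [60.0, 25.0, 40.0], "dims": [7.0, 5.0, 4.0],
         "sv_offset": 16.0, "velocity": [-0.4, 0.3, 0.0]},
        {"klass": "FISH", "anchor": [30.0, 150.0, 62.0], "dims": [9.0, 6.0, 5.0],
         "sv_offset": 15.0, "velocity": [0.8, -0.2, 0.0]},
        {"klass": "FISH", "anchor": [70.0, 170.0, 35.0], "dims": [6.0, 5.0, 4.0],
         "sv_offset": 16.0, "velocity": [-0.6, 0.0, 0.0]},
        {"klass": "FISH", "anchor": [20.0, 95.0, 68.0], "dims": [8.0, 7.0, 4.0],
         "sv_offset": 15.0, "velocity": [0.3, 0.5, 0.0]},
        {"klass": "FISH", "anchor": [55.0, 120.0, 50.0], "dims": [7.0, 6.0, 5.0],
         "sv_offset": 15.0, "velocity": [0.0, -0.4, 0.0]},
        # gas seeps rising from the seabed in the SE corner
        {"klass": "GAS", "anchor": [55.0, 35.0, 77.0], "dims": [3.0, 2.5, 15.0],
         "sv_offset": 18.0, "velocity": [0.0, 0.0, -12.0]},
        {"klass": "GAS", "anchor": [65.0, 45.0, 77.0], "dims": [3.0, 2.5, 14.0],
         "sv_offset": 18.0, "velocity": [0.0, 0.0, -11.0]},
        {"klass": "GAS", "anchor": [45.0, 55.0, 77.0], "dims": [3.0, 3.0, 16.0],
         "sv_offset": 17.0, "velocity": [0.0, 0.0, -13.0]},
        {"klass": "GAS", "anchor": [60.0, 60.0, 77.0], "dims": [3.0, 2.5, 15.0],
         "sv_offset": 18.0, "velocity": [0.0, 0.0, -12.0]},
        # the four platform legs (static, near-surface to seafloor)
        {"klass": "PLATFORM", "anchor": [32.0, 92.0, 40.5], "dims": [2.0, 2.0, 73.0],
         "sv_offset": 20.0},
        {"klass": "PLATFORM", "anchor": [32.0, 108.0, 40.5], "dims": [2.0, 2.0, 73.0],
         "sv_offset": 20.0},
        {"klass": "PLATFORM", "anchor": [48.0, 92.0, 40.5], "dims": [2.0, 2.0, 73.0],
         "sv_offset": 20.0},
        {"klass": "PLATFORM", "anchor": [48.0, 108.0, 40.5], "dims": [2.0, 2.0, 73.0],
         "sv_offset": 20.0},
        # diffuse shallow noise patches (entrained air below the surface layer)
        {"klass": "NOISE", "anchor": [25.0, 60.0, 7.0], "dims": [10.0, 12.0, 2.5],
         "sv_offset": 12.0},
        {"klass": "NOISE", "anchor": [50.0, 140.0, 8.0], "dims": [12.0, 10.0, 2.5],
         "sv_offset": 12.0},
        {"klass": "NOISE", "anchor": [40.0, 15.0, 6.5], "dims": [10.0, 10.0, 2.0],
         "sv_offset": 13.0},
    ]
    return {
        "survey": {
            "water_depth": 77.0,
            "area_side": 200.0,
            "n_transects": 5,
            "transect_spacing": 40.0,
            "vessel_speed": 2.0,
            "pings_per_transect": pings_per_transect,
            "seed": seed,
        },
        "targets": targets,
        "noise": {"surface_layer_depth": 3.0, "bad_ping_fraction": 0.01},
        "processing": dict(DEFAULT_PROCESSING),
        "ml": dict(DEFAULT_ML),
    }


def _build_scene(config: dict):
    survey_cfg = simulate.SurveyConfig(**config.get("survey", {}))
    targets = [simulate.TargetSpec(
        klass=t["klass"],
        anchor=tuple(t["anchor"]),
        dims=tuple(t["dims"]),
        sv_offset=t.get("sv_offset", 15.0),
        velocity=tuple(t.get("velocity", (0.0, 0.0, 0.0))),
        persistence=t.get("persistence"),
        t_start=t.get("t_start", 0.0),
    ) for t in config.get("targets", [])]
    noise = config.get("noise")
    noise_cfg = simulate.NoiseConfig(**noise) if noise is not None else None
    return survey_cfg, targets, noise_cfg


def process_survey(
    fans: Sequence[simulate.PingFan],
    background_sv: float,
    params: Optional[dict] = None,
) -> dict:
    """Run the cleaning + extraction chain on a ping sequence.

    Returns a dict with the stacked echogram, virtual lines, the seafloor
    TIN, retained/of-interest ping ids, slices and multi-ping objects.
    """
    p = {**DEFAULT_PROCESSING, **(params or {})}
    bg = background_sv

    soundings = seafloor.soundings_from_survey(
        fans, min_sv=bg + p["bottom_min_peak_offset"], stride=p["tin_sounding_stride"]
    )
    tin = seafloor.build_and_resample_tin(soundings) if len(soundings) >= 3 else None

    stacked = echogram.stack_max_intensity(fans)
    retained_ids = echogram.reject_bad_pings(
        stacked, p["bad_ping_frac_threshold"], bg + p["bad_ping_sv_offset"]
    )
    keep = np.isin(stacked.ping_ids, retained_ids)
    stacked_r = echogram.StackedEchogram(
        stacked.values[keep], stacked.ping_ids[keep], stacked.range_axis
    )
    cleaned = echogram.erosion_3x3(echogram.median_3x3(stacked_r))
    bottom = echogram.best_bottom_candidate(
        cleaned, p["bottom_window_pings"], bg + p["bottom_min_peak_offset"],
        min_range=p["near_field"],
    )
    surface_ref = echogram.VirtualLine(
        cleaned.ping_ids.copy(), np.zeros(len(cleaned.ping_ids)), kind="surface-exclusion"
    )
    surface = echogram.threshold_offset_line(
        cleaned, surface_ref, bg + p["surface_sv_offset"], p["surface_line_offset"]
    )
    surface.ranges = np.minimum(surface.ranges, p["surface_line_max"])
    poi = echogram.select_pings_of_interest(
        cleaned, surface, bottom, bg + p["detection_sv_offset"]
    )

    id_to_index = {f.ping_id: i for i, f in enumerate(fans)}
    surf_by_id = dict(zip(surface.ping_ids.tolist(), surface.ranges))

    slices: list[extract.SliceRegion] = []
    sid = 0
    for pid in poi:
        # the convolution neighbourhood is the true consecutive ping
        # sequence, not the selected subset
        fan = fans[id_to_index[pid]]
        sm = echogram.smooth_fan_45(fans, id_to_index[pid])
        mask = echogram.exclusion_mask(
            sm, tin, near_field=p["near_field"], tin_offset=p["tin_offset"]
        )
        s = surf_by_id.get(fan.ping_id)
        if s is not None and np.isfinite(s):
            mask |= (fan.geometry.ranges < s)[None, None, :]
        new = extract.detect_slices(
            sm, bg + p["detection_sv_offset"], p["min_height"], p["min_width"],
            mask=mask, first_slice_id=sid,
        )
        sid += len(new)
        slices.extend(new)
    objects = extract.track_regions(
        slices, p["track_max_distance"], p["track_max_ping_gap"]
    )
    return {
        "tin": tin,
        "stacked": stacked,
        "cleaned": cleaned,
        "bottom_line": bottom,
        "surface_line": surface,
        "retained_ping_ids": retained_ids,
        "pings_of_interest": poi,
        "slices": slices,
        "objects": objects,
    }


def object_truth_labels(
    slices: Sequence[extract.SliceRegion],
    objects: Sequence[extract.MultiPingObject],
) -> dict[int, str]:
    """Ground-truth class per slice, aggregated over its multi-ping object.

    The vote pools the linear-power-weighted truth codes of every member
    sample of every slice in the object, the way an operator judges the
    object as a whole; slices of an object with no injected cause at all
    are NOISE.  Per-ping "ghost" slices (the along-track smoothing halo of
    a moving target) thereby inherit the class of the object they belong
    to.
    """
    by_id = {s.slice_id: s for s in slices}
    out: dict[int, str] = {}
    for obj in objects:
        power = np.zeros(5)
        for sid in obj.slice_ids:
            s = by_id[sid]
            sel = s.truth > 0
            if sel.any():
                w = 10.0 ** (np.asarray(s.sv, dtype=float)[sel] / 10.0)
                power += np.bincount(s.truth[sel], weights=w, minlength=5)
        label = (
            simulate.CLASS_NAMES[int(np.argmax(power))] if power.any() else "NOISE"
        )
        for sid in obj.slice_ids:
            out[sid] = label
    for s in slices:  # slices not assigned to any object
        out.setdefault(s.slice_id, s.truth_label())
    return out


def assign_operator_labels(
    slices: Sequence[extract.SliceRegion],
    fraction: float,
    seed: int,
    truth: Optional[dict[int, str]] = None,
) -> dict[int, str]:
    """Emulate manual review: label a seeded subset of slices from truth.

    The subset is portioned as equally as possible among the classes
    present, mirroring a stratified manual review.
    """
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = {s.slice_id: s.truth_label() for s in slices}
    by_class: dict[str, list[int]] = {}
    for sid, lab in truth.items():
        by_class.setdefault(lab, []).append(sid)
    n_total = max(1, int(round(fraction * len(slices))))
    per_class = max(2, n_total // max(1, len(by_class)))
    labels: dict[int, str] = {}
    for lab, sids in sorted(by_class.items()):
        chosen = rng.choice(sids, size=min(per_class, len(sids)), replace=False)
        for sid in chosen:
            labels[int(sid)] = lab
    return labels


def features_from_survey(
    fans: Sequence[simulate.PingFan],
    background_sv: float,
    origin: tuple[float, float],
    params: Optional[dict] = None,
    seed: int = 0,
    labels: Optional[dict[int, str]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Cleaning, extraction and the 24-metric table in one call."""
    result = process_survey(fans, background_sv, params)
    table = metrics.build_feature_table(
        result["slices"], result["objects"], origin, seed=seed, labels=labels
    )
    return table, result


def train_from_table(
    table: pd.DataFrame, ml_params: Optional[dict] = None, seed: int = 0
) -> dict:
    """Label extension → normalization → pseudo-labelling → split → ensemble."""
    p = {**DEFAULT_ML, **(ml_params or {})}
    extended = classify.extend_labels(table)
    normed, normalizer = classify.normalize_features(extended)
    mi = classify.mutual_info_scores(normed, seed=seed)
    pseudo, knn_report, knn_cm = classify.pseudo_label(
        normed, k=p["knn_k"], seed=seed
    )
    train, test = classify.stratified_split(
        pseudo, test_fraction=p["test_fraction"], seed=seed
    )
    bundle = classify.train_ensemble(
        train, normalizer, seed=seed, cv=p["cv_folds"],
        knn_spec={"k": p["knn_k"], "metric": "euclidean", "weights": "distance"},
    )
    report, cm = classify.evaluate(bundle, test)
    return {
        "extended": extended,
        "normalized": normed,
        "pseudo": pseudo,
        "mutual_info": mi,
        "knn_report": knn_report,
        "knn_confusion": knn_cm,
        "train": train,
        "test": test,
        "bundle": bundle,
        "report": report,
        "confusion": cm,
    }


def run_pipeline(config: dict, outdir, seed: Optional[int] = None) -> io.RunManifest:
    """Execute the configured stages and write artifacts + manifest.

    Deterministic for a fixed seed; each stage failure aborts with the
    stage name in the exception message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = {**config, "survey": {**config.get("survey", {}), "seed": seed}}
    survey_cfg, targets, noise_cfg = _build_scene(config)
    run_seed = survey_cfg.seed

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    fans = stage("simulate", simulate.generate_survey, survey_cfg, targets, noise_cfg)
    origin = (survey_cfg.origin_lat, survey_cfg.origin_lon)
    result = stage(
        "extract", process_survey, fans, survey_cfg.background_sv,
        config.get("processing"),
    )
    slices, objects = result["slices"], result["objects"]
    ml_p = {**DEFAULT_ML, **config.get("ml", {})}
    truth_map = object_truth_labels(slices, objects)
    labels = assign_operator_labels(
        slices, ml_p["label_fraction"], run_seed, truth=truth_map
    )
    table = stage(
        "features", metrics.build_feature_table, slices, objects, origin,
        seed=run_seed, labels=labels,
    )
    ml = stage("train", train_from_table, table, ml_p, seed=run_seed)

    pred = stage(
        "predict", classify.predict_unseen, ml["bundle"], table, seed=run_seed
    )
    truth = np.array([truth_map[s.slice_id] for s in slices])
    accuracy = float((pred == truth).mean())

    io.write_feature_csv(table, outdir / "features.csv")
    io.write_slices_csv(slices, outdir / "slices.csv")
    ml["bundle"].save(outdir / "model_bundle.joblib")
    ml["report"].to_csv(outdir / "ensemble_report.csv")
    if len(ml["knn_report"]):
        ml["knn_report"].to_csv(outdir / "pseudo_label_report.csv")
    io.write_line_csv(result["bottom_line"], outdir / "bottom_line.csv")
    io.write_line_csv(result["surface_line"], outdir / "surface_line.csv")
    if result["tin"] is not None:
        result["tin"].to_ascii_grid(outdir / "seafloor.asc")

    manifest = io.RunManifest(
        config=config,
        seed=run_seed,
        counts={
            "n_pings": len(fans),
            "pings_retained": int(len(result["retained_ping_ids"])),
            "pings_of_interest": int(len(result["pings_of_interest"])),
            "n_slices": len(slices),
            "n_objects": len(objects),
            "rows_labelled": int((table["label"] != "").sum()),
            "rows_after_extension": int((ml["extended"]["label"] != "").sum()),
            "ensemble_test_accuracy": float(
                ml["report"].loc["accuracy", "F1-Score"]
            ),
            "truth_accuracy_all_slices": accuracy,
        },
        outputs={"dir": str(outdir)},
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
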