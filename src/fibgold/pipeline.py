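"""Stage orchestration: configuration, artifacts, consolidated report.

Stages communicate only through their on-disk artifacts, so re-running a
single stage from the files of a previous run is identical to running end to
end.  Every report records the configuration hash and seed so each number is
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect, preprocess, quantify, segment, spatial, stack_io, synth
from .detectability import DetectionGeometry
from .errors import ConfigError, FibgoldError

_KNOWN_KEYS = {"seed", "voxel_size", "input", "simulate", "preprocess",
               "segment", "detect", "quantify", "spatial"}


class StageError(FibgoldError):
    """An error attributed to one named pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    return validate_config(config)


def validate_config(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ConfigError("pipeline config must be a mapping")
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "simulate" not in config and "input" not in config:
        raise ConfigError("config needs either a 'simulate' block or an 'input' stack path")
    if "input" in config:
        stack_path = Path(config["input"].get("stack", ""))
        if not stack_path.exists():
            raise StageError("input", f"stack file does not exist: {stack_path}")
        if "voxel_size" not in config and "voxel_size" not in config["input"]:
            raise StageError("input", "voxel_size must be given for an input stack")
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _simulation_config(config: dict) -> synth.SimulationConfig:
    block = dict(config.get("simulate") or {})
    block.setdefault("seed", int(config.get("seed", 0)))
    if "densities" in block:
        block["densities"] = {int(k): float(v) for k, v in block["densities"].items()}
    if "base_intensities" in block:
        block["base_intensities"] = {int(k): float(v)
                                     for k, v in block["base_intensities"].items()}
    geom = block.pop("detection_geometry", None)
    for key in ("shape", "voxel_size", "cell_semiaxes", "nucleolus_offset"):
        if key in block:
            block[key] = tuple(block[key])
    try:
        sim = synth.SimulationConfig(**block)
        if geom:
            sim = sim.with_(detection_geometry=DetectionGeometry(**geom))
    except TypeError as exc:
        raise ConfigError(f"bad simulate block: {exc}") from exc
    return sim


def _geometry(config: dict) -> DetectionGeometry:
    block = dict(config.get("quantify") or {})
    return DetectionGeometry(
        d=float(block.get("d", 20.0)),
        t=float(block.get("t", config.get("voxel_size", [25.0])[0])),
        p=float(block.get("p", 0.0)),
    )


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured stages in order, writing every artifact under
    ``outdir``; returns a manifest of artifact paths plus the report dict."""
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {"config_hash": config_hash(config), "seed": seed}
    log_path = outdir / "pipeline.log"
    log_lines = [f"config_hash={manifest['config_hash']} seed={seed}"]

    # --- simulate / input ---------------------------------------------------
    truth = None
    if "simulate" in config:
        try:
            sim = _simulation_config(config)
            stack, truth = synth.simulate(sim)
            stack_io.write_stack(outdir / "stack.tif", stack)
            stack_io.write_labels(outdir / "labels_true.tif", truth.label_volume)
            truth.positions.to_csv(outdir / "truth.csv", index=False,
                                   float_format="%.9g", lineterminator="\n")
            log_lines.append(f"simulate: {len(truth)} particles, "
                             f"config={dataclasses.asdict(sim.detection_geometry)}")
        except FibgoldError as exc:
            raise StageError("simulate", str(exc)) from exc
        voxel_size = sim.voxel_size
    else:
        block = config["input"]
        voxel_size = tuple(block.get("voxel_size", config.get("voxel_size")))
        try:
            stack = stack_io.read_stack(block["stack"], voxel_size)
        except FibgoldError as exc:
            raise StageError("input", str(exc)) from exc

    # --- preprocess ---------------------------------------------------------
    pre = dict(config.get("preprocess") or {})
    try:
        if pre.get("invert", False):
            stack = preprocess.invert(stack)
        if pre.get("remove_drift", True):
            stack = preprocess.remove_slice_drift(stack)
        stack = preprocess.normalize(
            stack, mode=pre.get("normalize", "global"),
            clip_percentiles=tuple(pre.get("clip_percentiles", (0.0, 100.0))))
        if pre.get("align", True):
            stack, alignment = preprocess.align(
                stack, reference=pre.get("reference", "previous"),
                max_shift=pre.get("max_shift"), upsample=int(pre.get("upsample", 1)),
                detrend=pre.get("detrend", True))
            pd.DataFrame(alignment.shifts, columns=["dy_px", "dx_px"]).to_csv(
                outdir / "shifts.csv", index_label="slice", lineterminator="\n")
        if pre.get("crop"):
            stack = preprocess.crop_center(stack, tuple(pre["crop"]))
        stack_io.write_stack(outdir / "pre.tif", stack)
        log_lines.append(f"preprocess: {pre or 'defaults'}")
    except FibgoldError as exc:
        raise StageError("preprocess", str(exc)) from exc

    # --- segment ------------------------------------------------------------
    seg = dict(config.get("segment") or {})
    try:
        seeds = {int(lab): tuple(int(v) for v in s)
                 for lab, s in (seg.get("seeds") or {}).items()}
        bands = {int(lab): (b if b == "auto" else tuple(b))
                 for lab, b in (seg.get("bands") or {}).items()}
        if seeds and not bands:
            bands = {lab: "auto" for lab in seeds}
        params = segment.SegmentationParams(
            bands=bands, seeds=seeds,
            connectivity=int(seg.get("connectivity", 26)),
            min_object_voxels=int(seg.get("min_object_voxels", 100)),
            closing_radius=int(seg.get("closing_radius", 1)),
            smooth_sigma=float(seg.get("smooth_sigma", 2.0)),
        )
        if seeds:
            labels = segment.segment_semiautomatic(stack, params)
        else:
            labels = segment.segment_auto(stack, params)
        stack_io.write_labels(outdir / "labels.tif", labels)
        volumes = segment.compartment_volumes(labels)
        pd.DataFrame(sorted(volumes.items()), columns=["compartment", "volume_um3"]).to_csv(
            outdir / "volumes.csv", index=False, float_format="%.9g", lineterminator="\n")
        log_lines.append(f"segment: auto, {params}")
    except FibgoldError as exc:
        raise StageError("segment", str(exc)) from exc

    # --- detect -------------------------------------------------------------
    det = dict(config.get("detect") or {})
    geom = _geometry(config)
    try:
        params = detect.DetectionParams(
            threshold=det.get("threshold", "auto"),
            k_sigma=float(det.get("k_sigma", 6.0)),
            connectivity=int(det.get("connectivity", 26)),
            min_voxels=int(det.get("min_voxels", 2)),
            max_voxels=det.get("max_voxels",
                               detect.default_max_voxels(geom, stack.voxel_size)),
            slice_gap_tolerance=int(det.get("slice_gap_tolerance", 0)),
        )
        particles = detect.find_particles(stack, params, labels=labels)
        stack_io.write_particles(particles, outdir / "particles.csv")
        log_lines.append(f"detect: {len(particles)} particles, {params}")
    except FibgoldError as exc:
        raise StageError("detect", str(exc)) from exc

    # --- quantify -----------------------------------------------------------
    q = dict(config.get("quantify") or {})
    try:
        in_cell = particles[particles["compartment"] > 0]
        n_outside = int((particles["compartment"] == 0).sum())
        table = quantify.compartment_table(in_cell, labels)
        report = quantify.enrichment_report(
            table, geom,
            nucleus_diameter_um=float(q.get("nucleus_diameter_um", 14.0)),
            assumed_total=q.get("assumed_total"),
            n_outside=n_outside)
        table_frame = pd.DataFrame(
            [(s.name, s.n, s.volume_um3, s.density, s.density_rounded) for s in table],
            columns=["compartment", "number", "volume_um3", "density", "density_1dp"])
        table_frame.to_csv(outdir / "table.csv", index=False,
                           float_format="%.9g", lineterminator="\n")
        with open(outdir / "report.json", "w") as fh:
            json.dump({"config_hash": manifest["config_hash"], "seed": seed,
                       "geometry": dataclasses.asdict(geom),
                       "table": table_frame.to_dict(orient="records"),
                       "enrichment": dataclasses.asdict(report)},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")
        log_lines.append("quantify: done")
    except FibgoldError as exc:
        raise StageError("quantify", str(exc)) from exc

    # --- spatial ------------------------------------------------------------
    sp = dict(config.get("spatial") or {})
    domains = {"nucleus": stack_io.NUCLEUS_LABELS, "euchromatin": frozenset({2}),
               "cytoplasm": frozenset({1}), "cell": stack_io.CELL_LABELS}
    compartment = sp.get("compartment", "nucleus")
    if compartment not in domains:
        raise StageError("spatial", f"unknown compartment {compartment!r}")
    try:
        domain = domains[compartment]
        n_domain = int(particles["compartment"].isin(domain).sum())
        if n_domain < 2:
            # a sparse pattern is a reportable outcome, not a pipeline failure
            result = {"n": n_domain, "insufficient_points": True}
        else:
            result = spatial.analyze(
                particles, labels, domain,
                r_nm=float(sp.get("radius_nm", 200.0)),
                n_reps=int(sp.get("n_reps", 199)),
                seed=int(sp.get("seed", seed)))
        with open(outdir / "spatial.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log_lines.append(f"spatial: n={result['n']} clustered={result.get('clustered')}")
    except FibgoldError as exc:
        raise StageError("spatial", str(exc)) from exc

    _qc_projections(stack, outdir)
    log_path.write_text("\n".join(log_lines) + "\n")
    manifest.update({
        "table": str(outdir / "table.csv"),
        "report": str(outdir / "report.json"),
        "spatial": str(outdir / "spatial.json"),
        "log": str(log_path),
        "n_particles": int(len(particles)),
    })
    return manifest


def _qc_projections(stack, outdir: Path) -> None:
    """Max-intensity projections along each axis as PNG quality-control images."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for axis, name in enumerate(("z", "y", "x")):
        proj = np.max(stack.data, axis=axis)
        plt.imsave(outdir / f"qc_max_{name}.png", proj, cmap="gray")
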