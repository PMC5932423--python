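"""End-to-end pipeline orchestration with reproducible run manifests.

Stage order mirrors the two-camera processing chain: acquisition (real pair
or synthetic fixture) -> IR segmentation + visible simplification + fusion
-> nonlinear retargeting -> stimulator encoding and percept simulation.
Every stage's output is written to the run directory and hashed into a
manifest, so two runs with the same config are byte-identical and
verifiable.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np

from . import encode, fusion, retarget, segmentation, simplify
from .imaging import (
    GrayImage,
    IRFrame,
    SceneFixture,
    load_gray,
    save_gray,
    standard_scene,
)

__all__ = ["DEFAULT_CONFIG", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "input": {"fixture": {"seed": 0, "width": 128, "height": 128}},
    "mode": "edge",  # edge | cartoon
    "array": [32, 32],
    "shrink": 0.3,
    "sigma": None,  # IR smoothing scale; None -> 2% of the short side
    "diffusion": {"dt": 0.2, "n_iter": 15},
    "cartoon": {"n_bins": 8, "phi_q": 20.0, "edge_floor": 0.25},
    "encoding": {"input_gain": 20.0, "dt_ms": 0.5, "duration_ms": 100.0},
    "stage_only": None,
}

_STAGES = (
    "segmentation",
    "diffused",
    "gradient",
    "cartoon",
    "edge_weighted",
    "fused",
    "retargeted",
    "percept",
    "spikes",
    "pulses",
)


def _merge_config(config: dict | None) -> dict:
    merged = copy.deepcopy(DEFAULT_CONFIG)
    if config:
        bad = sorted(set(config) - set(DEFAULT_CONFIG))
        if bad:
            raise ValueError(
                f"unknown config keys {bad}; accepted keys: {sorted(DEFAULT_CONFIG)}"
            )
        for key, value in config.items():
            if isinstance(value, dict) and isinstance(merged[key], dict):
                sub_bad = sorted(set(value) - set(merged[key]))
                if key != "input" and sub_bad:
                    raise ValueError(
                        f"unknown {key} keys {sub_bad}; accepted: {sorted(merged[key])}"
                    )
                merged[key] = {**merged[key], **value}
            else:
                merged[key] = value
    return merged


def _acquire(input_cfg: dict) -> tuple[GrayImage, IRFrame, SceneFixture | None]:
    if "fixture" in input_cfg:
        fix = standard_scene(**input_cfg["fixture"])
        return fix.visible, fix.ir, fix
    visible = load_gray(input_cfg["visible"])
    import imageio.v3 as iio

    ir = IRFrame(iio.imread(input_cfg["ir"]), tuple(input_cfg.get("gain_range", (0.0, 40.0))))
    if ir.shape != visible.shape:
        from .imaging import resize_to

        visible = resize_to(visible, ir.shape)
    return visible, ir, None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_events(path: Path, schedule_like, kind: str) -> None:
    with path.open("w") as fh:
        if kind == "spikes":
            for i, times in enumerate(schedule_like.trains):
                for t in times:
                    fh.write(json.dumps({"stimulator": i, "t_ms": round(float(t), 4)}) + "\n")
        else:
            for i, pulses in enumerate(schedule_like.pulses):
                for onset, width in pulses:
                    fh.write(
                        json.dumps(
                            {"stimulator": i, "onset_ms": round(float(onset), 4),
                             "width_ms": float(width)}
                        )
                        + "\n"
                    )


def run_pipeline(config: dict | None = None, out_dir: str | Path = "run") -> dict:
    """Run the full chain and write one artifact per stage plus a manifest.

    ``config`` overrides :data:`DEFAULT_CONFIG`; unknown keys raise with the
    accepted list.  ``stage_only`` restricts the written artifacts to a
    single named stage.  Returns the manifest (params + artifact hashes).
    """
    cfg = _merge_config(config)
    if cfg["stage_only"] is not None and cfg["stage_only"] not in _STAGES:
        raise ValueError(f"unknown stage {cfg['stage_only']!r}; stages: {list(_STAGES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    visible, ir, fix = _acquire(cfg["input"])
    dp = simplify.DiffusionParams(**cfg["diffusion"])
    cp = simplify.CartoonParams(**cfg["cartoon"])

    seg = segmentation.segment(ir, cfg["sigma"])
    stages = simplify.simplify_chain(visible, dp, cp)
    if cfg["mode"] == "edge":
        fused = fusion.fuse_edge_weighted(seg, visible, stages["edge_weighted"])
    elif cfg["mode"] == "cartoon":
        fused = fusion.fuse_cartoon(seg, stages["cartoon"], visible)
    else:
        raise ValueError(f"unknown mode {cfg['mode']!r}; expected 'edge' or 'cartoon'")

    m = retarget.importance_matrix(simplify.gradient_magnitude(fused), seg)
    k_c = int(round(cfg["shrink"] * visible.width))
    k_r = int(round(cfg["shrink"] * visible.height))
    retargeted = retarget.retarget(fused, m, k_c, k_r)

    n_x, n_y = cfg["array"]
    array_cfg = encode.StimArrayConfig(n_x=n_x, n_y=n_y)
    drive = np.abs(encode.approx_bipolar(encode.bipolar_split(retargeted)))
    drive_grid = np.clip(
        encode.box_resample(drive / max(drive.max(), 1e-12), (n_y, n_x)), 0.0, 1.0
    )
    izp = encode.IzhikevichParams(**cfg["encoding"])
    spikes = encode.izhikevich_spikes(drive_grid, izp)
    pulses = encode.chr2_pulse_schedule(spikes)
    percept = encode.simulate_percept(retargeted, array_cfg)

    writers = {
        "segmentation": lambda p: save_gray(GrayImage(seg.values), p),
        "diffused": lambda p: save_gray(stages["diffused"], p),
        "gradient": lambda p: save_gray(GrayImage(stages["gradient"].normalized), p),
        "cartoon": lambda p: save_gray(stages["cartoon"], p),
        "edge_weighted": lambda p: save_gray(stages["edge_weighted"], p),
        "fused": lambda p: save_gray(fused, p),
        "retargeted": lambda p: save_gray(retargeted, p),
        "percept": lambda p: save_gray(percept, p),
        "spikes": lambda p: _write_events(p, spikes, "spikes"),
        "pulses": lambda p: _write_events(p, pulses, "pulses"),
    }
    wanted = [cfg["stage_only"]] if cfg["stage_only"] else list(_STAGES)
    artifacts: dict[str, str] = {}
    for name in wanted:
        suffix = ".jsonl" if name in ("spikes", "pulses") else ".png"
        path = out / f"{name}{suffix}"
        writers[name](path)
        artifacts[path.name] = _sha256(path)

    manifest = {
        "params": cfg,
        "seed": cfg["input"].get("fixture", {}).get("seed"),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
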