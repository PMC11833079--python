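"""Configuration-driven end-to-end runs with seeds and provenance.

Stage order: synthesize ground truth -> rasterize -> CT degradation ->
IQI resolution estimate -> segmentation -> canal-network morphometry ->
micro-FE homogenization for the three canal-phase scenarios -> phase
comparison.  Any stage can be bypassed by supplying its input artifact
(e.g. a pre-segmented label volume from a real scan).  One root seed
fans out to deterministic per-stage seeds so stages can be rerun in
isolation; every output is traceable to the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np

from . import microfe, network, resolution, segmentation, synthetic
from .io import GrayVolume, LabelVolume, read_gray_volume, read_label_volume, write_gray_volume, write_label_volume

__all__ = ["default_config", "run_pipeline", "stage_seed"]


def default_config() -> dict:
    """The default study configuration (a plain, serializable mapping)."""
    return {
        "seed": 0,
        "generator": {},  # overrides for synthetic.GeneratorParams
        "imaging": {},  # overrides for synthetic.ImagingParams
        "segmentation": {
            "alpha": 0.5,
            "min_voxels": 27,
            "connectivity": 26,
            "denoise_strength": 0.8,
        },
        "resolution": {"threshold": 0.10},
        "network": {"exclude_above": 30.0, "n_bins": 8},
        "fe": {
            "enabled": True,
            "strain": 0.02,
            "tol": 1.0e-4,
            # cuboid extracted from the middle (cellular) zone of the wall,
            # away from the pore-dominated core, like a cut cortical coupon
            "crop": [128, 128, 256],  # voxels
            "crop_anchor": "cortical",  # "cortical" (outer corner) | "center"
            "downsample": 2,
            "scenarios": ["solid", "liquid", "gas"],
        },
        "materials": {},  # overrides for microfe.MaterialSpec phases
        "inputs": {"gray_path": None, "label_path": None},
    }


_KNOWN_KEYS = set(default_config())


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict) -> dict:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = _merge(default_config(), config)
    if cfg["fe"]["downsample"] < 1 or int(cfg["fe"]["downsample"]) != cfg["fe"]["downsample"]:
        raise ValueError("fe.downsample must be a positive integer")
    for scen in cfg["fe"]["scenarios"]:
        if scen not in microfe.SCENARIOS:
            raise ValueError(f"unknown FE scenario {scen!r}")
    return cfg


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _material_spec(cfg: dict) -> microfe.MaterialSpec:
    spec = microfe.MaterialSpec()
    overrides = cfg.get("materials") or {}
    fields = {}
    for phase in ("bone", "canal_liquid", "canal_gas"):
        if phase in overrides:
            fields[phase] = microfe.Material(**overrides[phase])
    return dataclasses.replace(spec, **fields) if fields else spec


def run_pipeline(
    config: dict | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Execute the pipeline; returns the result bundle as a dict.

    With ``outdir`` set, every intermediate artifact (truth labels,
    grayscale volume, segmented labels, statistics, constants, comparison
    table, provenance log) is written there.
    """
    cfg = validate_config(config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    root = int(cfg["seed"])
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {"config": cfg, "config_hash": _config_hash(cfg)}
    prov: dict[str, Any] = {"config_hash": bundle["config_hash"], "stages": {}}
    t_all = time.time()

    def _tick(stage: str, t0: float, **info):
        prov["stages"][stage] = {"wall_s": round(time.time() - t0, 3), **info}

    # --- synthesis / inputs -------------------------------------------------
    truth_label = None
    gray = None
    label = None
    inputs = cfg["inputs"]
    if inputs.get("label_path"):
        label = read_label_volume(inputs["label_path"])
        prov["stages"]["inputs"] = {"label_path": str(inputs["label_path"])}
    elif inputs.get("gray_path"):
        gray = read_gray_volume(inputs["gray_path"])
        prov["stages"]["inputs"] = {"gray_path": str(inputs["gray_path"])}
    else:
        t0 = time.time()
        gp = synthetic.GeneratorParams(**cfg["generator"], seed=stage_seed(root, "generator"))
        net = synthetic.sample_canal_network(gp)
        truth_label = synthetic.rasterize_network(net, gp)
        _tick("synthesize", t0, n_centerlines=len(net.centerlines),
              n_pores=len(net.large_pores), porosity=float(np.mean(truth_label.labels == 2)))
        bundle["truth_network"] = net
        bundle["truth_label"] = truth_label
        t0 = time.time()
        ip = synthetic.ImagingParams(**cfg["imaging"], seed=stage_seed(root, "imaging"))
        gray = synthetic.simulate_ct(truth_label, ip)
        _tick("simulate_ct", t0, psf_sigma=ip.psf_sigma, noise_sd=ip.noise_sd)
        if out is not None:
            write_label_volume(truth_label, out / "truth_labels.tif")
            write_gray_volume(gray, out / "gray.tif")

    # --- resolution (IQI) ---------------------------------------------------
    res_um = None
    if label is None:
        t0 = time.time()
        ip = synthetic.ImagingParams(**cfg["imaging"], seed=stage_seed(root, "imaging"))
        pixel = gray.spacing[0]
        img, layout = synthetic.generate_iqi_image(
            psf_sigma=ip.psf_sigma, noise_sd=ip.noise_sd, pixel_um=pixel,
            seed=stage_seed(root, "iqi"),
        )
        curve = resolution.modulation_curve(img, layout, threshold=cfg["resolution"]["threshold"])
        res_um = resolution.mtf_limit(curve)
        if not np.isfinite(res_um):
            res_um = None
        _tick("resolution", t0, resolution_um=res_um)
        bundle["resolution_um"] = res_um

    # --- segmentation -------------------------------------------------------
    if label is None:
        t0 = time.time()
        seg_cfg = cfg["segmentation"]
        label, seg_prov = segmentation.segment(gray, resolution=res_um, **seg_cfg)
        _tick("segment", t0, **{k: v for k, v in seg_prov.items()})
        if truth_label is not None:
            prov["stages"]["segment"]["dice_vs_truth"] = segmentation.dice(label, truth_label)
        if out is not None:
            write_label_volume(label, out / "labels.tif")
    bundle["label"] = label

    # --- morphometry --------------------------------------------------------
    t0 = time.time()
    graph = network.build_graph(network.skeletonize(label), label)
    stats = network.network_stats(label, graph, **cfg["network"])
    _tick("network", t0, n_nodes=stats.n_nodes, n_edges=stats.n_edges)
    bundle["graph"] = graph
    bundle["stats"] = stats
    if out is not None:
        (out / "network_stats.json").write_text(json.dumps(stats.to_dict(), indent=1))
        (out / "canal_graph.json").write_text(json.dumps(graph.to_dict()))

    # --- micro-FE -----------------------------------------------------------
    if cfg["fe"]["enabled"]:
        t0 = time.time()
        fe_label = label
        crop = cfg["fe"].get("crop")
        if crop:
            fe_label = _crop(label, crop, cfg["fe"].get("crop_anchor", "cortical"))
        spec = _material_spec(cfg)
        fields = None
        constants = {}
        for scen in cfg["fe"]["scenarios"]:
            constants[scen], fields = microfe.homogenize(
                fe_label, spec, scen,
                strain=cfg["fe"]["strain"], tol=cfg["fe"]["tol"],
                downsample=int(cfg["fe"]["downsample"]),
                min_element_um=res_um,
                warm_start=fields, return_fields=True,
            )
        bundle["constants"] = constants
        _tick("microfe", t0, scenarios=list(constants))
        if out is not None:
            (out / "constants.json").write_text(
                json.dumps({s: ec.as_dict() for s, ec in constants.items()}, indent=1)
            )
        if all(s in constants for s in microfe.SCENARIOS):
            from .phase_report import compare_phases

            comparison = compare_phases(
                constants["solid"], constants["liquid"], constants["gas"]
            )
            bundle["comparison"] = comparison
            if out is not None:
                from .io import write_report

                write_report(comparison.to_table(), out / "phase_comparison")

    prov["total_wall_s"] = round(time.time() - t_all, 3)
    bundle["provenance"] = prov
    if out is not None:
        (out / "provenance.json").write_text(json.dumps(prov, indent=1))
    return bundle


def _crop(label: LabelVolume, crop: list[int], anchor: str = "cortical") -> LabelVolume:
    """Extract the FE cuboid.

    ``"center"`` takes the central block; ``"cortical"`` anchors the
    transverse window toward one corner (centered at ~70 % of the
    half-width) so the block samples the canal-bearing wall rather than
    the pore-dominated core, while staying clear of the sparse rim.
    """
    shape = label.shape
    crop = [min(c, s) for c, s in zip(crop, shape)]
    starts = []
    for ax, (s, c) in enumerate(zip(shape, crop)):
        if anchor == "cortical" and ax < 2:
            center = int(0.5 * s + 0.35 * s)  # ~0.7 of the half-width
            start = min(max(center - c // 2, 0), s - c)
        else:
            start = (s - c) // 2
        starts.append(start)
    sl = tuple(slice(st, st + c) for st, c in zip(starts, crop))
    return LabelVolume(label.labels[sl].copy(), label.spacing, label.origin)
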