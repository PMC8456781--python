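"""End-to-end workflows wiring the modules together.

``scene_profiles`` turns a synthetic scene into normalized, binned profiles
exactly the way annotated microscopy would be processed (per-channel
normalization to the brightest cellular structure, tip-first extraction,
40-bin median reduction).  ``run_pipeline`` executes the simulate -> map ->
stats workflow from a validated configuration and writes a manifest, so a
whole run is reproducible from one seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from . import __version__
from ._util import derive_seed
from .errors import ConfigError
from .io_formats import ImageStack, PolylineAnnotation, write_image, write_polylines, write_profiles
from .mapping import (
    POSITIVITY_THRESHOLD,
    BinnedProfile,
    bin_profile,
    build_map,
    per_filopodium_table,
    percent_positive,
)
from .profiles import ProfileRecord, extract_profile, normalize_image
from .flow_stats import randomization_test
from .synthgen import SceneConfig, SyntheticScene, make_scene


def signal_mask(image: np.ndarray) -> np.ndarray:
    """Foreground mask for normalization: pixels above the Otsu threshold."""
    return np.asarray(image, dtype=float) > threshold_otsu(np.asarray(image, dtype=float))


def scene_profiles(
    scene: SyntheticScene,
    channels: list[str] | None = None,
    normalize: bool = True,
) -> list[ProfileRecord]:
    """Extract tip-first profiles for every filopodium and channel."""
    records = []
    for name in channels or scene.channel_names:
        image = scene.images[name]
        if normalize:
            image = normalize_image(image, signal_mask(image))
        for k, poly in enumerate(scene.polylines):
            records.append(
                extract_profile(
                    image, poly, scene.config.pixel_size,
                    filopodium_id=k, channel=name,
                )
            )
    return records


def bin_records(records: list[ProfileRecord]) -> list[BinnedProfile]:
    return [bin_profile(r) for r in records]


_ALLOWED = {
    "seed": None,
    "scene": {
        "image_size", "pixel_size", "n_filopodia", "filopodium_length_range",
        "cell_radius", "poisson_scale", "read_sd",
    },
    "map": {"threshold"},
    "stats": {"n_resamples", "compare_channels"},
}


def _validate(config: dict) -> None:
    unknown = set(config) - set(_ALLOWED)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _ALLOWED.items():
        if allowed is None or section not in config:
            continue
        extra = set(config[section]) - allowed
        if extra:
            raise ConfigError(f"unknown keys in {section!r}: {sorted(extra)}")


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run simulate -> map -> stats and write all artifacts plus a manifest.

    ``config`` may contain ``seed`` (global seed; per-stage seeds are derived
    by stable hashing), a ``scene`` section overriding generator defaults, a
    ``map`` section (positivity ``threshold``) and a ``stats`` section
    (``n_resamples``, ``compare_channels`` pair for the randomization test).
    Unknown keys are rejected, never silently defaulted.
    """
    _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    scene_kwargs = dict(config.get("scene", {}))
    for key in ("image_size", "filopodium_length_range"):
        if key in scene_kwargs:
            scene_kwargs[key] = tuple(scene_kwargs[key])
    scene_cfg = replace(SceneConfig(seed=derive_seed(seed, "scene")), **scene_kwargs)
    scene = make_scene(scene_cfg)

    stack = ImageStack(
        pixels=np.stack([scene.images[c] for c in scene.channel_names]),
        channel_names=scene.channel_names,
        pixel_size=scene_cfg.pixel_size,
    )
    write_image(stack, out / "scene.tif")
    write_polylines(
        [PolylineAnnotation(k, p) for k, p in enumerate(scene.polylines)],
        out / "polylines.csv",
    )
    truth = {
        "lengths_um": scene.lengths_um.tolist(),
        "tip_positive": {c: v.tolist() for c, v in scene.ground_truth_positive.items()},
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))

    records = scene_profiles(scene)
    write_profiles(records, out / "profiles.csv")
    binned = bin_records(records)
    threshold = float(config.get("map", {}).get("threshold", POSITIVITY_THRESHOLD))
    fmap = build_map(binned)
    fmap.table.to_csv(out / "map.csv", index=False)
    per_filo = per_filopodium_table(binned, threshold)
    per_filo.to_csv(out / "per_filopodium.csv", index=False)

    stats_cfg = config.get("stats", {})
    n_res = int(stats_cfg.get("n_resamples", 1000))
    pair = stats_cfg.get("compare_channels", ["active-integrin", "inactive-integrin"])
    summary: dict = {"percent_positive": {}, "threshold": threshold}
    for name in scene.channel_names:
        sub = [b for b in binned if b.channel == name]
        summary["percent_positive"][name] = percent_positive(sub, threshold)
    a = per_filo[(per_filo["channel"] == pair[0]) & per_filo["enrichment"].notna()]["enrichment"]
    b = per_filo[(per_filo["channel"] == pair[1]) & per_filo["enrichment"].notna()]["enrichment"]
    if len(a) >= 2 and len(b) >= 2:
        summary["enrichment_randomization_p"] = randomization_test(
            a, b, n_resamples=n_res, seed=derive_seed(seed, "stats")
        )
        summary["compared_channels"] = list(pair)
    (out / "summary.json").write_text(json.dumps(summary, indent=1))

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "version": __version__,
        "config": config,
        "config_hash": cfg_hash,
        "seed": seed,
        "scene_config": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in asdict(scene_cfg).items() if k != "channel_models"},
        "artifacts": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
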