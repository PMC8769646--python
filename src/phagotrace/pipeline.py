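"""End-to-end pipeline: simulate -> render -> quantify -> events -> coloc.

``run_pipeline`` executes one reproducible run into an output
directory: the rendered OME-TIFF stack, ground-truth and annotation
sidecars, per-phagosome time-course CSV, events CSV, an optional
colocalization JSON (when the scene carries two vesicle reporters), a
time-course figure, the resolved config, and a run log naming the seed
and package version.  With noise disabled a rerun is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .events import engulfment_duration, fusion_onset, phagosome_lifespan
from .io import RunConfig, write_annotation, write_stack
from .photophysics import GFP, MCHERRY
from .puncta import detect_puncta, match_puncta, percent_double_positive
from .quantify import (acidification_index, annotation_from_scene,
                       disc_diameter_timecourse, luminal_relative_intensity,
                       nuclear_diameter_ratio, surface_relative_intensity)
from .render import ChannelSpec, default_channels, render_stack
from .simulate import simulate_scene

__all__ = ["run_pipeline", "build_channels"]

log = logging.getLogger("phagotrace")


def build_channels(config: RunConfig) -> list[ChannelSpec]:
    """Default channels, plus a GFP channel per secondary vesicle reporter."""
    channels = default_channels()
    for rep in config.params.reporters[1:]:
        channels.append(ChannelSpec(f"{rep}_gfp", GFP, "vesicle", reporter=rep))
    return channels


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run one phagosome end to end; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mp = config.measurement

    scene = _stage("simulate")(simulate_scene)(config.params, config.seed)
    channels = build_channels(config)
    stack = _stage("render")(render_stack)(
        scene, channels, config.optics, seed=config.seed + 1_000_003)
    ann = annotation_from_scene(scene, rim_halfwidth=mp.rim_halfwidth)

    write_stack(stack, out / "stack.ome.tif")
    scene.to_json(out / "ground_truth.json")
    write_annotation(ann, out / "annotations.json")
    config.save(out / "config.json")

    # --- time courses ----------------------------------------------
    quant = _stage("quantify")(_quantify)
    tc = quant(stack, ann, mp)
    df = pd.DataFrame(tc)
    df.to_csv(out / "timecourses.csv", index=False, float_format="%.8g")

    # --- events -----------------------------------------------------
    lumen_tc = luminal_relative_intensity(
        stack, stack.channel_index("lgg_mcherry"), ann, mp.lumen_box_side)
    phago_tc = disc_diameter_timecourse(
        stack, stack.channel_index("phago_mcherry"), ann)
    onset = fusion_onset(lumen_tc, mp.fusion_threshold, mp.fusion_persistence)
    lifespan = phagosome_lifespan(phago_tc)
    engulf = engulfment_duration(
        {"bud_time": scene.bud_time, "seal_time": scene.seal_time})
    rows = [
        {"phagosome_id": 0, "kind": "engulfment", "time_min": engulf,
         "censored": False},
        {"phagosome_id": 0, "kind": "lifespan",
         "time_min": "" if lifespan.censored else lifespan.time,
         "censored": lifespan.censored},
        {"phagosome_id": 0, "kind": "fusion_onset",
         "time_min": "" if onset.censored else onset.time,
         "censored": onset.censored},
    ]
    pd.DataFrame(rows).to_csv(out / "events.csv", index=False)

    # --- colocalization (two vesicle reporters only) ----------------
    vesicle_channels = [c for c in channels if c.source == "vesicle"]
    if len(vesicle_channels) >= 2:
        coloc = _stage("coloc")(_colocalize)(stack, scene, vesicle_channels, mp)
        (out / "coloc.json").write_text(json.dumps(coloc, indent=1, sort_keys=True))

    _plot(tc, out / "curves.png")

    (out / "run.json").write_text(json.dumps({
        "package": "phagotrace",
        "version": __version__,
        "seed": config.seed,
        "preset": config.preset,
        "noise_free": config.optics.noise_free,
        "channels": [c.name for c in channels],
    }, indent=1, sort_keys=True))
    log.info("run complete: %s (seed %d)", out, config.seed)
    return out


def _quantify(stack, ann, mp) -> dict:
    lumen = luminal_relative_intensity(
        stack, stack.channel_index("lgg_mcherry"), ann, mp.lumen_box_side)
    surface = surface_relative_intensity(
        stack, stack.channel_index("lgg_mcherry"), ann)
    aidx = acidification_index(
        stack, stack.channel_index("nuc_gfp"), stack.channel_index("nuc_mcherry"),
        ann, mp.aidx_box_side)
    nuc_diam = disc_diameter_timecourse(
        stack, stack.channel_index("nuc_mcherry"), ann)
    nuc_ratio = nuclear_diameter_ratio(
        stack, stack.channel_index("nuc_mcherry"), ann)
    phago_diam = disc_diameter_timecourse(
        stack, stack.channel_index("phago_mcherry"), ann)
    return {
        "time_min": lumen.times,
        "rint_lumen": lumen.values,
        "rint_surface": surface.values,
        "a_idx": aidx.values,
        "diameter_um": nuc_diam.values,
        "diameter_ratio": nuc_ratio.values,
        "phago_diameter_um": phago_diam.values,
    }


def _colocalize(stack, scene, vesicle_channels, mp) -> dict:
    """Per-frame detection + greedy matching on two vesicle channels,
    split by location (phagosome-surface annulus vs cytoplasm)."""
    ci = [stack.channel_index(c.name) for c in vesicle_channels[:2]]
    n_both = n_a = n_b = 0
    n_both_surface = n_a_surface = 0
    for t, frame in enumerate(scene.frames):
        sets = [
            detect_puncta(stack.data[t, c], threshold=mp.detect_threshold,
                          min_separation=mp.match_radius, frame=t,
                          channel=vesicle_channels[k].name)
            for k, c in enumerate(ci)
        ]
        res = match_puncta(sets[0], sets[1], radius=mp.match_radius)
        n_both += res.n_both
        n_a += res.n_A_only
        n_b += res.n_B_only
        cy, cx = frame.phagosome_center
        r = frame.phagosome_radius
        hw = mp.surface_annulus_halfwidth
        for y, x, _peak in sets[0].spots:
            dist = np.hypot(y - cy, x - cx)
            on_surface = (r - hw) <= dist <= (r + hw)
            # classify A spots by whether they sit on the surface annulus
            matched = any(
                np.hypot(y - yb, x - xb) <= mp.match_radius
                for yb, xb, _p in sets[1].spots)
            if on_surface:
                n_a_surface += 1
                if matched:
                    n_both_surface += 1
    total_a = n_a + n_both
    summary = {
        "n_A_only": n_a, "n_B_only": n_b, "n_both": n_both,
        "n_A_total": total_a,
        "n_A_on_surface": n_a_surface,
        "n_both_on_surface": n_both_surface,
    }
    if total_a > 0:
        summary["pct_double_positive_of_A"] = percent_double_positive(n_both, total_a)
    if n_a_surface > 0:
        summary["pct_double_positive_on_surface"] = percent_double_positive(
            n_both_surface, n_a_surface)
    return summary


def _plot(tc: dict, path: Path) -> None:
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    t = tc["time_min"]
    panels = [
        ("rint_lumen", "Luminal relative intensity"),
        ("rint_surface", "Surface relative intensity"),
        ("a_idx", "Acidification index"),
        ("diameter_ratio", "Nuclear diameter ratio"),
    ]
    for ax, (key, label) in zip(axes.ravel(), panels):
        ax.plot(t, tc[key], marker="o", ms=2.5)
        ax.set_ylabel(label)
        ax.set_xlabel("time after sealing (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": "phagotrace"})
    plt.close(fig)
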