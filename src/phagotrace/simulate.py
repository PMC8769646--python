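"""Stochastic simulation of phagosome maturation.

The latent process on the 2-min frame grid:

* vesicle births in the cytosol follow a homogeneous Poisson process
  (``puncta_birth_rate`` per min), positions uniform over the cytosolic
  annulus between the phagosome rim (plus a margin) and the embryo edge;
* each cytosolic punctum docks onto the rim within a frame with
  probability ``1 - exp(-k_recruit * dt)``, each docked punctum fuses
  with probability ``1 - exp(-k_fuse * dt)``; events are resolved in
  birth -> dock -> fuse order within a frame, so a newly born punctum
  may dock (and a newly docked one fuse) in the same interval;
* on fusion of a double-membrane vesicle half the label joins the rim
  pool (outer membrane) and half the lumen pool (inner membrane,
  released into the phagosomal lumen); a single-membrane vesicle
  delivers all label to the rim and none to the lumen;
* luminal pH, phagosome radius and nucleus radius follow the
  deterministic laws in :class:`~phagotrace.kinetics.KineticParams`;
  the shrinkage onset is jittered per scene.

Fused puncta appear with state ``"fused"`` (label already transferred)
on their fusion frame and are dropped from the list afterwards.
``simulate_scene(params, seed)`` is a pure function.
"""

from __future__ import annotations

import math

import numpy as np

from .kinetics import KineticParams
from .scene import FrameTruth, GroundTruthScene, Punctum

__all__ = ["simulate_scene"]


def _assign_reporters(params: KineticParams, rng: np.random.Generator) -> dict[str, float]:
    """Per-reporter label content of a newborn vesicle."""
    labels = {params.reporters[0]: params.label_per_vesicle}
    for rep in params.reporters[1:]:
        if rng.random() < params.secondary_reporter_fraction:
            labels[rep] = params.label_per_vesicle
    return labels


def simulate_scene(params: KineticParams, seed: int) -> GroundTruthScene:
    """Simulate one phagosome's ground-truth scene.

    Identical ``(params, seed)`` yield identical scenes.
    """
    if params.frame_interval <= 0:  # defensive; also enforced by KineticParams
        raise ValueError("frame_interval must be positive")

    master = np.random.SeedSequence(seed)
    kin_ss, jitter_ss = master.spawn(2)
    rng = np.random.default_rng(kin_ss)
    jrng = np.random.default_rng(jitter_ss)

    dt = params.frame_interval
    n_steps = params.n_frames - 1
    p_dock = 1.0 - math.exp(-params.k_recruit * dt)
    p_fuse = 1.0 - math.exp(-params.k_fuse * dt)

    cy, cx = (params.image_shape[0] / 2.0, params.image_shape[1] / 2.0)
    embryo_radius = params.embryo_radius_um / params.pixel_size_um

    if math.isfinite(params.shrink_onset):
        onset = params.shrink_onset + jrng.uniform(
            -params.shrink_onset_jitter, params.shrink_onset_jitter
        )
    else:
        onset = math.inf

    reporters = params.reporters
    rim = {r: 0.0 for r in reporters}
    lumen = {r: 0.0 for r in reporters}
    born = {r: 0.0 for r in reporters}
    puncta: list[Punctum] = []
    frames: list[FrameTruth] = []

    def snapshot(t: float) -> FrameTruth:
        r_t = params.phagosome_radius_px(t, shrink_onset=onset)
        return FrameTruth(
            t_min=t,
            phagosome_center=(cy, cx),
            phagosome_radius=r_t,
            lumen_pH=params.lumen_pH(t),
            rim_label=dict(rim),
            lumen_label=dict(lumen),
            nucleus_radius=params.nucleus_radius_px(t),
            puncta=[Punctum(p.y, p.x, p.state, dict(p.labels), p.angle) for p in puncta],
            cum_born_label=dict(born),
        )

    frames.append(snapshot(0.0))

    for k in range(1, n_steps + 1):
        t = k * dt
        r_t = params.phagosome_radius_px(t, shrink_onset=onset)

        # drop puncta that fused on the previous frame
        puncta = [p for p in puncta if p.state != "fused"]

        # births: uniform over the cytosolic annulus, keeping a margin
        # from the rim so undocked vesicles never overlap the surface ROI
        n_born = rng.poisson(params.puncta_birth_rate * dt)
        r_min = r_t + params.birth_margin_px
        r_max = embryo_radius - 4.0
        for _ in range(n_born):
            rad = math.sqrt(rng.uniform(r_min**2, r_max**2))
            theta = rng.uniform(0.0, 2.0 * math.pi)
            labels = _assign_reporters(params, rng)
            for rep, amount in labels.items():
                born[rep] += amount
            puncta.append(
                Punctum(cy + rad * math.sin(theta), cx + rad * math.cos(theta),
                        "cytosolic", labels)
            )

        # docking
        for p in puncta:
            if p.state == "cytosolic" and rng.random() < p_dock:
                p.state = "docked"
                p.angle = math.atan2(p.y - cy, p.x - cx)

        # fusion
        for p in puncta:
            if p.state == "docked" and rng.random() < p_fuse:
                p.state = "fused"
                for rep, amount in p.labels.items():
                    if params.membrane_topology == "double":
                        rim[rep] += amount / 2.0
                        lumen[rep] += amount / 2.0
                    else:
                        rim[rep] += amount
                p.labels = {rep: 0.0 for rep in p.labels}

        # docked puncta ride the (possibly shrinking) rim
        for p in puncta:
            if p.state in ("docked", "fused") and p.angle is not None:
                p.y = cy + r_t * math.sin(p.angle)
                p.x = cx + r_t * math.cos(p.angle)

        frames.append(snapshot(t))

    return GroundTruthScene(
        frames=frames,
        params=params,
        pixel_size=params.pixel_size_um,
        frame_interval=dt,
        seal_frame_index=0,
        image_shape=params.image_shape,
        embryo_center=(cy, cx),
        embryo_radius=embryo_radius,
        bud_time=-params.engulf_duration,
        seal_time=0.0,
        seed=seed,
    )
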