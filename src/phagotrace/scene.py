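"""Ground-truth latent state of a simulated recording.

A :class:`GroundTruthScene` is the frame-by-frame truth underlying a
rendered stack: phagosome geometry, luminal pH, the per-reporter label
pools on the phagosome rim and in the lumen, the engulfed nucleus, and
every vesicle (punctum) with its position, state and label content.
Scenes serialize losslessly to JSON sidecars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .kinetics import KineticParams

__all__ = ["Punctum", "FrameTruth", "GroundTruthScene"]

PUNCTUM_STATES = ("cytosolic", "docked", "fused")


@dataclass
class Punctum:
    """One vesicle: position (px, y/x), state, and per-reporter label."""

    y: float
    x: float
    state: str
    labels: dict[str, float]
    angle: float | None = None  # rim angle once docked, radians

    def total_label(self) -> float:
        return sum(self.labels.values())


@dataclass
class FrameTruth:
    """Latent state at one frame."""

    t_min: float
    phagosome_center: tuple[float, float]
    phagosome_radius: float            # px
    lumen_pH: float
    rim_label: dict[str, float]        # label units per reporter
    lumen_label: dict[str, float]
    nucleus_radius: float              # px
    puncta: list[Punctum]
    cum_born_label: dict[str, float]   # bookkeeping for conservation checks


@dataclass
class GroundTruthScene:
    """Ordered frame truths plus scene-level metadata."""

    frames: list[FrameTruth]
    params: KineticParams
    pixel_size: float                  # um / px
    frame_interval: float              # min
    seal_frame_index: int = 0
    image_shape: tuple[int, int] = (128, 128)
    embryo_center: tuple[float, float] = (64.0, 64.0)
    embryo_radius: float = 56.0        # px
    bud_time: float = -6.0             # pseudopod budding, min (pre-seal)
    seal_time: float = 0.0
    seed: int | None = None

    @property
    def times(self) -> list[float]:
        return [f.t_min for f in self.frames]

    @property
    def reporters(self) -> tuple[str, ...]:
        return self.params.reporters

    # --- JSON sidecar ------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        """Write the scene (one object per frame) as a JSON sidecar."""
        doc = {
            "pixel_size_um": self.pixel_size,
            "frame_interval_min": self.frame_interval,
            "seal_frame_index": self.seal_frame_index,
            "image_shape": list(self.image_shape),
            "embryo_center": list(self.embryo_center),
            "embryo_radius": self.embryo_radius,
            "bud_time": self.bud_time,
            "seal_time": self.seal_time,
            "seed": self.seed,
            "params": _params_to_dict(self.params),
            "frames": [
                {
                    "t_min": f.t_min,
                    "phagosome_center": list(f.phagosome_center),
                    "phagosome_radius": f.phagosome_radius,
                    "lumen_pH": f.lumen_pH,
                    "rim_label": f.rim_label,
                    "lumen_label": f.lumen_label,
                    "nucleus_radius": f.nucleus_radius,
                    "cum_born_label": f.cum_born_label,
                    "puncta": [
                        {"y": p.y, "x": p.x, "state": p.state,
                         "labels": p.labels, "angle": p.angle}
                        for p in f.puncta
                    ],
                }
                for f in self.frames
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthScene":
        doc = json.loads(Path(path).read_text())
        params = _params_from_dict(doc["params"])
        frames = [
            FrameTruth(
                t_min=f["t_min"],
                phagosome_center=tuple(f["phagosome_center"]),
                phagosome_radius=f["phagosome_radius"],
                lumen_pH=f["lumen_pH"],
                rim_label=dict(f["rim_label"]),
                lumen_label=dict(f["lumen_label"]),
                nucleus_radius=f["nucleus_radius"],
                cum_born_label=dict(f["cum_born_label"]),
                puncta=[Punctum(**p) for p in f["puncta"]],
            )
            for f in doc["frames"]
        ]
        return cls(
            frames=frames,
            params=params,
            pixel_size=doc["pixel_size_um"],
            frame_interval=doc["frame_interval_min"],
            seal_frame_index=doc["seal_frame_index"],
            image_shape=tuple(doc["image_shape"]),
            embryo_center=tuple(doc["embryo_center"]),
            embryo_radius=doc["embryo_radius"],
            bud_time=doc["bud_time"],
            seal_time=doc["seal_time"],
            seed=doc["seed"],
        )


def _params_to_dict(params: KineticParams) -> dict:
    d = asdict(params)
    d["reporters"] = list(params.reporters)
    d["image_shape"] = list(params.image_shape)
    return d


def _params_from_dict(d: dict) -> KineticParams:
    d = dict(d)
    d["reporters"] = tuple(d["reporters"])
    d["image_shape"] = tuple(d["image_shape"])
    return KineticParams(**d)
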