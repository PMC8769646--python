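"""File I/O: OME-TIFF stacks, annotation and scene sidecars, run configs.

Stacks are written as OME-TIFF with TCYX axis order, pixel size (um)
and frame interval (min) in the OME metadata; annotations and ground
truth travel as JSON sidecars; run configurations round-trip through
YAML or JSON.
"""

from __future__ import annotations

import hashlib
import json
import uuid
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .kinetics import KineticParams, preset_genotype
from .quantify import RoiAnnotation
from .render import ImageStack, Optics
from .scene import _params_from_dict, _params_to_dict

__all__ = [
    "read_stack", "write_stack",
    "read_annotation", "write_annotation",
    "MeasurementParams", "RunConfig",
]


# --- OME-TIFF stacks ------------------------------------------------


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF (TCYX) with physical metadata.

    The OME UUID is derived from the array content so that identical
    stacks produce byte-identical files.
    """
    digest = hashlib.sha1(np.ascontiguousarray(stack.data)).hexdigest()
    metadata = {
        "UUID": "urn:uuid:" + str(uuid.uuid5(uuid.NAMESPACE_OID, digest)),
        "axes": "TCYX",
        "PhysicalSizeX": stack.pixel_size,
        "PhysicalSizeXUnit": "um",
        "PhysicalSizeY": stack.pixel_size,
        "PhysicalSizeYUnit": "um",
        "TimeIncrement": stack.frame_interval,
        "TimeIncrementUnit": "min",
        "Channel": {"Name": list(stack.channel_names)},
    }
    tifffile.imwrite(Path(path), stack.data, ome=True, metadata=metadata,
                     photometric="minisblack")


def _ome_pixels_element(xml_text: str) -> tuple[ET.Element, str]:
    root = ET.fromstring(xml_text)
    ns = root.tag.split("}")[0].strip("{") if root.tag.startswith("{") else ""
    pixels = root.find(f".//{{{ns}}}Pixels" if ns else ".//Pixels")
    if pixels is None:
        raise ValueError("OME metadata lacks a Pixels element")
    return pixels, ns


def read_stack(path: str | Path) -> ImageStack:
    """Read an OME-TIFF written by :func:`write_stack` (lossless).

    Raises ``ValueError`` with a remediation hint when the pixel size
    or frame interval metadata is missing.
    """
    with tifffile.TiffFile(Path(path)) as tf:
        if tf.ome_metadata is None:
            raise ValueError(
                f"{path} carries no OME metadata; re-export as OME-TIFF "
                "with PhysicalSizeX and TimeIncrement set")
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        pixels, ns = _ome_pixels_element(tf.ome_metadata)

    if pixels.get("PhysicalSizeX") is None:
        raise ValueError(
            f"{path} lacks PhysicalSizeX (pixel size); set it in the OME "
            "metadata, e.g. via tifffile metadata={'PhysicalSizeX': ...}")
    if pixels.get("TimeIncrement") is None:
        raise ValueError(
            f"{path} lacks TimeIncrement (frame interval); set it in the "
            "OME metadata, e.g. metadata={'TimeIncrement': ...}")
    pixel_size = float(pixels.get("PhysicalSizeX"))
    frame_interval = float(pixels.get("TimeIncrement"))
    tag = f"{{{ns}}}Channel" if ns else "Channel"
    names = [c.get("Name") or f"ch{i}" for i, c in enumerate(pixels.iter(tag))]

    # normalise axis order to TCYX
    for missing in set("TC") - set(axes):
        data = data[np.newaxis]
        axes = missing + axes
    order = [axes.index(a) for a in "TCYX"]
    data = np.transpose(data, order)
    if not names:
        names = [f"ch{i}" for i in range(data.shape[1])]
    return ImageStack(data=data, channel_names=names,
                      pixel_size=pixel_size, frame_interval=frame_interval)


# --- annotations ----------------------------------------------------


def write_annotation(ann: RoiAnnotation, path: str | Path) -> None:
    doc = {
        "center_track": ann.center_track.tolist(),
        "inner_polygons": [p.tolist() for p in ann.inner_polygons],
        "outer_polygons": [p.tolist() for p in ann.outer_polygons],
        "background_box": list(ann.background_box),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_annotation(path: str | Path) -> RoiAnnotation:
    doc = json.loads(Path(path).read_text())
    return RoiAnnotation(
        center_track=np.array(doc["center_track"], dtype=float),
        inner_polygons=[np.array(p, dtype=float) for p in doc["inner_polygons"]],
        outer_polygons=[np.array(p, dtype=float) for p in doc["outer_polygons"]],
        background_box=tuple(doc["background_box"]),
    )


# --- run configuration ----------------------------------------------


@dataclass(frozen=True)
class MeasurementParams:
    """Measurement knobs shared by the pipeline stages."""

    lumen_box_side: int = 4
    aidx_box_side: int = 3
    fusion_threshold: float = 1.5
    fusion_persistence: int = 2
    match_radius: float = 3.0
    rim_halfwidth: float = 3.0
    surface_annulus_halfwidth: float = 4.0
    detect_threshold: float = 100.0

    def __post_init__(self) -> None:
        if self.lumen_box_side < 1 or self.aidx_box_side < 1:
            raise ValueError("box sides must be >= 1")
        if self.fusion_threshold <= 0 or self.fusion_persistence < 1:
            raise ValueError("invalid fusion onset parameters")
        if min(self.match_radius, self.rim_halfwidth, self.detect_threshold) <= 0:
            raise ValueError("radii and thresholds must be positive")


@dataclass
class RunConfig:
    """A fully serializable end-to-end run specification."""

    params: KineticParams = field(default_factory=KineticParams)
    optics: Optics = field(default_factory=Optics)
    measurement: MeasurementParams = field(default_factory=MeasurementParams)
    seed: int = 0
    preset: str | None = None

    @classmethod
    def from_preset(cls, name: str, seed: int = 0, **overrides) -> "RunConfig":
        return cls(params=preset_genotype(name), seed=seed, preset=name, **overrides)

    def to_dict(self) -> dict:
        return {
            "preset": self.preset,
            "seed": self.seed,
            "params": _params_to_dict(self.params),
            "optics": asdict(self.optics),
            "measurement": asdict(self.measurement),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            params=_params_from_dict(d["params"]),
            optics=Optics(**d["optics"]),
            measurement=MeasurementParams(**d["measurement"]),
            seed=int(d["seed"]),
            preset=d.get("preset"),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(doc, sort_keys=True))
        else:
            path.write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        doc = (yaml.safe_load(text) if path.suffix in (".yaml", ".yml")
               else json.loads(text))
        return cls.from_dict(doc)
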