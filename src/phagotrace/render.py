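"""Render ground-truth scenes into noisy multi-channel image stacks.

Each channel images one structure through one fluorophore:

* ``vesicle`` channels see a reporter carried by the vesicles (puncta as
  Gaussian spots at cytosolic pH, the rim pool as an annulus at
  cytosolic pH, the lumen pool spread uniformly over the phagosome disc
  at luminal pH) plus a uniform out-of-plane haze of diffuse cytosolic
  reporter over the embryo disc;
* ``nucleus`` channels see the engulfed apoptotic nucleus as a uniform
  disc at luminal pH (chromatin-bound reporter, no haze);
* ``phagosome`` channels see the phagosome extent as a uniform disc of
  fixed label density at luminal pH (used for diameter tracking).

Every label unit contributes ``brightness * emission_fraction(pKa, pH)``
expected photons, spread by an isotropic Gaussian PSF.  Expected images
are corrupted by Poisson shot noise, then Gaussian read noise, then a
constant background offset.  Noise-free renders are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .photophysics import GFP, MCHERRY, FluorophoreModel
from .scene import GroundTruthScene

__all__ = ["Optics", "ChannelSpec", "ImageStack", "render_stack", "default_channels"]

_TRUNCATE = 6.0  # PSF kernel cut-off in sigmas; keeps mass loss < 1e-8


@dataclass(frozen=True)
class Optics:
    """Imaging parameters shared by all channels."""

    psf_sigma: float = 1.5        # px
    background: float = 10.0      # offset counts per pixel
    shot_noise: bool = True
    read_noise: float = 3.0       # Gaussian sd, counts
    haze_density: float = 0.1     # diffuse label units / px^2 (vesicle channels)

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.read_noise < 0 or self.haze_density < 0 or self.background < 0:
            raise ValueError("background, read_noise, haze_density must be >= 0")

    @property
    def noise_free(self) -> bool:
        return not self.shot_noise and self.read_noise == 0.0


@dataclass(frozen=True)
class ChannelSpec:
    """What one channel images and through which fluorophore."""

    name: str
    fluorophore: FluorophoreModel
    source: str                    # "vesicle" | "nucleus" | "phagosome"
    reporter: str | None = None    # vesicle channels: which reporter
    label_density: float = 1.0     # label units / px^2 (disc sources)

    def __post_init__(self) -> None:
        if self.source not in ("vesicle", "nucleus", "phagosome"):
            raise ValueError(f"unknown channel source {self.source!r}")
        if self.source == "vesicle" and self.reporter is None:
            raise ValueError("vesicle channel requires a reporter name")


def default_channels() -> list[ChannelSpec]:
    """The default four-channel configuration.

    mCherry::LGG on vesicles (fusion readout), GFP+mCherry tandem on the
    engulfed nucleus (acidification and nuclear-diameter readouts), and
    an acid-resistant luminal phagosome marker (diameter/lifespan).
    """
    return [
        ChannelSpec("lgg_mcherry", MCHERRY, "vesicle", reporter="lgg"),
        ChannelSpec("nuc_gfp", GFP, "nucleus", label_density=2.0),
        ChannelSpec("nuc_mcherry", MCHERRY, "nucleus", label_density=2.0),
        ChannelSpec("phago_mcherry", MCHERRY, "phagosome", label_density=1.0),
    ]


@dataclass
class ImageStack:
    """A T x C x Y x X intensity array with physical metadata."""

    data: np.ndarray
    channel_names: list[str]
    pixel_size: float       # um / px
    frame_interval: float   # min

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be T x C x Y x X")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length must match axis 1")
        if np.any(self.data < 0):
            raise ValueError("negative intensities")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.frame_interval


def _gaussian_spot(shape: tuple[int, int], y: float, x: float, sigma: float) -> np.ndarray:
    """Unit-mass Gaussian at a sub-pixel position, evaluated on a window."""
    h, w = shape
    rad = int(math.ceil(_TRUNCATE * sigma))
    y0, y1 = int(math.floor(y)) - rad, int(math.floor(y)) + rad + 1
    x0, x1 = int(math.floor(x)) - rad, int(math.floor(x)) + rad + 1
    yy = np.arange(y0, y1, dtype=float)
    xx = np.arange(x0, x1, dtype=float)
    patch = np.exp(-((yy - y)[:, None] ** 2 + (xx - x)[None, :] ** 2) / (2.0 * sigma**2))
    patch /= patch.sum()  # mass on the (unclipped) window is exactly 1
    out = np.zeros(shape)
    sy0, sy1 = max(y0, 0), min(y1, h)
    sx0, sx1 = max(x0, 0), min(x1, w)
    if sy0 < sy1 and sx0 < sx1:
        out[sy0:sy1, sx0:sx1] = patch[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0]
    return out


def render_stack(
    scene: GroundTruthScene,
    channels: list[ChannelSpec] | None = None,
    optics: Optics | None = None,
    seed: int = 0,
) -> ImageStack:
    """Render a scene into a T x C x Y x X stack.

    Raises ``ValueError`` when a vesicle channel references a reporter
    the scene does not carry.
    """
    channels = default_channels() if channels is None else channels
    optics = Optics() if optics is None else optics
    if not channels:
        raise ValueError("at least one channel required")
    for ch in channels:
        if ch.source == "vesicle" and ch.reporter not in scene.reporters:
            raise ValueError(
                f"channel {ch.name!r} images reporter {ch.reporter!r} "
                f"but the scene carries {scene.reporters}"
            )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shape = tuple(scene.image_shape)
    yy, xx = np.indices(shape, dtype=float)
    cy, cx = scene.embryo_center
    embryo_mask = ((yy - cy) ** 2 + (xx - cx) ** 2) <= scene.embryo_radius**2
    cytosol_pH = scene.params.cytosol_pH

    n_t = len(scene.frames)
    data = np.empty((n_t, len(channels)) + shape)

    for ti, frame in enumerate(scene.frames):
        py, px = frame.phagosome_center
        dist2 = (yy - py) ** 2 + (xx - px) ** 2
        for ci, ch in enumerate(channels):
            b = ch.fluorophore.brightness
            em_cyt = ch.fluorophore.emission(cytosol_pH)
            em_lum = ch.fluorophore.emission(frame.lumen_pH)
            expected = np.zeros(shape)

            if ch.source == "vesicle":
                rep = ch.reporter
                # out-of-plane haze: uniform, un-quenched, not PSF-blurred
                expected += b * em_cyt * optics.haze_density * embryo_mask
                r = frame.phagosome_radius
                rim_amount = frame.rim_label.get(rep, 0.0)
                if rim_amount > 0:
                    ring = (dist2 >= (max(r - 1.5, 0.0)) ** 2) & (dist2 <= (r + 1.5) ** 2)
                    n_px = int(ring.sum())
                    if n_px:
                        expected += b * em_cyt * gaussian_filter(
                            ring * (rim_amount / n_px), optics.psf_sigma,
                            mode="constant", truncate=_TRUNCATE)
                lum_amount = frame.lumen_label.get(rep, 0.0)
                if lum_amount > 0:
                    disc = dist2 <= r**2
                    n_px = int(disc.sum())
                    if n_px:
                        expected += b * em_lum * gaussian_filter(
                            disc * (lum_amount / n_px), optics.psf_sigma,
                            mode="constant", truncate=_TRUNCATE)
                for p in frame.puncta:
                    amount = p.labels.get(rep, 0.0)
                    if amount > 0:
                        expected += b * em_cyt * amount * _gaussian_spot(
                            shape, p.y, p.x, optics.psf_sigma)
            else:
                radius = (frame.nucleus_radius if ch.source == "nucleus"
                          else frame.phagosome_radius)
                disc = dist2 <= radius**2
                expected += b * em_lum * gaussian_filter(
                    disc * ch.label_density, optics.psf_sigma,
                    mode="constant", truncate=_TRUNCATE)

            img = expected
            if optics.shot_noise:
                img = rng.poisson(img).astype(float)
            if optics.read_noise > 0:
                img = img + rng.normal(0.0, optics.read_noise, shape)
            img = img + optics.background
            data[ti, ci] = np.maximum(img, 0.0)

    return ImageStack(
        data=data,
        channel_names=[ch.name for ch in channels],
        pixel_size=scene.pixel_size,
        frame_interval=scene.frame_interval,
    )
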