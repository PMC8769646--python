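"""Shared fixtures: noise-free optics, a wild-type scene/stack, helpers."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from phagotrace import (annotation_from_scene, preset_genotype, render_stack,
                        simulate_scene)
from phagotrace.render import ChannelSpec, Optics, default_channels
from phagotrace.scene import FrameTruth, GroundTruthScene, Punctum


@pytest.fixture(scope="session")
def noise_free():
    return Optics(shot_noise=False, read_noise=0.0)


@pytest.fixture(scope="session")
def lgg_channel():
    return [default_channels()[0]]


@pytest.fixture(scope="session")
def nucleus_channels():
    return default_channels()[1:3]


@pytest.fixture(scope="session")
def wt_scene():
    return simulate_scene(preset_genotype("wild_type"), seed=1)


@pytest.fixture(scope="session")
def wt_stack(wt_scene, noise_free):
    return render_stack(wt_scene, optics=noise_free, seed=2)


@pytest.fixture(scope="session")
def wt_annotation(wt_scene):
    return annotation_from_scene(wt_scene)


def make_spot_scene(positions, label=300.0, reporter="lgg", shape=(128, 128)):
    """A single-frame scene containing only cytosolic puncta at
    ``positions`` — for detection/rendering tests."""
    params = replace(preset_genotype("atg7_like"), observation_span=2.0,
                     image_shape=shape)
    puncta = [Punctum(y, x, "cytosolic", {reporter: label}) for y, x in positions]
    frame = FrameTruth(
        t_min=0.0,
        phagosome_center=(shape[0] / 2.0, shape[1] / 2.0),
        phagosome_radius=params.phagosome_radius_um / params.pixel_size_um,
        lumen_pH=params.pH_initial,
        rim_label={reporter: 0.0},
        lumen_label={reporter: 0.0},
        nucleus_radius=params.nucleus_radius_um / params.pixel_size_um,
        puncta=puncta,
        cum_born_label={reporter: label * len(puncta)},
    )
    return GroundTruthScene(
        frames=[frame], params=params, pixel_size=params.pixel_size_um,
        frame_interval=params.frame_interval, image_shape=shape,
        embryo_center=(shape[0] / 2.0, shape[1] / 2.0),
        embryo_radius=params.embryo_radius_um / params.pixel_size_um,
    )
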