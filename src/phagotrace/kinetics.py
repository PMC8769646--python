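"""Kinetic parameters of a simulated phagosome maturation scenario.

A scenario bundles the stochastic vesicle kinetics (birth of LC3/LGG-
labelled vesicles in the cytosol, docking onto the phagosome surface,
fusion), the membrane topology that decides whether fusion delivers
label into the lumen, the luminal pH trajectory, and the deterministic
geometry programme (phagosome shrinkage during degradation, shrinkage of
the engulfed apoptotic nucleus).

Genotype presets encode the qualitative phenotypes of the classical
engulfment/autophagy mutants as parameter changes: recruitment-defective
(``ced1_like``), fusion-defective (``rab7_like``), autophagosome-
biogenesis-defective (``atg7_like``), acidification-defective
(``cup5_like``), and a single-membrane (LAP-like) control whose fusion
leaves label on the phagosome membrane only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = ["KineticParams", "preset_genotype", "GENOTYPES"]


@dataclass(frozen=True)
class KineticParams:
    """Rates, switches and geometry for one simulated phagosome.

    Times are minutes, rates per minute, label in arbitrary label units,
    lengths in pixels unless suffixed ``_um``.
    """

    # vesicle kinetics
    puncta_birth_rate: float = 0.25      # cytosolic births / min
    k_recruit: float = 0.12              # per-punctum docking rate / min
    k_fuse: float = 0.05                 # per-docked-punctum fusion rate / min
    membrane_topology: str = "double"    # "double" or "single"
    label_per_vesicle: float = 300.0     # total label units per vesicle
    # reporters carried by vesicles; the first is carried by every
    # punctum, later ones by a fraction `secondary_reporter_fraction`
    reporters: tuple[str, ...] = ("lgg",)
    secondary_reporter_fraction: float = 1.0

    # luminal pH programme: exponential approach pH_initial -> pH_final
    pH_initial: float = 7.2
    pH_final: float = 5.0
    pH_tau: float = 20.0                 # min

    # degradation geometry
    shrink_onset: float = 24.0           # min; inf disables shrinkage
    shrink_halftime: float = 25.0        # min for radius to halve
    shrink_onset_jitter: float = 7.0     # +- uniform jitter on onset, min
    nucleus_decay_halftime: float = 60.0  # min; inf disables nuclear decay

    # engulfment (pseudopod budding to sealing), recorded as metadata
    engulf_duration: float = 6.0         # min

    # observation grid
    observation_span: float = 100.0      # min
    frame_interval: float = 2.0          # min

    # scene geometry
    pixel_size_um: float = 0.1
    image_shape: tuple[int, int] = (128, 128)
    phagosome_radius_um: float = 2.0
    nucleus_radius_um: float = 1.0
    embryo_radius_um: float = 5.6
    birth_margin_px: float = 10.0        # cytosolic births keep this distance
                                         # from the phagosome rim
    cytosol_pH: float = 7.2

    def __post_init__(self) -> None:
        for name in ("puncta_birth_rate", "k_recruit", "k_fuse"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.membrane_topology not in ("single", "double"):
            raise ValueError(f"unknown membrane_topology {self.membrane_topology!r}")
        if self.label_per_vesicle < 0:
            raise ValueError("label_per_vesicle must be >= 0")
        if not self.reporters:
            raise ValueError("at least one reporter required")
        if not (0.0 <= self.secondary_reporter_fraction <= 1.0):
            raise ValueError("secondary_reporter_fraction must be in [0, 1]")
        if self.pH_final > self.pH_initial:
            raise ValueError("pH_final must be <= pH_initial")
        if self.pH_tau <= 0:
            raise ValueError("pH_tau must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.observation_span < self.frame_interval:
            raise ValueError("observation_span shorter than one frame")
        if self.engulf_duration < 0:
            raise ValueError("engulf_duration must be >= 0")
        if self.shrink_halftime <= 0 or self.nucleus_decay_halftime <= 0:
            raise ValueError("halftimes must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    # --- deterministic component laws -------------------------------

    def lumen_pH(self, t: float) -> float:
        """Luminal pH at ``t`` minutes after sealing."""
        if t <= 0:
            return self.pH_initial
        return self.pH_final + (self.pH_initial - self.pH_final) * math.exp(-t / self.pH_tau)

    def phagosome_radius_px(self, t: float, shrink_onset: float | None = None) -> float:
        """Phagosome radius in px; halves every ``shrink_halftime`` after onset."""
        r0 = self.phagosome_radius_um / self.pixel_size_um
        onset = self.shrink_onset if shrink_onset is None else shrink_onset
        if not math.isfinite(onset) or t <= onset:
            return r0
        return r0 * 2.0 ** (-(t - onset) / self.shrink_halftime)

    def nucleus_radius_px(self, t: float) -> float:
        r0 = self.nucleus_radius_um / self.pixel_size_um
        if not math.isfinite(self.nucleus_decay_halftime) or t <= 0:
            return r0
        return r0 * 2.0 ** (-t / self.nucleus_decay_halftime)

    @property
    def n_frames(self) -> int:
        return int(round(self.observation_span / self.frame_interval)) + 1


def _wild_type() -> KineticParams:
    return KineticParams()


# Phenotypes are encoded relative to wild type.  Degradation-defective
# genotypes (fusion- or acidification-blocked) neither shrink the
# phagosome nor digest the nucleus within the recording.
GENOTYPES = {
    "wild_type": _wild_type(),
    "ced1_like": replace(_wild_type(), k_recruit=0.0, shrink_onset=math.inf,
                         nucleus_decay_halftime=math.inf),
    "rab7_like": replace(_wild_type(), k_fuse=0.0, shrink_onset=math.inf,
                         nucleus_decay_halftime=math.inf),
    "atg7_like": replace(_wild_type(), puncta_birth_rate=0.0, pH_final=6.0,
                         nucleus_decay_halftime=100.0, shrink_onset=math.inf),
    "cup5_like": replace(_wild_type(), pH_final=7.2, shrink_onset=math.inf,
                         nucleus_decay_halftime=math.inf),
    "single_membrane_control": replace(_wild_type(), membrane_topology="single"),
}


def preset_genotype(name: str) -> KineticParams:
    """Return the kinetic parameter preset for a genotype.

    Known names: ``wild_type``, ``ced1_like``, ``rab7_like``,
    ``atg7_like``, ``cup5_like``, ``single_membrane_control``.
    """
    try:
        return GENOTYPES[name]
    except KeyError:
        raise ValueError(
            f"unknown genotype preset {name!r}; choose from {sorted(GENOTYPES)}"
        ) from None
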