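"""pH-dependent fluorophore emission.

Low-pKa fluorophores (mCherry, mNeonGreen) keep emitting inside an
acidifying phagosome lumen, while GFP (pKa ~6) is quenched.  Emission is
modelled as a single-site protonation equilibrium: the fraction of the
fluorophore population that is deprotonated (and hence fluorescent) at a
given pH follows a Henderson-Hasselbalch titration curve, optionally with
a pH-independent residual floor.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FluorophoreModel", "emission_fraction", "GFP", "MCHERRY", "MNEONGREEN"]


def emission_fraction(pKa: float, pH: float, floor: float = 0.0) -> float:
    """Fluorescent fraction at ``pH`` for a fluorophore with given ``pKa``.

    ``f = floor + (1 - floor) / (1 + 10**(pKa - pH))``

    Monotonically increasing in pH; tends to ``floor`` in strong acid and
    to 1 at high pH.  ``f(pKa) = (1 + floor) / 2``.
    """
    return floor + (1.0 - floor) / (1.0 + 10.0 ** (pKa - pH))


@dataclass(frozen=True)
class FluorophoreModel:
    """A fluorescent protein's photophysical parameters.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"GFP"``.
    pKa:
        pH of half-maximal quenching, in [3, 9].
    brightness:
        Expected photons emitted per label unit per frame at full
        (deprotonated) emission.
    floor:
        Residual emission fraction at pH far below pKa, in [0, 1).
    """

    name: str
    pKa: float
    brightness: float = 200.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if not (3.0 <= self.pKa <= 9.0):
            raise ValueError(f"pKa must be in [3, 9], got {self.pKa}")
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")
        if not (0.0 <= self.floor < 1.0):
            raise ValueError("floor must be in [0, 1)")

    def emission(self, pH: float) -> float:
        """Fluorescent fraction at ``pH``."""
        return emission_fraction(self.pKa, pH, self.floor)


# Standard reporters.  mCherry's pKa is only bounded above (<4.5) in the
# literature; 4.5 is adopted as the conservative worst case.
GFP = FluorophoreModel("GFP", pKa=6.0)
MCHERRY = FluorophoreModel("mCherry", pKa=4.5)
MNEONGREEN = FluorophoreModel("mNeonGreen", pKa=5.1)
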