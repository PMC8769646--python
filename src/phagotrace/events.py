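"""Event-time statistics derived from per-phagosome time courses.

* engulfment duration — pseudopod budding to sealing;
* phagosome lifespan — sealing until the phagosome diameter first
  drops to half its T0 value (degradation-rate proxy), right-censored
  at the end of the recording;
* fusion onset — first sustained entry of vesicle label into the lumen
  (luminal RInt above a threshold for a number of consecutive frames),
  censored as "no fusion" when never sustained;
* censored histograms over user bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .quantify import TimeCourse

__all__ = [
    "EventResult",
    "engulfment_duration",
    "phagosome_lifespan",
    "fusion_onset",
    "summarize_event_distribution",
]

EVENT_KINDS = ("engulfment", "lifespan", "fusion_onset")


@dataclass(frozen=True)
class EventResult:
    """An event time in minutes, or a right-censoring record."""

    kind: str
    time: float | None          # None when censored
    censored: bool
    censor_horizon: float       # min; the last observed time

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.censored and self.time is not None:
            raise ValueError("censored results carry no event time")
        if not self.censored and (self.time is None or self.time < 0):
            raise ValueError("uncensored results need a non-negative time")


def engulfment_duration(pseudopod_events: dict) -> float:
    """Minutes between pseudopod budding and sealing."""
    bud = pseudopod_events["bud_time"]
    seal = pseudopod_events["seal_time"]
    if seal < bud:
        raise ValueError(f"seal_time {seal} precedes bud_time {bud}")
    return float(seal - bud)


def phagosome_lifespan(diameters: TimeCourse) -> EventResult:
    """First time the diameter is at or below half its T0 value.

    ``nan`` frames (disc not found) are skipped; censored at the last
    frame when the half-diameter is never reached.
    """
    if not len(diameters):
        raise ValueError("empty diameter series")
    d0 = diameters.values[0]
    if not math.isfinite(d0) or d0 <= 0:
        raise ValueError("diameter at T0 must be positive")
    horizon = float(diameters.times[-1])
    for t, d in zip(diameters.times, diameters.values):
        if math.isfinite(d) and d <= 0.5 * d0:
            return EventResult("lifespan", float(t), False, horizon)
    return EventResult("lifespan", None, True, horizon)


def fusion_onset(
    lumen: TimeCourse,
    threshold: float = 1.5,
    persistence: int = 2,
) -> EventResult:
    """First time luminal RInt stays >= ``threshold`` for ``persistence``
    consecutive frames; censored ("no fusion") otherwise."""
    if not len(lumen):
        raise ValueError("empty luminal series")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    v = lumen.values
    horizon = float(lumen.times[-1])
    above = v >= threshold
    for i in range(len(v) - persistence + 1):
        if above[i:i + persistence].all():
            return EventResult("fusion_onset", float(lumen.times[i]), False, horizon)
    return EventResult("fusion_onset", None, True, horizon)


def summarize_event_distribution(
    events: list[EventResult],
    bin_edges,
) -> dict:
    """Histogram fractions over ``bin_edges`` plus a censored fraction.

    Fractions are over all events (censored included) and sum to 1.
    """
    if not events:
        raise ValueError("no events to summarize")
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    times = np.array([e.time for e in events if not e.censored], dtype=float)
    n_total = len(events)
    n_censored = n_total - len(times)
    counts, _ = np.histogram(times, bins=edges)
    return {
        "bin_edges": edges.tolist(),
        "fractions": (counts / n_total).tolist(),
        "censored_fraction": n_censored / n_total,
        "n": n_total,
    }
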