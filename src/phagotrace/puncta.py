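"""Puncta detection and two-channel colocalization counting.

Detection is multi-scale Laplacian-of-Gaussian blob detection with
non-maximum suppression; the threshold applies to the scale-normalised
LoG response of the raw-intensity image, so an empty (haze-only) frame
yields no detections at default settings.

Colocalization is greedy nearest-neighbour matching under a distance
cap, each spot used once.  The matched/unmatched counts feed the two
percentage formulas used for puncta populations: the three-class
distribution (A-only / B-only / both) and the double-positive fraction
of a reference channel (%RAB-7+, % autolysosomes).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import blob_log

__all__ = [
    "PunctaSet",
    "ColocalizationResult",
    "detect_puncta",
    "match_puncta",
    "match_puncta_exhaustive",
    "class_distribution",
    "percent_double_positive",
]


@dataclass
class PunctaSet:
    """Detected or ground-truth spots of one channel at one frame."""

    frame: int
    channel: str
    spots: np.ndarray              # (n, 3): y, x, peak intensity
    detection_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spots = np.asarray(self.spots, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def positions(self) -> np.ndarray:
        return self.spots[:, :2]


@dataclass
class ColocalizationResult:
    """Counts from matching two single-frame puncta sets."""

    n_A_only: int
    n_B_only: int
    n_both: int
    formula_tag: str = "greedy_nearest_neighbor"

    def __post_init__(self) -> None:
        if min(self.n_A_only, self.n_B_only, self.n_both) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_A_only + self.n_B_only + self.n_both


def detect_puncta(
    image: np.ndarray,
    min_sigma: float = 1.0,
    max_sigma: float = 3.0,
    threshold: float = 100.0,
    min_separation: float = 3.0,
    frame: int = 0,
    channel: str = "",
) -> PunctaSet:
    """LoG blob detection on a single 2-D frame.

    ``threshold`` is absolute on the scale-normalised LoG response in
    intensity counts.  Spots closer than ``min_separation`` px are
    suppressed, keeping the brighter one.  Deterministic for a fixed
    input.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    blobs = blob_log(img, min_sigma=min_sigma, max_sigma=max_sigma,
                     num_sigma=5, threshold=threshold)
    spots = []
    for y, x, _sigma in blobs:
        iy = int(min(max(round(y), 0), img.shape[0] - 1))
        ix = int(min(max(round(x), 0), img.shape[1] - 1))
        spots.append((y, x, img[iy, ix]))
    # non-maximum suppression by peak intensity
    spots.sort(key=lambda s: (-s[2], s[0], s[1]))
    kept: list[tuple[float, float, float]] = []
    for s in spots:
        if all(math.hypot(s[0] - k[0], s[1] - k[1]) >= min_separation for k in kept):
            kept.append(s)
    kept.sort(key=lambda s: (s[0], s[1]))
    params = dict(min_sigma=min_sigma, max_sigma=max_sigma,
                  threshold=threshold, min_separation=min_separation)
    return PunctaSet(frame, channel, np.array(kept).reshape(-1, 3), params)


def _pairs_within(A: np.ndarray, B: np.ndarray, radius: float):
    out = []
    for i, (ya, xa) in enumerate(A):
        for j, (yb, xb) in enumerate(B):
            d = math.hypot(ya - yb, xa - xb)
            if d <= radius:
                out.append((d, ya, xa, yb, xb, i, j))
    return out


def match_puncta(
    setA: PunctaSet,
    setB: PunctaSet,
    radius: float = 3.0,
) -> ColocalizationResult:
    """Greedy nearest-neighbour matching under a distance cap.

    Candidate pairs are taken in order of increasing distance (ties
    broken by lower (y, x)); each spot is used at most once.
    """
    if setA.frame != setB.frame:
        raise ValueError(f"frame mismatch: {setA.frame} vs {setB.frame}")
    pairs = sorted(_pairs_within(setA.positions, setB.positions, radius))
    usedA: set[int] = set()
    usedB: set[int] = set()
    n_both = 0
    for _d, _ya, _xa, _yb, _xb, i, j in pairs:
        if i not in usedA and j not in usedB:
            usedA.add(i)
            usedB.add(j)
            n_both += 1
    return ColocalizationResult(
        n_A_only=len(setA) - n_both,
        n_B_only=len(setB) - n_both,
        n_both=n_both,
    )


def match_puncta_exhaustive(
    setA: PunctaSet,
    setB: PunctaSet,
    radius: float = 3.0,
) -> ColocalizationResult:
    """Reference matcher: exhaustive optimal bipartite matching.

    Maximises match cardinality, breaking ties by minimum total
    distance.  Exponential in the smaller set; intended as a validation
    oracle for small instances (<= ~8 spots per channel).
    """
    if setA.frame != setB.frame:
        raise ValueError(f"frame mismatch: {setA.frame} vs {setB.frame}")
    A, B = setA.positions, setB.positions
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(A))}
    for d, _ya, _xa, _yb, _xb, i, j in _pairs_within(A, B, radius):
        adj[i].append((j, d))

    best_card = 0
    best_dist = math.inf

    def recurse(i: int, used: set[int], card: int, dist: float) -> None:
        nonlocal best_card, best_dist
        if i == len(A):
            if card > best_card or (card == best_card and dist < best_dist):
                best_card, best_dist = card, dist
            return
        # bound: remaining A spots can add at most len(A) - i matches
        if card + (len(A) - i) < best_card:
            return
        recurse(i + 1, used, card, dist)
        for j, d in adj[i]:
            if j not in used:
                used.add(j)
                recurse(i + 1, used, card + 1, dist + d)
                used.remove(j)

    recurse(0, set(), 0, 0.0)
    return ColocalizationResult(
        n_A_only=len(A) - best_card,
        n_B_only=len(B) - best_card,
        n_both=best_card,
        formula_tag="exhaustive_optimal",
    )


def class_distribution(result: ColocalizationResult) -> dict[str, float]:
    """Percentages of A-only / B-only / double-labelled puncta."""
    total = result.total
    if total == 0:
        raise ValueError("no puncta to classify")
    return {
        "A_only_pct": 100.0 * result.n_A_only / total,
        "B_only_pct": 100.0 * result.n_B_only / total,
        "both_pct": 100.0 * result.n_both / total,
    }


def percent_double_positive(n_both: int, n_ref_total: int) -> float:
    """``100 * n_both / n_ref_total`` (e.g. %RAB-7+ of mCherry+ puncta,
    or % autolysosomes of the mNG+ population)."""
    if n_ref_total <= 0:
        raise ValueError("reference total must be positive")
    if not (0 <= n_both <= n_ref_total):
        raise ValueError("need 0 <= n_both <= n_ref_total")
    return 100.0 * n_both / n_ref_total
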