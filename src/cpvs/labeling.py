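"""Histogram-based labeling of docking scores.

Continuous docking scores become binary training labels through a 10-bin
equal-width histogram: bins up to ``low_max`` are 'low-scoring' (class 0),
bins from ``high_min`` up are 'high-scoring' (class 1), and the bins in
between are excluded from training entirely. The histogram approach avoids
a global sort; the bin-combination scheme is written ``a_b`` (e.g. ``1_5``).

Convention throughout the package: HIGHER score = better binder. Engines
where lower is better are negated on ingest (``score_higher_is_better``
flag in the screening configuration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigError, DegenerateDataError


@dataclass
class ScoreHistogram:
    """Equal-width histogram: 11 ascending edges, 10 counts, n scores."""

    edges: np.ndarray
    counts: np.ndarray
    n: int

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def bin_of(self, score: float, clamp: bool = True) -> int:
        """1-based bin index for a score.

        A score equal to an interior edge belongs to the higher bin; the
        last bin is right-closed. Out-of-range scores are clamped to the
        first/last bin with a warning when ``clamp`` is true.
        """
        if score < self.edges[0] or score > self.edges[-1]:
            if not clamp:
                raise ValueError(f"score {score} outside histogram range")
            warnings.warn(f"score {score} outside histogram range; clamped",
                          stacklevel=2)
            return 1 if score < self.edges[0] else self.n_bins
        # interior edges only: value == edge lands in the higher bin
        return int(np.digitize(score, self.edges[1:-1], right=False)) + 1


@dataclass(frozen=True)
class BinScheme:
    """Bin combination ``low_max_high_min``: bins <= low_max are class 0,
    bins >= high_min are class 1, bins in between are excluded."""

    low_max: int
    high_min: int

    def __post_init__(self) -> None:
        if not (1 <= self.low_max < self.high_min <= 10):
            raise ConfigError(
                f"invalid bin scheme {self.low_max}_{self.high_min}: "
                "need 1 <= low_max < high_min <= 10")

    @classmethod
    def parse(cls, text: str) -> "BinScheme":
        try:
            low, high = text.split("_")
            return cls(int(low), int(high))
        except (ValueError, AttributeError) as exc:
            raise ConfigError(f"cannot parse bin scheme {text!r}") from exc

    def __str__(self) -> str:
        return f"{self.low_max}_{self.high_min}"


@dataclass
class LabelAssignment:
    """Labels per molecule id; excluded-bin molecules are absent entirely."""

    labels: dict[str, int]
    excluded: list[str]
    n_clamped: int = 0

    def ids_with_label(self, label: int) -> list[str]:
        return [i for i, l in self.labels.items() if l == label]


def histogram_scores(scores, n_bins: int = 10) -> ScoreHistogram:
    """Equal-width histogram spanning [min, max] on the raw score scale."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size < 2 or np.unique(arr).size < 2:
        raise DegenerateDataError(
            "histogram needs at least 2 distinct scores")
    edges = np.linspace(arr.min(), arr.max(), n_bins + 1)
    counts, _ = np.histogram(arr, bins=edges)
    return ScoreHistogram(edges=edges, counts=counts, n=int(arr.size))


def assign_labels(scored: Mapping[str, float],
                  hist: ScoreHistogram,
                  scheme: BinScheme) -> LabelAssignment:
    """Label every scored molecule by its histogram bin under ``scheme``.

    Scores outside the histogram range are clamped into the boundary bins
    (one warning per call). Excluded-bin molecules keep their scores and
    may re-enter labeling in later iterations once bin edges move.
    """
    labels: dict[str, int] = {}
    excluded: list[str] = []
    n_clamped = 0
    lo, hi = hist.edges[0], hist.edges[-1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single summary warning below
        for mol_id, score in scored.items():
            if score < lo or score > hi:
                n_clamped += 1
            b = hist.bin_of(score)
            if b <= scheme.low_max:
                labels[mol_id] = 0
            elif b >= scheme.high_min:
                labels[mol_id] = 1
            else:
                excluded.append(mol_id)
    if n_clamped:
        warnings.warn(f"{n_clamped} scores outside histogram range were "
                      "clamped into boundary bins", stacklevel=2)
    return LabelAssignment(labels=labels, excluded=excluded, n_clamped=n_clamped)
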