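"""Paired-stimulation flow-histogram analysis.

Agonist- and null-stimulated samples are exported as binned intensity
histograms.  The null histogram is subtracted bin-by-bin from the agonist
histogram; bins left with a positive count are treated as responding cells.
Summary statistics (percent responders, mean intensity, SEM) are computed on
the unsmoothed difference; a nearest-neighbour moving average is provided as
a display layer only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BinnedHistogram",
    "DifferenceHistogram",
    "ResponseStats",
    "SmoothingConfig",
    "subtract_background",
    "percent_responders",
    "response_stats",
    "smooth",
    "normalize_to_control",
    "read_histogram_csv",
    "write_histogram_csv",
]


class AlignmentError(ValueError):
    """Histograms cannot be compared (edges or channels differ)."""


@dataclass(frozen=True)
class BinnedHistogram:
    """Per-bin event counts for a single stimulation.

    Parameters
    ----------
    bin_edges : array of shape (n + 1,)
        Strictly increasing bin boundaries on the log10-intensity axis.
    counts : array of shape (n,)
        Non-negative event counts per bin.
    label : str
        Stimulation tag, e.g. ``"null"`` or ``"agonist"``.
    channel : str
        Readout name, e.g. ``"pCD3z"``, ``"pZAP70"``, ``"pPLCg1"``.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    label: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if edges.ndim != 1 or counts.ndim != 1 or edges.size != counts.size + 1:
            raise ValueError("bin_edges must have length len(counts) + 1")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class DifferenceHistogram:
    """Signed per-bin agonist-minus-null differences."""

    bin_edges: np.ndarray
    diffs: np.ndarray
    total_agonist: float
    total_null: float
    channel: str = ""

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class ResponseStats:
    percent_responders: float
    mean_intensity: float  # NaN when positive_mass == 0
    sem_intensity: float
    positive_mass: float


@dataclass(frozen=True)
class SmoothingConfig:
    """Centered moving-average smoother; ``window`` counts neighbouring bins.

    Even windows are widened by one bin so the average is centered. The
    default of 500 bins mirrors a 500-nearest-neighbour smoother on a
    1024-bin export.
    """

    window: int = 500

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")


def subtract_background(
    agonist: BinnedHistogram,
    null: BinnedHistogram,
    *,
    rescale: bool = True,
) -> DifferenceHistogram:
    """Subtract the null histogram from the agonist one, bin by bin.

    When the two samples collected different event totals and ``rescale`` is
    true, the null counts are scaled by ``total_agonist / total_null`` first
    so that the difference sums to zero.
    """
    if agonist.bin_edges.shape != null.bin_edges.shape or not np.allclose(
        agonist.bin_edges, null.bin_edges
    ):
        raise AlignmentError("agonist and null histograms have different bin edges")
    if agonist.channel != null.channel:
        raise AlignmentError(
            f"channel mismatch: {agonist.channel!r} vs {null.channel!r}"
        )
    null_counts = null.counts
    if rescale and null.total > 0 and null.total != agonist.total:
        null_counts = null_counts * (agonist.total / null.total)
    return DifferenceHistogram(
        bin_edges=agonist.bin_edges,
        diffs=agonist.counts - null_counts,
        total_agonist=agonist.total,
        total_null=null.total,
        channel=agonist.channel,
    )


def percent_responders(d: DifferenceHistogram) -> float:
    """Percent of agonist-stimulated cells in bins above the null background.

    Bins with a positive difference are counted as responders:
    ``100 * sum(max(diff, 0)) / total_agonist``.
    """
    if d.total_agonist <= 0:
        raise ValueError("percent_responders undefined for zero agonist events")
    positive = np.clip(d.diffs, 0.0, None).sum()
    return float(100.0 * positive / d.total_agonist)


def response_stats(d: DifferenceHistogram) -> ResponseStats:
    """Mean intensity and SEM of the background-subtracted response.

    Only bins with positive differences contribute; the positive mass acts as
    the effective n for the SEM.  With no positive mass the mean and SEM are
    reported as NaN and percent_responders as 0.
    """
    weights = np.clip(d.diffs, 0.0, None)
    mass = float(weights.sum())
    if mass == 0.0:
        return ResponseStats(0.0, float("nan"), float("nan"), 0.0)
    centers = d.bin_centers
    mean = float((weights * centers).sum() / mass)
    var = float((weights * (centers - mean) ** 2).sum() / mass)
    sem = float(np.sqrt(var / mass))
    return ResponseStats(
        percent_responders=percent_responders(d),
        mean_intensity=mean,
        sem_intensity=sem,
        positive_mass=mass,
    )


def smooth(d: DifferenceHistogram, cfg: SmoothingConfig = SmoothingConfig()) -> DifferenceHistogram:
    """Centered moving average over ``cfg.window`` bins, truncated at edges.

    Display layer only — statistics must be computed on the unsmoothed
    difference.
    """
    half = cfg.window // 2
    diffs = d.diffs
    n = diffs.size
    out = np.empty_like(diffs, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(diffs)])
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return DifferenceHistogram(
        bin_edges=d.bin_edges,
        diffs=out,
        total_agonist=d.total_agonist,
        total_null=d.total_null,
        channel=d.channel,
    )


def normalize_to_control(mutant: ResponseStats, control: ResponseStats) -> float:
    """Ratio of mutant to paired-control mean intensity (x100 in tables)."""
    if not control.mean_intensity > 0:
        raise ValueError("control mean intensity must be positive")
    return mutant.mean_intensity / control.mean_intensity


# ---------------------------------------------------------------------------
# CSV I/O (bin_lo, bin_hi, count)


def read_histogram_csv(path: str | Path, *, label: str = "", channel: str = "") -> BinnedHistogram:
    df = pd.read_csv(path)
    for col in ("bin_lo", "bin_hi", "count"):
        if col not in df.columns:
            raise ValueError(f"histogram CSV missing column {col!r}")
    edges = np.concatenate([df["bin_lo"].to_numpy(float), [float(df["bin_hi"].iloc[-1])]])
    return BinnedHistogram(edges, df["count"].to_numpy(float), label=label, channel=channel)


def write_histogram_csv(hist: BinnedHistogram, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_lo": hist.bin_edges[:-1],
            "bin_hi": hist.bin_edges[1:],
            "count": hist.counts,
        }
    ).to_csv(path, index=False)
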