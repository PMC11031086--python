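"""Sucrose-gradient bead-capture (FFLISA) normalization and AUC analysis.

A run yields geometric-mean fluorescence (gMFI) for ten gradient fractions in
three channels (CD4, LCK, CTxB).  Fraction 1 is pure background and is
subtracted from every fraction; CD4 is expressed as percent of its own total;
companion channels are normalized to CD4 per fraction; area under the curve
over fractions 1-6 summarizes the detergent-resistant (DRM) compartment and
over fractions 6-10 the detergent-soluble (DSM) compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHANNELS = ("CD4", "LCK", "CTxB")
N_FRACTIONS = 10
DRM_FRACTIONS = (1, 6)
DSM_FRACTIONS = (6, 10)

__all__ = [
    "GradientProfile",
    "AucResult",
    "subtract_fraction1",
    "cd4_percent_of_total",
    "normalize_channel_to_cd4",
    "auc_drm_dsm",
    "read_gradient_csv",
    "write_gradient_csv",
]


@dataclass(frozen=True)
class GradientProfile:
    """Ten-fraction per-channel gMFI table.

    ``raw`` is indexed by fraction 1..10 with columns CD4/LCK/CTxB.
    ``subtracted`` holds the fraction-1-background-subtracted layer once
    :func:`subtract_fraction1` has run.
    """

    raw: pd.DataFrame
    subtracted: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        raw = self.raw.copy()
        missing = [c for c in CHANNELS if c not in raw.columns]
        if missing:
            raise ValueError(f"gradient profile missing channels {missing}")
        raw = raw[list(CHANNELS)].astype(float)
        if list(raw.index) != list(range(1, N_FRACTIONS + 1)):
            raise ValueError("gradient profile must have fractions 1..10 as its index")
        if (raw.to_numpy() < 0).any():
            raise ValueError("raw gMFI must be non-negative")
        object.__setattr__(self, "raw", raw)

    def require_subtracted(self) -> pd.DataFrame:
        if self.subtracted is None:
            raise ValueError("background subtraction has not been applied")
        return self.subtracted


@dataclass(frozen=True)
class AucResult:
    drm_auc: float
    dsm_auc: float
    total_auc: float


def subtract_fraction1(p: GradientProfile) -> GradientProfile:
    """Subtract the fraction-1 gMFI from every fraction, per channel.

    Fraction 1 becomes exactly 0; negative results are floored at 0 (a
    negative gMFI is nonphysical).
    """
    sub = p.raw - p.raw.loc[1]
    sub = sub.clip(lower=0.0)
    return GradientProfile(raw=p.raw, subtracted=sub)


def cd4_percent_of_total(p: GradientProfile) -> pd.Series:
    """CD4 signal per fraction as percent of the summed CD4 signal."""
    cd4 = p.require_subtracted()["CD4"]
    total = cd4.sum()
    if total <= 0:
        raise ValueError("total CD4 gMFI is zero; cannot normalize")
    return 100.0 * cd4 / total


def normalize_channel_to_cd4(p: GradientProfile, channel: str) -> pd.Series:
    """Normalize LCK or CTxB to the CD4 signal, fraction by fraction.

    normalized[f] = channel[f] / CD4[f] * cd4_percent[f]; fractions with no
    CD4 signal are reported as 0 (no CD4-bound signal attributable).
    """
    if channel not in ("LCK", "CTxB"):
        raise ValueError(f"channel must be LCK or CTxB, got {channel!r}")
    sub = p.require_subtracted()
    cd4 = sub["CD4"]
    pct = cd4_percent_of_total(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = sub[channel] / cd4 * pct
    return norm.where(cd4 > 0, 0.0)


def auc_drm_dsm(normalized: pd.Series | np.ndarray) -> AucResult:
    """Trapezoid AUC over fraction index: DRM = [1, 6], DSM = [6, 10].

    The shared endpoint at fraction 6 makes DRM + DSM equal the total AUC
    exactly.
    """
    y = np.asarray(normalized, dtype=float)
    if y.size != N_FRACTIONS:
        raise ValueError(f"expected {N_FRACTIONS} values, got {y.size}")
    x = np.arange(1, N_FRACTIONS + 1, dtype=float)
    drm = float(np.trapezoid(y[0:6], x[0:6]))
    dsm = float(np.trapezoid(y[5:10], x[5:10]))
    return AucResult(drm_auc=drm, dsm_auc=dsm, total_auc=drm + dsm)


# ---------------------------------------------------------------------------
# CSV I/O (long format: fraction, channel, gmfi)


def read_gradient_csv(path: str | Path) -> GradientProfile:
    df = pd.read_csv(path)
    for col in ("fraction", "channel", "gmfi"):
        if col not in df.columns:
            raise ValueError(f"gradient CSV missing column {col!r}")
    wide = df.pivot_table(index="fraction", columns="channel", values="gmfi")
    wide.index = wide.index.astype(int)
    wide = wide.sort_index()
    return GradientProfile(raw=wide)


def write_gradient_csv(p: GradientProfile, path: str | Path, *, layer: str = "raw") -> None:
    table = p.raw if layer == "raw" else p.require_subtracted()
    long = table.reset_index(names="fraction").melt(
        id_vars="fraction", var_name="channel", value_name="gmfi"
    )
    long.sort_values(["fraction", "channel"]).to_csv(path, index=False)
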