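"""IL-2 dose-response summaries, endocytosis deltas, percent-of-control tables."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseSeries",
    "EndocytosisRecord",
    "dose_response_auc",
    "sensitivity_at",
    "endocytosis_delta",
    "percent_of_control",
    "build_summary_table",
    "read_dose_csv",
    "write_dose_csv",
    "ND",
]

ND = "ND"  # not-done marker in summary tables


@dataclass(frozen=True)
class DoseSeries:
    """Peptide titration with replicate IL-2 readings.

    ``conc_nM`` is strictly decreasing (default titration: 30 uM top, 1:3
    steps).  ``replicates`` holds one sequence of readings per dose.
    """

    conc_nM: np.ndarray
    replicates: tuple[tuple[float, ...], ...]
    line_id: str = ""
    pairing: str | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc_nM, dtype=float)
        if conc.size < 2:
            raise ValueError("a dose series needs at least 2 doses")
        if not np.all(np.diff(conc) < 0):
            raise ValueError("conc_nM must be strictly decreasing")
        reps = tuple(tuple(float(v) for v in r) for r in self.replicates)
        if len(reps) != conc.size:
            raise ValueError("one replicate tuple required per dose")
        if any(len(r) == 0 for r in reps):
            raise ValueError("every dose needs at least one replicate")
        object.__setattr__(self, "conc_nM", conc)
        object.__setattr__(self, "replicates", reps)

    @property
    def means(self) -> np.ndarray:
        return np.array([np.mean(r) for r in self.replicates])


@dataclass(frozen=True)
class EndocytosisRecord:
    """Surface gMFI replicates at 0 uM and 10 uM peptide for one marker."""

    gmfi_0uM: tuple[float, ...]
    gmfi_10uM: tuple[float, ...]
    marker: str = "CD4"

    def __post_init__(self) -> None:
        if len(self.gmfi_0uM) == 0 or len(self.gmfi_10uM) == 0:
            raise ValueError("replicates required at both 0 uM and 10 uM")


def dose_response_auc(s: DoseSeries, *, axis: str = "log10") -> float:
    """Trapezoid AUC of the mean IL-2 reading against the dose axis.

    ``axis='log10'`` (default) integrates against log10(conc_nM), dropping
    any non-positive concentration; ``axis='index'`` integrates against the
    dilution step index.  Baseline is 0.
    """
    y = s.means
    if axis == "log10":
        keep = s.conc_nM > 0
        if keep.sum() < 2:
            raise ValueError("need >= 2 positive concentrations for log10 AUC")
        x = np.log10(s.conc_nM[keep])
        y = y[keep]
    elif axis == "index":
        x = np.arange(s.conc_nM.size, 0, -1, dtype=float)
    else:
        raise ValueError(f"unknown axis mode {axis!r}")
    order = np.argsort(x)
    return float(np.trapezoid(y[order], x[order]))


def sensitivity_at(s: DoseSeries, target_nM: float = 41.0) -> float:
    """Mean IL-2 at the titration point closest to ``target_nM``.

    The measured point is used directly (no curve interpolation).  For the
    default 30 uM / 1:3 series the 7th dose, 30000/3^6 ~ 41.15 nM, is the
    low-dose sensitivity point.  Errors if no dose is within 25% relative
    distance of the target.
    """
    rel = np.abs(s.conc_nM - target_nM) / target_nM
    k = int(np.argmin(rel))
    if rel[k] > 0.25:
        raise ValueError(
            f"no dose within 25% of {target_nM} nM (closest: {s.conc_nM[k]:.3g} nM)"
        )
    return float(np.mean(s.replicates[k]))


def endocytosis_delta(r: EndocytosisRecord) -> np.ndarray:
    """Change in surface gMFI from 0 uM to 10 uM peptide.

    Each 10 uM replicate is subtracted from the 0 uM average; positive values
    indicate internalization, negative values a surface increase.
    """
    base = float(np.mean(r.gmfi_0uM))
    return base - np.asarray(r.gmfi_10uM, dtype=float)


def percent_of_control(metric_mutant: float, metric_control: float) -> int:
    """Mutant metric as integer percent of its paired control.

    100 * mutant / control, rounded half away from zero; sign preserved.
    """
    if metric_control == 0:
        raise ValueError("control metric is zero; percent of control undefined")
    ratio = 100.0 * metric_mutant / metric_control
    return int(math.copysign(math.floor(abs(ratio) + 0.5), ratio))


def build_summary_table(
    metrics: Mapping[str, Mapping[str, float]],
    pairings: Mapping[str, str],
    *,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble a percent-of-control summary table.

    ``metrics`` maps line name -> metric name -> raw value; ``pairings`` maps
    every line (controls map to themselves) to its control line.  Control
    rows are 100 in every measured column; metrics missing for a line are
    marked ``ND``.
    """
    if columns is None:
        seen: list[str] = []
        for m in metrics.values():
            for name in m:
                if name not in seen:
                    seen.append(name)
        columns = seen
    rows = {}
    for line in pairings:
        if line not in metrics:
            raise KeyError(f"no metrics recorded for line {line!r}")
        control = pairings[line]
        if control not in metrics:
            raise KeyError(f"line {line!r} paired to unknown control {control!r}")
        row = {}
        for col in columns:
            mv = metrics[line].get(col)
            cv = metrics[control].get(col)
            if mv is None or cv is None:
                row[col] = ND
            else:
                row[col] = percent_of_control(mv, cv)
        rows[line] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(columns))


# ---------------------------------------------------------------------------
# CSV I/O (long format: conc_nM, rep, il2)


def read_dose_csv(path: str | Path, *, line_id: str = "") -> DoseSeries:
    df = pd.read_csv(path)
    for col in ("conc_nM", "rep", "il2"):
        if col not in df.columns:
            raise ValueError(f"dose CSV missing column {col!r}")
    conc = np.sort(df["conc_nM"].unique())[::-1]
    reps = tuple(
        tuple(df.loc[df["conc_nM"] == c].sort_values("rep")["il2"]) for c in conc
    )
    return DoseSeries(conc_nM=conc, replicates=reps, line_id=line_id)


def write_dose_csv(s: DoseSeries, path: str | Path) -> None:
    records = [
        {"conc_nM": c, "rep": j + 1, "il2": v}
        for c, reps in zip(s.conc_nM, s.replicates)
        for j, v in enumerate(reps)
    ]
    pd.DataFrame.from_records(records).to_csv(path, index=False)
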