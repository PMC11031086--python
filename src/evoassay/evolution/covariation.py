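"""Column-pair mutual information, average-product correction, covariation calls.

The calling rule is a dual threshold: a pair covaries when MI > 4 and both
members score below -0.5 on the normalized conservation scale, or when
MI > 8 and both score below -0.3.  A cap keeps at most 0.5% of all possible
pairs, ranked by MI.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import AMINO_ACIDS
from .msa import MsaBundle

__all__ = ["CovariationCriteria", "mutual_information", "call_covariation"]

_AA_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_N_AA = len(AMINO_ACIDS)


@dataclass(frozen=True)
class CovariationCriteria:
    mi_lo: float = 4.0
    cons_lo: float = -0.5
    mi_hi: float = 8.0
    cons_hi: float = -0.3
    select_fraction: float = 0.005

    def __post_init__(self) -> None:
        if not self.mi_lo < self.mi_hi:
            raise ValueError("mi_lo must be below mi_hi")
        if not self.cons_lo < self.cons_hi:
            raise ValueError("cons_lo must be below cons_hi")
        if not 0 < self.select_fraction <= 1:
            raise ValueError("select_fraction must be in (0, 1]")


def _encode(msa: MsaBundle) -> np.ndarray:
    codes = np.full(msa.protein.shape, -1, dtype=np.int16)
    for aa, k in _AA_CODE.items():
        codes[msa.protein == aa] = k
    return codes


def mutual_information(
    msa: MsaBundle, *, min_joint_coverage: float = 0.5
) -> pd.DataFrame:
    """Plug-in mutual information (bits) for every unordered column pair.

    Only rows that are non-gap in both columns enter a pair's joint counts.
    Pairs whose joint coverage falls below ``min_joint_coverage`` of the
    alignment rows (or below 2 rows) are left unscored (NaN).  ``mi_apc``
    subtracts the average-product correction, computed over scored pairs.
    """
    if msa.n_cols < 3:
        raise ValueError("need >= 3 columns for the average-product correction")
    codes = _encode(msa)
    n_rows = msa.n_seqs
    min_rows = max(2, int(np.ceil(min_joint_coverage * n_rows)))
    positions = msa.positions
    pairs = list(itertools.combinations(range(msa.n_cols), 2))
    mi = np.full(len(pairs), np.nan)
    n_joint = np.zeros(len(pairs), dtype=int)
    for k, (i, j) in enumerate(pairs):
        a, b = codes[:, i], codes[:, j]
        ok = (a >= 0) & (b >= 0)
        n = int(ok.sum())
        n_joint[k] = n
        if n < min_rows:
            continue
        joint = np.bincount(
            a[ok].astype(np.int64) * _N_AA + b[ok], minlength=_N_AA * _N_AA
        ).reshape(_N_AA, _N_AA) / n
        pa = joint.sum(axis=1)
        pb = joint.sum(axis=0)
        mask = joint > 0
        mi[k] = float(
            (joint[mask] * np.log2(joint[mask] / np.outer(pa, pb)[mask])).sum()
        )
    df = pd.DataFrame(
        {
            "pos_i": [int(positions[i]) for i, _ in pairs],
            "pos_j": [int(positions[j]) for _, j in pairs],
            "n_joint": n_joint,
            "mi_raw": mi,
        }
    )
    df["mi_apc"] = df["mi_raw"] - _apc(df, positions)
    return df


def _apc(df: pd.DataFrame, positions: np.ndarray) -> pd.Series:
    """Average-product correction term mean_i * mean_j / mean_all."""
    scored = df.dropna(subset=["mi_raw"])
    sums = {int(p): 0.0 for p in positions}
    counts = {int(p): 0 for p in positions}
    for pi, pj, v in zip(scored["pos_i"], scored["pos_j"], scored["mi_raw"]):
        sums[pi] += v
        counts[pi] += 1
        sums[pj] += v
        counts[pj] += 1
    col_mean = {p: (sums[p] / counts[p] if counts[p] else np.nan) for p in sums}
    overall = scored["mi_raw"].mean() if len(scored) else np.nan
    if not overall or np.isnan(overall):
        return pd.Series(0.0, index=df.index)
    return pd.Series(
        [col_mean[pi] * col_mean[pj] / overall for pi, pj in zip(df["pos_i"], df["pos_j"])],
        index=df.index,
    )


def call_covariation(
    pairs: pd.DataFrame,
    conservation: pd.Series,
    criteria: CovariationCriteria = CovariationCriteria(),
    *,
    score: str = "mi_raw",
    apply_cap: bool = True,
) -> pd.DataFrame:
    """Apply the dual-threshold covariation rule to a pair table.

    A pair is called when ``score > mi_lo`` and both members' conservation is
    strictly below ``cons_lo`` (low-MI rule), or ``score > mi_hi`` with both
    below ``cons_hi`` (high-MI rule).  When more than ``select_fraction`` of
    all possible pairs pass and ``apply_cap`` is set, only the top fraction
    ranked by MI (ties broken by lexicographic pair order) is kept.  The
    result carries ``covary_call``, ``rule_fired``, and a ``called_fraction``
    attribute.
    """
    out = pairs.copy()
    cons_i = out["pos_i"].map(conservation)
    cons_j = out["pos_j"].map(conservation)
    mi = out[score]
    scored = mi.notna() & cons_i.notna() & cons_j.notna()
    low = scored & (mi > criteria.mi_lo) & (cons_i < criteria.cons_lo) & (cons_j < criteria.cons_lo)
    high = scored & (mi > criteria.mi_hi) & (cons_i < criteria.cons_hi) & (cons_j < criteria.cons_hi)
    call = low | high
    rule = np.where(low, "low_MI_rule", np.where(high, "high_MI_rule", "none"))
    n_positions = conservation.size
    total_pairs = n_positions * (n_positions - 1) // 2
    if apply_cap and total_pairs > 0:
        # ceiling so the cap never zeroes out a small pair table
        cap = int(np.ceil(criteria.select_fraction * total_pairs))
        if call.sum() > cap:
            called = out[call].copy()
            called["_mi"] = mi[call]
            called = called.sort_values(
                ["_mi", "pos_i", "pos_j"], ascending=[False, True, True]
            )
            keep_idx = called.index[:cap]
            dropped = call.index[call].difference(keep_idx)
            call.loc[dropped] = False
            rule = np.where(call, rule, "none")
    out["covary_call"] = call
    out["rule_fired"] = rule
    out.attrs["called_fraction"] = float(call.sum() / total_pairs) if total_pairs else 0.0
    out.attrs["total_possible_pairs"] = total_pairs
    return out
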