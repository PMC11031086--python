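"""Global MG94 fitting and per-site dN/dS likelihood-ratio tests (FEL-style).

A global fit estimates the transition/transversion ratio kappa and a tree
scale (with an optional shared omega) by maximum likelihood.  The per-site
test then fits a synonymous rate alpha and nonsynonymous rate beta for one
codon column, against a null with beta = alpha; significance comes from a
chi-square(1) likelihood-ratio test, and a site is flagged as purifying when
beta < alpha with p below the significance level (default 0.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .models import CODON_INDEX, mg94_model
from .msa import MsaBundle
from .trees import TreeIndex, alignment_log_likelihood

__all__ = [
    "GlobalFit",
    "FelResult",
    "fit_global_kappa_and_scale",
    "fit_global_mg94",
    "fel_site_test",
    "fel_scan",
]

P_SIGNIFICANCE = 0.1  # per-site LRT threshold for the purifying flag


@dataclass(frozen=True)
class GlobalFit:
    kappa: float
    scale: float
    omega: float
    log_likelihood: float


@dataclass(frozen=True)
class FelResult:
    site: int
    alpha: float
    beta: float
    omega: float
    lrt_stat: float
    p_value: float
    purifying_flag: bool
    informative: bool = True


def _codon_states(msa: MsaBundle) -> dict[str, np.ndarray]:
    if msa.codon is None:
        raise ValueError("bundle has no codon layer")
    states = {}
    for row, seq_id in enumerate(msa.ids):
        states[seq_id] = np.array(
            [CODON_INDEX.get(c, -1) for c in msa.codon[row]], dtype=int
        )
    return states


def _compress_patterns(
    states: dict[str, np.ndarray],
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    ids = sorted(states)
    matrix = np.stack([states[i] for i in ids], axis=0)  # (n_tips, n_sites)
    patterns, counts = np.unique(matrix, axis=1, return_counts=True)
    compressed = {i: patterns[k] for k, i in enumerate(ids)}
    return compressed, counts.astype(float)


def _require_tree(msa: MsaBundle) -> TreeIndex:
    if msa.tree is None:
        raise ValueError("bundle has no tree")
    tree = TreeIndex.from_newick(msa.tree)
    if tree.total_length <= 0:
        raise ValueError("tree has zero total length; likelihood is degenerate")
    return tree


def _global_loglik(
    tree: TreeIndex,
    tips: dict[str, np.ndarray],
    weights: np.ndarray,
    kappa: float,
    scale: float,
    omega: float,
) -> float:
    model = mg94_model(kappa, alpha=1.0, beta=omega)
    return alignment_log_likelihood(tree, model, tips, scale=scale, weights=weights)


def fit_global_mg94(
    msa: MsaBundle,
    *,
    fit_omega: bool = True,
    omega: float = 1.0,
    start: tuple[float, float, float] = (2.0, 1.0, 1.0),
) -> GlobalFit:
    """Maximum-likelihood fit of kappa, tree scale, and (optionally) omega.

    Equal codon frequencies; the synonymous rate is fixed at 1 so the scale
    parameter absorbs the overall rate.  Deterministic (fixed start point).
    """
    tree = _require_tree(msa)
    tips, weights = _compress_patterns(_codon_states(msa))

    if fit_omega:
        def objective(logp: np.ndarray) -> float:
            k, s, w = np.exp(logp)
            return -_global_loglik(tree, tips, weights, k, s, w)
        x0 = np.log(np.asarray(start))
    else:
        def objective(logp: np.ndarray) -> float:
            k, s = np.exp(logp)
            return -_global_loglik(tree, tips, weights, k, s, omega)
        x0 = np.log(np.asarray(start[:2]))

    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"MG94 optimization failed: {res.message}")
    vals = np.exp(res.x)
    fitted_omega = float(vals[2]) if fit_omega else float(omega)
    return GlobalFit(
        kappa=float(vals[0]),
        scale=float(vals[1]),
        omega=fitted_omega,
        log_likelihood=float(-res.fun),
    )


def fit_global_kappa_and_scale(msa: MsaBundle, *, omega: float = 1.0) -> GlobalFit:
    """Fit kappa and tree scale with omega held as a fixed nuisance (default 1)."""
    return fit_global_mg94(msa, fit_omega=False, omega=omega)


def _site_loglik(
    tree: TreeIndex,
    site_states: dict[str, np.ndarray],
    kappa: float,
    scale: float,
    alpha: float,
    beta: float,
) -> float:
    model = mg94_model(kappa, alpha=alpha, beta=beta)
    return alignment_log_likelihood(tree, model, site_states, scale=scale)


_LOG_RATE_LO, _LOG_RATE_HI = -7.0, 3.0


def fel_site_test(
    msa: MsaBundle,
    site: int,
    kappa: float,
    scale: float,
    *,
    p_threshold: float = P_SIGNIFICANCE,
) -> FelResult:
    """Per-site test of selection: beta = alpha (null) vs free alpha, beta.

    ``site`` is a 0-based codon column index.  Invariant sites are reported
    as uninformative with p = 1.  ``purifying_flag`` is true when
    beta < alpha and p < ``p_threshold``.
    """
    return _fel_site(_require_tree(msa), _codon_states(msa), site, kappa, scale,
                     p_threshold=p_threshold)


def _fel_site(
    tree: TreeIndex,
    states: dict[str, np.ndarray],
    site: int,
    kappa: float,
    scale: float,
    *,
    p_threshold: float = P_SIGNIFICANCE,
) -> FelResult:
    site_states = {k: v[site : site + 1] for k, v in states.items()}
    observed = {int(v[0]) for v in site_states.values() if v[0] >= 0}
    if len(observed) <= 1:
        return FelResult(site, math.nan, math.nan, math.nan, 0.0, 1.0, False,
                         informative=False)

    def null_neg(log_a: float) -> float:
        a = math.exp(log_a)
        return -_site_loglik(tree, site_states, kappa, scale, a, a)

    null = minimize_scalar(null_neg, bounds=(_LOG_RATE_LO, _LOG_RATE_HI),
                           method="bounded", options={"xatol": 1e-6})
    lnl_null = -null.fun

    def alt_neg(logp: np.ndarray) -> float:
        a, b = np.exp(np.clip(logp, _LOG_RATE_LO, _LOG_RATE_HI))
        return -_site_loglik(tree, site_states, kappa, scale, a, b)

    alt = minimize(alt_neg, np.array([null.x, null.x]), method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 500})
    lnl_alt = -alt.fun
    alpha, beta = np.exp(np.clip(alt.x, _LOG_RATE_LO, _LOG_RATE_HI))
    lrt = max(0.0, 2.0 * (lnl_alt - lnl_null))
    p = float(chi2.sf(lrt, df=1))
    omega = float(beta / alpha) if alpha > 0 else math.inf
    return FelResult(
        site=site,
        alpha=float(alpha),
        beta=float(beta),
        omega=omega,
        lrt_stat=float(lrt),
        p_value=p,
        purifying_flag=bool(beta < alpha and p < p_threshold),
    )


def fel_scan(
    msa: MsaBundle,
    kappa: float | None = None,
    scale: float | None = None,
    *,
    sites: list[int] | None = None,
    p_threshold: float = P_SIGNIFICANCE,
) -> pd.DataFrame:
    """Run the per-site test across codon columns; fits kappa/scale if absent."""
    if kappa is None or scale is None:
        g = fit_global_kappa_and_scale(msa)
        kappa = g.kappa if kappa is None else kappa
        scale = g.scale if scale is None else scale
    if sites is None:
        sites = list(range(msa.n_cols))
    tree = _require_tree(msa)
    states = _codon_states(msa)
    rows = [_fel_site(tree, states, s, kappa, scale, p_threshold=p_threshold)
            for s in sites]
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("site")
    df.attrs["kappa"] = kappa
    df.attrs["scale"] = scale
    return df
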