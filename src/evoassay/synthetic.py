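"""Seeded synthetic-data generators for every pipeline input.

Each generator is a pure function of its parameter record (seed included)
and draws from its own named RNG stream, so adding draws to one generator
never perturbs another.  Ground truth (planted responder fractions, peak
positions, site classes) is carried in the parameter records for
parameter-recovery tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .assays import DoseSeries
from .flow import BinnedHistogram
from .gradient import CHANNELS, N_FRACTIONS, GradientProfile
from .evolution.models import (
    AMINO_ACIDS,
    SENSE_CODONS,
    mg94_rate_matrix,
)
from .evolution.msa import MsaBundle
from .evolution.trees import TreeIndex

__all__ = [
    "FlowSimParams",
    "GradientSimParams",
    "EvoSimParams",
    "gen_flow_pair",
    "gen_gradient_profile",
    "gen_dose_series",
    "gen_protein_msa",
    "gen_codon_alignment",
    "make_covariation_fixture",
    "balanced_tree_newick",
]

# fixed per-operation stream ids (see module docstring)
_STREAMS = {
    "flow": 101,
    "gradient": 102,
    "dose": 103,
    "protein_msa": 104,
    "codon_alignment": 105,
}


def _rng(op: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[op], seed])


# ---------------------------------------------------------------------------
# Flow-cytometry histogram pairs


@dataclass(frozen=True)
class FlowSimParams:
    """Two-population event mixture for a null/agonist stimulation pair.

    Intensities live on a log10 scale.  Non-responders draw from
    N(null_log_mean, null_log_sd); responders are shifted up by ``shift``.
    The default 1024 bins over [0, 5] mirror a cytometer histogram export.
    """

    n_events: int = 10_000
    responder_fraction: float = 0.3
    null_log_mean: float = 2.0
    null_log_sd: float = 0.25
    shift: float = 1.0
    n_bins: int = 1024
    bin_range: tuple[float, float] = (0.0, 5.0)
    channel: str = "pCD3z"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not self.bin_range[0] < self.bin_range[1]:
            raise ValueError("bin_range must satisfy lo < hi")


def gen_flow_pair(params: FlowSimParams) -> tuple[BinnedHistogram, BinnedHistogram]:
    """Generate matched (null, agonist) histograms on identical bin edges.

    Both histograms contain exactly ``n_events`` counts; events falling
    outside ``bin_range`` are clamped into the edge bins.
    """
    rng = _rng("flow", params.seed)
    lo, hi = params.bin_range
    edges = np.linspace(lo, hi, params.n_bins + 1)

    null_vals = rng.normal(params.null_log_mean, params.null_log_sd, params.n_events)
    n_resp = rng.binomial(params.n_events, params.responder_fraction)
    ago_null = rng.normal(
        params.null_log_mean, params.null_log_sd, params.n_events - n_resp
    )
    ago_resp = rng.normal(
        params.null_log_mean + params.shift, params.null_log_sd, n_resp
    )
    ago_vals = np.concatenate([ago_null, ago_resp])

    def binned(values: np.ndarray, label: str) -> BinnedHistogram:
        clamped = np.clip(values, lo, np.nextafter(hi, lo))
        counts, _ = np.histogram(clamped, bins=edges)
        return BinnedHistogram(edges, counts.astype(float), label=label,
                               channel=params.channel)

    return binned(null_vals, "null"), binned(ago_vals, "agonist")


# ---------------------------------------------------------------------------
# Sucrose-gradient profiles


@dataclass(frozen=True)
class GradientSimParams:
    """Ten-fraction gradient with Gaussian DRM and DSM peaks over a background.

    ``amplitudes`` maps each channel to (drm_amplitude, dsm_amplitude).
    Fraction 1 carries background (plus noise) only.
    """

    drm_center: float = 3.0
    dsm_center: float = 8.0
    amplitudes: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "CD4": (60.0, 40.0),
            "LCK": (50.0, 20.0),
            "CTxB": (80.0, 10.0),
        }
    )
    peak_width: float = 0.8
    background_offset: float = 5.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for center in (self.drm_center, self.dsm_center):
            if not 1 <= center <= N_FRACTIONS:
                raise ValueError("peak centers must lie in fractions 1..10")
        if self.background_offset < 0:
            raise ValueError("background_offset must be >= 0")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")
        missing = [c for c in CHANNELS if c not in self.amplitudes]
        if missing:
            raise ValueError(f"amplitudes missing channels {missing}")


def gen_gradient_profile(params: GradientSimParams) -> GradientProfile:
    rng = _rng("gradient", params.seed)
    fx = np.arange(1, N_FRACTIONS + 1, dtype=float)
    data = {}
    for channel in CHANNELS:
        drm_amp, dsm_amp = params.amplitudes[channel]
        drm = drm_amp * np.exp(-((fx - params.drm_center) ** 2) / (2 * params.peak_width**2))
        dsm = dsm_amp * np.exp(-((fx - params.dsm_center) ** 2) / (2 * params.peak_width**2))
        signal = drm + dsm
        signal[0] = 0.0  # fraction 1 is pure background
        noise = rng.normal(0.0, params.noise_sd, N_FRACTIONS) if params.noise_sd > 0 else 0.0
        data[channel] = np.clip(params.background_offset + signal + noise, 0.0, None)
    raw = pd.DataFrame(data, index=pd.RangeIndex(1, N_FRACTIONS + 1, name="fraction"))
    return GradientProfile(raw=raw)


# ---------------------------------------------------------------------------
# IL-2 dose-response series


def gen_dose_series(
    top_conc_uM: float = 30.0,
    dilution: float = 3.0,
    n_points: int = 12,
    fourpl: tuple[float, float, float, float] = (0.0, 1000.0, 300.0, 1.0),
    cv: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
    line_id: str = "",
) -> DoseSeries:
    """Simulate a 1:3-style titration with 4PL-mean replicate readings.

    ``fourpl`` is (bottom, top, ec50_nM, hill); replicate readings are the
    4PL mean times multiplicative lognormal noise with coefficient of
    variation ``cv`` (mean-1 noise, so cv=0 reproduces the curve exactly).
    """
    if dilution <= 1:
        raise ValueError("dilution must be > 1")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = _rng("dose", seed)
    conc = top_conc_uM * 1000.0 / dilution ** np.arange(n_points)
    bottom, top, ec50, hill = fourpl
    means = bottom + (top - bottom) / (1.0 + (ec50 / conc) ** hill)
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=(n_points, n_reps))
    else:
        noise = np.ones((n_points, n_reps))
    readings = means[:, None] * noise
    return DoseSeries(
        conc_nM=conc,
        replicates=tuple(tuple(row) for row in readings),
        line_id=line_id,
    )


# ---------------------------------------------------------------------------
# Alignments with planted site classes


@dataclass(frozen=True)
class EvoSimParams:
    """Tree plus per-site class labels for alignment simulation.

    Site classes: ``conserved`` (invariant), ``neutral``, ``covary:<k>``
    (the two members of pair k are copies up to a random state relabeling),
    ``purifying:<w>`` / ``positive:<w>`` (rate/omega multiplier w).
    """

    tree: str
    site_classes: tuple[str, ...]
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        object.__setattr__(self, "site_classes", tuple(self.site_classes))
        pair_counts: dict[str, int] = {}
        for label in self.site_classes:
            kind, arg = _parse_class(label)
            if kind == "covary":
                pair_counts[arg] = pair_counts.get(arg, 0) + 1
        bad = {k: n for k, n in pair_counts.items() if n != 2}
        if bad:
            raise ValueError(f"covary pair labels must appear exactly twice: {bad}")

    @property
    def n_sites(self) -> int:
        return len(self.site_classes)


def _parse_class(label: str) -> tuple[str, str]:
    kind, _, arg = label.partition(":")
    if kind not in ("conserved", "neutral", "covary", "purifying", "positive"):
        raise ValueError(f"unknown site class {label!r}")
    if kind in ("covary", "purifying", "positive") and not arg:
        raise ValueError(f"site class {label!r} needs an argument")
    if kind in ("purifying", "positive") and float(arg) < 0:
        raise ValueError("omega must be >= 0")
    return kind, arg


def _simulate_sites(
    tree: TreeIndex,
    q: np.ndarray,
    n_states: int,
    n_sites: int,
    rng: np.random.Generator,
    rate: float = 1.0,
) -> np.ndarray:
    """Evolve ``n_sites`` iid characters along the tree; returns tip rows.

    Transition matrices come from a direct matrix exponential (cached per
    branch length), kept independent of the spectral code used for
    estimation.
    """
    pcache: dict[float, np.ndarray] = {}

    def pmat(t: float) -> np.ndarray:
        if t not in pcache:
            p = expm(q * t)
            np.clip(p, 0.0, None, out=p)
            p /= p.sum(axis=1, keepdims=True)
            pcache[t] = np.cumsum(p, axis=1)
        return pcache[t]

    states = np.empty((tree.n_nodes, n_sites), dtype=int)
    states[tree.root] = rng.integers(0, n_states, n_sites)
    for i in reversed(tree.postorder):  # preorder
        for c in tree.children[i]:
            t = tree.edge_length[c] * rate
            if t == 0:
                states[c] = states[i]
                continue
            cum = pmat(t)
            u = rng.random(n_sites)
            rows = cum[states[i]]
            states[c] = (rows < u[:, None]).sum(axis=1)
    tips = tree.tips
    return states[list(tips)]


def _poisson_q(n_states: int) -> np.ndarray:
    q = np.full((n_states, n_states), 1.0 / (n_states - 1))
    np.fill_diagonal(q, -1.0)
    return q


def gen_protein_msa(params: EvoSimParams, ref_offset: int = 48) -> MsaBundle:
    """Simulate a protein alignment with planted site classes on the tree.

    Conserved sites are invariant; neutral sites evolve under the symmetric
    20-state model; each covary pair shares one latent neutral character,
    with the second member relabeled by a random permutation (perfect
    covariation); purifying/positive classes scale the neutral rate by their
    omega argument.
    """
    tree = TreeIndex.from_newick(params.tree, require_lengths=False)
    if len(tree.tip_labels) < 3:
        raise ValueError("tree must have >= 3 tips")
    rng = _rng("protein_msa", params.seed)
    n_aa = len(AMINO_ACIDS)
    q = _poisson_q(n_aa)
    tip_order = [tree.tip_labels[i] for i in tree.tips]
    n_tips = len(tip_order)
    out = np.empty((n_tips, params.n_sites), dtype=int)

    parsed = [_parse_class(lbl) for lbl in params.site_classes]
    pair_first: dict[str, int] = {}
    for col, (kind, arg) in enumerate(parsed):
        if kind == "conserved":
            out[:, col] = rng.integers(0, n_aa)
        elif kind == "neutral":
            out[:, col] = _simulate_sites(tree, q, n_aa, 1, rng)[:, 0]
        elif kind == "covary":
            if arg not in pair_first:
                pair_first[arg] = col
                out[:, col] = _simulate_sites(tree, q, n_aa, 1, rng)[:, 0]
            else:
                perm = rng.permutation(n_aa)
                out[:, col] = perm[out[:, pair_first[arg]]]
        else:  # purifying / positive: rate-scaled neutral evolution
            out[:, col] = _simulate_sites(tree, q, n_aa, 1, rng, rate=float(arg))[:, 0]

    letters = np.array(list(AMINO_ACIDS))
    return MsaBundle(
        ids=tuple(tip_order),
        protein=letters[out],
        tree=params.tree,
        ref_offset=ref_offset,
    )


def gen_codon_alignment(params: EvoSimParams, ref_offset: int = 48) -> MsaBundle:
    """Simulate a codon alignment with per-site omega on the tree.

    Sites evolve independently under the MG94-style model (equal codon
    frequencies, global kappa): neutral sites have omega 1, purifying and
    positive classes their given omega, conserved sites are invariant.
    ``covary`` classes are protein-level only and rejected here.
    """
    tree = TreeIndex.from_newick(params.tree)  # branch lengths required
    rng = _rng("codon_alignment", params.seed)
    n_codons = len(SENSE_CODONS)
    tip_order = [tree.tip_labels[i] for i in tree.tips]
    out = np.empty((len(tip_order), params.n_sites), dtype=int)

    omegas: list[float | None] = []
    for lbl in params.site_classes:
        kind, arg = _parse_class(lbl)
        if kind == "covary":
            raise ValueError("covary site classes are not supported at codon level")
        if kind == "conserved":
            omegas.append(None)
        elif kind == "neutral":
            omegas.append(1.0)
        else:
            omegas.append(float(arg))

    # batch columns sharing an omega so transition matrices are reused
    for omega in sorted({w for w in omegas if w is not None}):
        cols = [c for c, w in enumerate(omegas) if w == omega]
        q = mg94_rate_matrix(params.kappa, 1.0, omega)
        out[:, cols] = _simulate_sites(tree, q, n_codons, len(cols), rng)
    for col, omega in enumerate(omegas):
        if omega is None:
            out[:, col] = rng.integers(0, n_codons)

    codons = np.array(SENSE_CODONS)
    from .evolution.models import CODON_TO_AA

    aa_of = np.array([CODON_TO_AA[c] for c in SENSE_CODONS])
    return MsaBundle(
        ids=tuple(tip_order),
        protein=aa_of[out],
        codon=codons[out],
        tree=params.tree,
        ref_offset=ref_offset,
    )


def balanced_tree_newick(
    n_tips: int, branch_length: float = 0.1, prefix: str = "t"
) -> str:
    """Newick for a balanced tree with uniform branch lengths.

    Tip counts that are not powers of two are split as evenly as possible.
    """
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    counter = itertools.count(1)

    def build(n: int) -> str:
        if n == 1:
            return f"{prefix}{next(counter)}:{branch_length}"
        left = build(n // 2)
        right = build(n - n // 2)
        return f"({left},{right}):{branch_length}"

    body = build(n_tips)
    return body.rsplit(":", 1)[0] + ";"


# ---------------------------------------------------------------------------
# Deterministic covariation fixture


def make_covariation_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic 401-position site/pair fixture for the calling rule.

    Positions 1-58 have conservation -1.0, positions 59-401 have 0.0.  The
    first 401 lexicographic pairs among positions 1-58 carry MI 9.0; every
    other pair carries MI 0.1.  Exactly 401 of the C(401, 2) = 80,200 pairs
    (0.5%) satisfy the dual-threshold rule.
    """
    n_pos = 401
    positions = np.arange(1, n_pos + 1)
    conservation = np.where(positions <= 58, -1.0, 0.0)
    sites = pd.DataFrame({"conservation": conservation}, index=positions)
    sites.index.name = "position"

    hot = set(itertools.islice(itertools.combinations(range(1, 59), 2), 401))
    records = [
        (i, j, 9.0 if (i, j) in hot else 0.1)
        for i, j in itertools.combinations(range(1, n_pos + 1), 2)
    ]
    pairs = pd.DataFrame(records, columns=["pos_i", "pos_j", "mi_raw"])
    return sites, pairs
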