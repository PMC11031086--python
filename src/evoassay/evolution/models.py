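"""Substitution models: amino-acid (Poisson, JTT) and MG94-style codon model.

All models are time-reversible.  Transition matrices are computed from an
eigendecomposition of the symmetrized rate matrix so that repeated
evaluations along a tree are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

from ._jtt import JTT_EXCHANGE_LOWER, JTT_FREQS, JTT_ORDER

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

__all__ = [
    "AMINO_ACIDS",
    "SENSE_CODONS",
    "CODON_TO_AA",
    "SubstitutionModel",
    "poisson_aa_model",
    "jtt_aa_model",
    "mg94_rate_matrix",
    "mg94_model",
]


def _sense_codons() -> tuple[tuple[str, ...], dict[str, str]]:
    table = CodonTable.unambiguous_dna_by_id[1]  # standard code
    codons = tuple(
        sorted(c for c in table.forward_table if set(c) <= set(NUCLEOTIDES))
    )
    return codons, {c: table.forward_table[c] for c in codons}


SENSE_CODONS, CODON_TO_AA = _sense_codons()
N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _codon_change_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean (61, 61) masks: single-nt change, transition, synonymous."""
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    synonymous = np.zeros_like(single)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transition[i, j] = diffs[0] in _TRANSITIONS
            synonymous[i, j] = CODON_TO_AA[ci] == CODON_TO_AA[cj]
    return single, transition, synonymous


SINGLE_NT_MASK, TRANSITION_MASK, SYNONYMOUS_MASK = _codon_change_masks()


@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible substitution model with precomputed spectral decomposition.

    ``transition_matrix(t)`` returns P(t) with rows indexed by the parent
    state and columns by the child state.
    """

    kind: str
    states: tuple[str, ...]
    rate_matrix: np.ndarray
    freqs: np.ndarray
    _eigvals: np.ndarray
    _left: np.ndarray  # rows: eigenbasis -> states (inverse transform)
    _right: np.ndarray  # states -> eigenbasis

    @classmethod
    def from_rates(cls, kind: str, states: tuple[str, ...], q: np.ndarray,
                   freqs: np.ndarray) -> "SubstitutionModel":
        q = np.asarray(q, dtype=float)
        freqs = np.asarray(freqs, dtype=float)
        if not np.allclose(q.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("rate matrix rows must sum to 0")
        if not np.isclose(freqs.sum(), 1.0):
            raise ValueError("equilibrium frequencies must sum to 1")
        # symmetrize: B = D^(1/2) Q D^(-1/2) is symmetric for reversible Q
        sqrt_pi = np.sqrt(freqs)
        b = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        b = 0.5 * (b + b.T)
        w, u = np.linalg.eigh(b)
        right = u / sqrt_pi[:, None]       # D^(-1/2) U
        left = (u * sqrt_pi[:, None]).T    # U^T D^(1/2)
        return cls(kind, states, q, freqs, w, left, right)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = (self._right * np.exp(self._eigvals * t)[None, :]) @ self._left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def state_index(self, state: str) -> int:
        return self.states.index(state)


def poisson_aa_model() -> SubstitutionModel:
    """Symmetric 20-state model, equal frequencies, mean rate 1."""
    n = len(AMINO_ACIDS)
    q = np.full((n, n), 1.0 / (n - 1))
    np.fill_diagonal(q, -1.0)
    freqs = np.full(n, 1.0 / n)
    return SubstitutionModel.from_rates("poisson_aa", tuple(AMINO_ACIDS), q, freqs)


@lru_cache(maxsize=1)
def jtt_aa_model() -> SubstitutionModel:
    """JTT amino-acid replacement model, mean rate scaled to 1."""
    n = 20
    s = np.zeros((n, n))
    k = 0
    for j in range(n - 1):
        for i in range(j + 1, n):
            s[i, j] = s[j, i] = JTT_EXCHANGE_LOWER[k]
            k += 1
    freqs = np.asarray(JTT_FREQS, dtype=float)
    q = s * freqs[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -(freqs * np.diag(q)).sum()
    q /= mean_rate
    # reorder PAML -> alphabetical
    order = [JTT_ORDER.index(a) for a in AMINO_ACIDS]
    q = q[np.ix_(order, order)]
    freqs = freqs[order]
    freqs = freqs / freqs.sum()
    return SubstitutionModel.from_rates("jtt_aa", tuple(AMINO_ACIDS), q, freqs)


def mg94_rate_matrix(kappa: float, alpha: float, beta: float) -> np.ndarray:
    """MG94-style codon rate matrix with equal codon frequencies.

    Single-nucleotide changes only: synonymous at rate ``alpha``,
    nonsynonymous at rate ``beta``, each multiplied by ``kappa`` for
    transitions.  Multi-nucleotide changes have rate 0.  No normalization is
    applied; branch lengths are interpreted through a fitted global scale.
    """
    if kappa < 0 or alpha < 0 or beta < 0:
        raise ValueError("kappa, alpha, beta must be non-negative")
    q = np.where(SYNONYMOUS_MASK, alpha, beta) * np.where(TRANSITION_MASK, kappa, 1.0)
    q = np.where(SINGLE_NT_MASK, q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def mg94_model(kappa: float, alpha: float = 1.0, beta: float = 1.0) -> SubstitutionModel:
    q = mg94_rate_matrix(kappa, alpha, beta)
    freqs = np.full(N_CODONS, 1.0 / N_CODONS)
    return SubstitutionModel.from_rates("mg94_codon", SENSE_CODONS, q, freqs)
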