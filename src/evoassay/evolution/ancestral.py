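"""Marginal ancestral sequence reconstruction at internal tree nodes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import AMINO_ACIDS, SubstitutionModel, jtt_aa_model
from .msa import GAP, MsaBundle
from .trees import TreeIndex, marginal_posteriors

__all__ = ["AncestralReconstruction", "marginal_ancestral_reconstruction"]

_AA_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class AncestralReconstruction:
    """Per-site state posteriors at one node plus the MAP sequence.

    ``tie_flags`` marks sites where the MAP state was a tie broken
    alphabetically.
    """

    node: str
    posteriors: np.ndarray  # (n_sites, n_states)
    map_sequence: str
    map_posterior: np.ndarray
    tie_flags: np.ndarray
    states: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.posteriors, columns=list(self.states))
        df.insert(0, "map_state", list(self.map_sequence))
        df.insert(1, "map_posterior", self.map_posterior)
        df.insert(2, "tie", self.tie_flags)
        return df


def _aa_states(msa: MsaBundle) -> dict[str, np.ndarray]:
    states = {}
    for row, seq_id in enumerate(msa.ids):
        states[seq_id] = np.array(
            [_AA_CODE.get(a, -1) for a in msa.protein[row]], dtype=int
        )
    return states


def marginal_ancestral_reconstruction(
    msa: MsaBundle,
    node,
    model: SubstitutionModel | None = None,
    *,
    scale: float = 1.0,
) -> AncestralReconstruction:
    """Marginal posterior over amino acids at ``node``, per alignment column.

    ``node`` may be an internal-node label, a node index, or a collection of
    tip labels whose MRCA is reconstructed.  Gaps are treated as missing data
    (flat tip message).  The default model is JTT; MAP ties are broken
    alphabetically and flagged.
    """
    if msa.tree is None:
        raise ValueError("bundle has no tree")
    if model is None:
        model = jtt_aa_model()
    if model.n_states != len(AMINO_ACIDS):
        raise ValueError("ancestral reconstruction requires an amino-acid model")
    tree = TreeIndex.from_newick(msa.tree, require_lengths=False)
    node_idx = tree.resolve_node(node)
    post = marginal_posteriors(tree, model, _aa_states(msa), node_idx, scale=scale)
    # MAP with alphabetical tie-break: treat posteriors within 1e-9 of the
    # maximum as tied and take the first (alphabetically smallest) state.
    peak = post.max(axis=1)
    near_peak = post >= peak[:, None] - 1e-9
    map_idx = near_peak.argmax(axis=1)
    map_post = post[np.arange(post.shape[0]), map_idx]
    ties = near_peak.sum(axis=1) > 1
    seq = "".join(model.states[i] for i in map_idx)
    return AncestralReconstruction(
        node=str(node),
        posteriors=post,
        map_sequence=seq,
        map_posterior=map_post,
        tie_flags=ties,
        states=model.states,
    )
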