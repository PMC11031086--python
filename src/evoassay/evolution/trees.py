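"""Indexed phylogenies and Felsenstein pruning.

Newick parsing is delegated to dendropy; the tree is then flattened into
arrays so that likelihood evaluations inside optimizers stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .models import SubstitutionModel

__all__ = ["TreeIndex", "alignment_log_likelihood", "marginal_posteriors"]


class TreeFormatError(ValueError):
    pass


@dataclass(frozen=True)
class TreeIndex:
    """Array view of a rooted (or arbitrarily rooted) phylogeny.

    Nodes are numbered in postorder with the root last.  ``edge_length[i]``
    is the length of the edge above node ``i`` (0 for the root).
    """

    n_nodes: int
    root: int
    parent: np.ndarray
    edge_length: np.ndarray
    children: tuple[tuple[int, ...], ...]
    postorder: tuple[int, ...]
    tip_labels: dict[int, str]
    node_labels: dict[str, int]
    newick: str

    @classmethod
    def from_newick(cls, text: str, *, require_lengths: bool = True) -> "TreeIndex":
        try:
            tree = dendropy.Tree.get(data=text, schema="newick")
        except Exception as exc:  # dendropy raises various parse errors
            raise TreeFormatError(f"malformed Newick: {exc}") from exc
        nodes = list(tree.postorder_node_iter())
        if sum(1 for n in nodes if n.is_leaf()) < 2:
            raise TreeFormatError("tree must have at least 2 tips")
        index = {id(n): i for i, n in enumerate(nodes)}
        n_nodes = len(nodes)
        parent = np.full(n_nodes, -1, dtype=int)
        edge_length = np.zeros(n_nodes)
        children: list[tuple[int, ...]] = [()] * n_nodes
        tip_labels: dict[int, str] = {}
        node_labels: dict[str, int] = {}
        for node in nodes:
            i = index[id(node)]
            children[i] = tuple(index[id(c)] for c in node.child_nodes())
            if node.parent_node is not None:
                parent[i] = index[id(node.parent_node)]
                if node.edge.length is None:
                    if require_lengths:
                        raise TreeFormatError("tree is missing branch lengths")
                    edge_length[i] = 0.0
                else:
                    edge_length[i] = float(node.edge.length)
            if node.is_leaf():
                if node.taxon is None or node.taxon.label is None:
                    raise TreeFormatError("unlabeled tip in tree")
                tip_labels[i] = node.taxon.label
                node_labels[node.taxon.label] = i
            elif node.taxon is not None and node.taxon.label:
                node_labels[node.taxon.label] = i
            elif node.label:
                node_labels[node.label] = i
        if np.any(edge_length < 0):
            raise TreeFormatError("negative branch length")
        root = index[id(tree.seed_node)]
        return cls(
            n_nodes=n_nodes,
            root=root,
            parent=parent,
            edge_length=edge_length,
            children=tuple(children),
            postorder=tuple(range(n_nodes)),
            tip_labels=tip_labels,
            node_labels=node_labels,
            newick=text.strip(),
        )

    @property
    def tips(self) -> tuple[int, ...]:
        return tuple(sorted(self.tip_labels))

    @property
    def total_length(self) -> float:
        return float(self.edge_length.sum())

    def resolve_node(self, node: str | int | list | tuple | set) -> int:
        """Resolve a node reference: index, label, or a set of tip labels (MRCA)."""
        if isinstance(node, (int, np.integer)):
            if not 0 <= node < self.n_nodes:
                raise KeyError(f"node index {node} out of range")
            return int(node)
        if isinstance(node, str):
            if node not in self.node_labels:
                raise KeyError(f"unknown node label {node!r}")
            return self.node_labels[node]
        return self.mrca(node)

    def mrca(self, tip_names) -> int:
        ids = []
        for name in tip_names:
            if name not in self.node_labels:
                raise KeyError(f"unknown tip {name!r}")
            ids.append(self.node_labels[name])
        if not ids:
            raise KeyError("empty tip set")
        paths = []
        for i in ids:
            path = []
            while i != -1:
                path.append(i)
                i = self.parent[i]
            paths.append(path[::-1])
        anc = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            level = {p[depth] for p in paths}
            if len(level) == 1:
                anc = level.pop()
            else:
                break
        return anc


def _tip_message(states: np.ndarray, n_states: int) -> np.ndarray:
    """One-hot tip conditionals; missing states (-1) give a flat message."""
    n_sites = states.size
    msg = np.zeros((n_sites, n_states))
    observed = states >= 0
    msg[observed, states[observed]] = 1.0
    msg[~observed, :] = 1.0
    return msg


def _conditional_down(
    tree: TreeIndex,
    model: SubstitutionModel,
    tip_states: dict[str, np.ndarray],
    scale: float,
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray]]:
    """Postorder conditional likelihoods with per-site log scaling.

    Returns (partials[n_nodes, n_sites, n_states], log_scaler[n_sites],
    branch transition matrices keyed by node).
    """
    n_states = model.n_states
    n_sites = next(iter(tip_states.values())).size
    partials = np.empty((tree.n_nodes, n_sites, n_states))
    log_scaler = np.zeros(n_sites)
    pmats: dict[int, np.ndarray] = {}
    pcache: dict[float, np.ndarray] = {}  # branches of equal length share P
    for i in tree.postorder:
        kids = tree.children[i]
        if not kids:
            label = tree.tip_labels[i]
            if label not in tip_states:
                raise KeyError(f"tip {label!r} missing from alignment")
            partials[i] = _tip_message(tip_states[label], n_states)
            continue
        acc = np.ones((n_sites, n_states))
        for c in kids:
            t = tree.edge_length[c] * scale
            p = pcache.get(t)
            if p is None:
                p = pcache[t] = model.transition_matrix(t)
            pmats[c] = p
            acc *= partials[c] @ p.T
        peak = acc.max(axis=1)
        peak = np.where(peak > 0, peak, 1.0)
        acc /= peak[:, None]
        log_scaler += np.log(peak)
        partials[i] = acc
    return partials, log_scaler, pmats


def alignment_log_likelihood(
    tree: TreeIndex,
    model: SubstitutionModel,
    tip_states: dict[str, np.ndarray],
    *,
    scale: float = 1.0,
    weights: np.ndarray | None = None,
) -> float:
    """Log-likelihood of aligned site columns under the model.

    ``tip_states`` maps tip labels to per-site state indices (-1 = missing).
    ``weights`` multiplies per-site log-likelihoods (for pattern
    compression).
    """
    partials, log_scaler, _ = _conditional_down(tree, model, tip_states, scale)
    site_l = partials[tree.root] @ model.freqs
    if np.any(site_l <= 0):
        return -np.inf
    site_ll = np.log(site_l) + log_scaler
    if weights is not None:
        site_ll = site_ll * weights
    return float(site_ll.sum())


def marginal_posteriors(
    tree: TreeIndex,
    model: SubstitutionModel,
    tip_states: dict[str, np.ndarray],
    node: int,
    *,
    scale: float = 1.0,
) -> np.ndarray:
    """Per-site marginal posterior over states at an internal (or tip) node.

    Standard two-pass algorithm: conditional likelihoods up from the tips,
    then an outside message propagated from the root.
    """
    partials, _, pmats = _conditional_down(tree, model, tip_states, scale)
    n_sites, n_states = partials.shape[1:]
    outside = np.empty_like(partials)
    outside[tree.root] = model.freqs[None, :]
    # preorder = reversed postorder
    for i in reversed(tree.postorder):
        for c in tree.children[i]:
            acc = outside[i].copy()
            for s in tree.children[i]:
                if s != c:
                    acc *= partials[s] @ pmats[s].T
            out = acc @ pmats[c]
            peak = out.max(axis=1)
            peak = np.where(peak > 0, peak, 1.0)
            outside[c] = out / peak[:, None]
    post = outside[node] * partials[node]
    if node == tree.root:
        post = partials[node] * model.freqs[None, :]
    total = post.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero likelihood at requested node; check inputs")
    return post / total
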