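"""Independent brute-force oracles for the likelihood and reconstruction.

These enumerate every joint assignment of states to internal nodes with
plain array broadcasting — no pruning, no shared code with the engine
they check. Feasible only for small trees (<= 5 tips / 4 internal nodes).
"""

import numpy as np

from ancres.io import Alignment, Phylogeny
from ancres.substitution_models import ReplacementModel


def _placed(arr2d: np.ndarray, ax_parent: int, ax_child: int, ndim: int) -> np.ndarray:
    shape = [1] * ndim
    shape[ax_parent] = 20
    shape[ax_child] = 20
    if ax_parent < ax_child:
        return arr2d.reshape(shape)
    return arr2d.T.reshape(shape)


def _site_joint(
    tree: Phylogeny,
    site_codes: dict[int, int],
    P: dict[int, np.ndarray],
    pi: np.ndarray,
) -> np.ndarray:
    """Joint probability array over all internal-node state assignments."""
    internals = tree.internal_nodes()
    axis = {nd.index: i for i, nd in enumerate(internals)}
    ndim = len(internals)
    shape = [1] * ndim
    shape[axis[tree.root.index]] = 20
    joint = pi.reshape(shape).copy()
    for nd in tree.branches():
        pax = axis[nd.parent.index]
        if nd.is_tip:
            code = site_codes[nd.index]
            if code < 0:
                continue  # missing tip: sum_j P_ij = 1, no factor
            vec_shape = [1] * ndim
            vec_shape[pax] = 20
            joint = joint * P[nd.index][:, code].reshape(vec_shape)
        else:
            joint = joint * _placed(P[nd.index], pax, axis[nd.index], ndim)
    return joint


def enumeration_site_logliks(
    tree: Phylogeny, alignment: Alignment, model: ReplacementModel
) -> np.ndarray:
    """Per-site log-likelihoods by exhaustive enumeration."""
    tips = {nd.index: alignment.row(nd.name) for nd in tree.tips()}
    out = np.empty(alignment.nsites)
    for s in range(alignment.nsites):
        codes = {i: int(row[s]) for i, row in tips.items()}
        per_cat = []
        for r in model.rates:
            P = {nd.index: model.transition_matrix(r * nd.length)
                 for nd in tree.branches()}
            per_cat.append(_site_joint(tree, codes, P, model.pi).sum())
        out[s] = np.log(np.mean(per_cat))
    return out


def enumeration_node_posterior(
    tree: Phylogeny, alignment: Alignment, model: ReplacementModel, node_name: str
) -> np.ndarray:
    """(nsites, 20) marginal posterior at one internal node by enumeration."""
    node = tree.find(node_name)
    internals = tree.internal_nodes()
    axis = {nd.index: i for i, nd in enumerate(internals)}
    target_axis = axis[node.index]
    tips = {nd.index: alignment.row(nd.name) for nd in tree.tips()}
    out = np.empty((alignment.nsites, 20))
    for s in range(alignment.nsites):
        codes = {i: int(row[s]) for i, row in tips.items()}
        marg = np.zeros(20)
        for r in model.rates:
            P = {nd.index: model.transition_matrix(r * nd.length)
                 for nd in tree.branches()}
            joint = _site_joint(tree, codes, P, model.pi)
            other = tuple(i for i in range(joint.ndim) if i != target_axis)
            marg += joint.sum(axis=other)
        out[s] = marg / marg.sum()
    return out


def random_small_tree(rng: np.random.Generator, ntips: int) -> Phylogeny:
    """Random rooted binary tree with uniform(0.02, 0.6) branch lengths."""
    from ancres.io import Node

    lineages = [Node(name=chr(ord("A") + i)) for i in range(ntips)]
    counter = 0
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        counter += 1
        parent = Node(name=f"i{counter}")
        for k in (j, i):
            child = lineages.pop(k)
            child.length = float(rng.uniform(0.02, 0.6))
            parent.add(child)
        lineages.append(parent)
    return Phylogeny(lineages[0])


def random_alignment(
    rng: np.random.Generator, names: list[str], nsites: int, gap_rate: float = 0.05
) -> Alignment:
    from ancres.io import AMINO_ACIDS

    rows = []
    for _ in names:
        chars = [AMINO_ACIDS[rng.integers(20)] for _ in range(nsites)]
        for k in range(nsites):
            if rng.random() < gap_rate:
                chars[k] = "-"
        rows.append("".join(chars))
    return Alignment.from_sequences(names, rows)
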