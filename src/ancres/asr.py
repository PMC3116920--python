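"""Marginal (empirical-Bayes) ancestral sequence reconstruction.

At fixed maximum-likelihood parameters, the posterior over the 20 amino
acids at an internal node and site is proportional to the equilibrium
frequency times the product of the conditional likelihoods of every
subtree hanging off that node — equivalently, the tree is rerooted at the
node and the pruning partials are read off there. Rate categories are
mixed by their per-site posterior weight. Reconstructions over several
candidate topologies are combined as a weighted average of posteriors,
the weights being the trees' posterior probabilities (supplied by the
user, or approximated from relative likelihoods).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AMINO_ACIDS, Alignment, Phylogeny
from .likelihood import PruningEngine
from .substitution_models import ReplacementModel


class ASRError(ValueError):
    pass


@dataclass
class AncestralReconstruction:
    """Per-site posterior state distributions at one ancestral node.

    ``pp`` has shape (nsites, 20) in ARNDCQEGHILKMFPSTWYV order; the ML
    sequence is the per-site argmax, ties broken alphabetically by
    one-letter code (deterministic).
    """

    node: str
    pp: np.ndarray

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if self.pp.ndim != 2 or self.pp.shape[1] != 20:
            raise ASRError(f"posterior matrix must be (nsites, 20), got {self.pp.shape}")
        if not np.allclose(self.pp.sum(axis=1), 1.0, atol=1e-8):
            raise ASRError("site posteriors must sum to one")

    @property
    def nsites(self) -> int:
        return self.pp.shape[0]

    @property
    def ml_indices(self) -> np.ndarray:
        # argmax over a column order sorted by letter => alphabetical ties
        order = np.argsort(list(AMINO_ACIDS), kind="stable")
        best = order[np.argmax(self.pp[:, order], axis=1)]
        return best

    @property
    def ml_sequence(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.ml_indices)

    @property
    def ml_pp(self) -> np.ndarray:
        """Posterior probability of the ML state at every site."""
        return self.pp.max(axis=1)

    @property
    def mean_pp(self) -> float:
        """Mean posterior probability of the ML state across sites."""
        return float(self.ml_pp.mean())


@dataclass
class TreeEnsemble:
    """Candidate topologies with normalized posterior weights."""

    trees: list[Phylogeny]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.trees) != len(w):
            raise ASRError("one weight per tree required")
        if (w < 0).any() or w.sum() <= 0:
            raise ASRError("weights must be non-negative and not all zero")
        self.weights = w / w.sum()

    @staticmethod
    def from_log_likelihoods(trees: list[Phylogeny], lnls: list[float]) -> "TreeEnsemble":
        """Approximate posterior weights from relative likelihoods
        (equal prior over the candidate topologies)."""
        lnls = np.asarray(lnls, dtype=float)
        w = np.exp(lnls - lnls.max())
        return TreeEnsemble(trees, w / w.sum())


def marginal_reconstruction(
    tree: Phylogeny,
    alignment: Alignment,
    model: ReplacementModel,
    node: str,
) -> AncestralReconstruction:
    """Empirical-Bayes marginal reconstruction at one internal node.

    The tree's branch lengths and the model's gamma shape are taken as
    given (fit them first with :func:`ancres.likelihood.optimize`).
    """
    nd = tree.find(node)
    if nd.is_tip:
        raise ASRError(f"node {node!r} is a tip; ancestral states live at internal nodes")
    engine = PruningEngine(tree, alignment, model)
    return AncestralReconstruction(node=node, pp=engine.node_posteriors(nd))


def combine_over_trees(
    ensemble: TreeEnsemble,
    alignment: Alignment,
    model: ReplacementModel,
    node_map: dict[int, str] | str,
) -> AncestralReconstruction:
    """Combine reconstructions across candidate trees by posterior weight.

    ``node_map`` names the homologous ancestral node in each tree (tree
    index -> label), or a single label shared by all trees. The combined
    posterior is the weight-averaged posterior, per site and state.
    """
    if isinstance(node_map, str):
        node_map = {i: node_map for i in range(len(ensemble.trees))}
    recons = []
    for i, (tree, w) in enumerate(zip(ensemble.trees, ensemble.weights)):
        if i not in node_map:
            raise ASRError(f"no node mapped for tree {i}")
        try:
            tree.find(node_map[i])
        except KeyError:
            raise ASRError(f"node {node_map[i]!r} missing from tree {i}") from None
        recons.append(marginal_reconstruction(tree, alignment, model, node_map[i]))
    sizes = {r.nsites for r in recons}
    if len(sizes) != 1:
        raise ASRError("trees reconstruct different numbers of sites")
    pp = np.zeros_like(recons[0].pp)
    for r, w in zip(recons, ensemble.weights):
        pp += w * r.pp
    return AncestralReconstruction(node=recons[0].node, pp=pp)


def alternate_states(
    recon: AncestralReconstruction, threshold: float = 0.20
) -> dict[int, list[tuple[str, float]]]:
    """Plausible alternate states: non-ML states with posterior strictly
    above ``threshold``. Keys are 1-based sites; sites with no alternates
    are omitted. Within a site, alternates are ordered by decreasing
    posterior."""
    if not 0.0 < threshold < 1.0:
        raise ASRError(f"threshold must be inside (0, 1), got {threshold}")
    ml = recon.ml_indices
    out: dict[int, list[tuple[str, float]]] = {}
    for s in range(recon.nsites):
        alts = [
            (AMINO_ACIDS[i], float(recon.pp[s, i]))
            for i in np.argsort(-recon.pp[s], kind="stable")
            if i != ml[s] and recon.pp[s, i] > threshold
        ]
        if alts:
            out[s + 1] = alts
    return out


@dataclass
class ComparisonReport:
    """Summary comparison of two reconstructions of the same ancestor."""

    n_sites: int
    n_differences: int
    fraction_differing: float
    mean_pp_a: float
    mean_pp_b: float
    n_certain_a: int  # sites at posterior 1.00 (within printing precision)
    n_certain_b: int
    n_ambiguous_a: int  # sites with at least one alternate state
    n_ambiguous_b: int


def compare_reconstructions(
    recon_a: AncestralReconstruction,
    recon_b: AncestralReconstruction,
    alt_threshold: float = 0.20,
    certain_tol: float = 5e-3,
) -> ComparisonReport:
    """Contrast two reconstructions: ML-state differences, mean posterior,
    sites reconstructed with effectively 100% posterior, and ambiguous
    sites (those carrying at least one plausible alternate state)."""
    if recon_a.nsites != recon_b.nsites:
        raise ASRError(
            f"reconstruction lengths differ: {recon_a.nsites} vs {recon_b.nsites}"
        )
    diff = int((recon_a.ml_indices != recon_b.ml_indices).sum())
    return ComparisonReport(
        n_sites=recon_a.nsites,
        n_differences=diff,
        fraction_differing=diff / recon_a.nsites,
        mean_pp_a=recon_a.mean_pp,
        mean_pp_b=recon_b.mean_pp,
        n_certain_a=int((recon_a.ml_pp >= 1.0 - certain_tol).sum()),
        n_certain_b=int((recon_b.ml_pp >= 1.0 - certain_tol).sum()),
        n_ambiguous_a=len(alternate_states(recon_a, alt_threshold)),
        n_ambiguous_b=len(alternate_states(recon_b, alt_threshold)),
    )
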