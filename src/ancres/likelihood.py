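"""Phylogenetic likelihood by Felsenstein pruning, with branch/shape
optimization and the two likelihood-ratio procedures the analysis uses.

The engine computes per-site likelihoods on a rooted tree under a
reversible replacement model with K discrete-gamma rate categories,
averaging categories with equal prior weight. Gap and 'X' characters
contribute all-ones tip partials (missing data). Per-node rescaling in log
space keeps partials in range on large trees. A complementary "up" pass
gives, for every branch, the likelihood as a cheap function of that single
branch length; coordinate-wise optimization and marginal ancestral
posteriors are both built on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .io import Alignment, Node, Phylogeny
from .substitution_models import ReplacementModel

BL_MIN, BL_MAX = 1e-8, 20.0
ALPHA_MIN, ALPHA_MAX = 0.02, 100.0


class PruningError(ValueError):
    pass


@dataclass
class LikelihoodResult:
    """Fitted likelihood summary: total and per-site lnL plus parameters."""

    lnl: float
    site_lnl: np.ndarray
    alpha: float
    lengths: dict[int, float]  # node index -> branch length above that node
    converged: bool = True
    n_cycles: int = 0
    tree: Phylogeny | None = None


@dataclass
class LRTResult:
    """Nested likelihood-ratio comparison between two branch-length models."""

    lnl_free: float
    lnl_constrained: float
    df: int
    p_value: float = field(init=False)
    statistic: float = field(init=False)
    mixture_null: bool = False

    def __post_init__(self) -> None:
        self.statistic = 2.0 * (self.lnl_free - self.lnl_constrained)
        stat = max(self.statistic, 0.0)
        if self.mixture_null:
            # boundary null: the constrained value sits on the edge of the
            # parameter space, so the statistic is a 50:50 mix of a point
            # mass at zero and a chi-square with one degree of freedom
            self.p_value = 1.0 if stat == 0.0 else 0.5 * float(chi2.sf(stat, 1))
        else:
            self.p_value = float(chi2.sf(stat, self.df))

    @property
    def support(self) -> float:
        """Branch support in the 1 - p form."""
        return 1.0 - self.p_value


class PruningEngine:
    """Pruning-algorithm likelihood on one (tree, alignment, model) binding.

    Site patterns are compressed to unique columns. All partial arrays are
    shaped (K, n_patterns, 20) and carry an additive log-scale array of
    shape (K, n_patterns).
    """

    def __init__(self, tree: Phylogeny, alignment: Alignment, model: ReplacementModel):
        tree.bind(alignment)
        self.tree = tree
        self.alignment = alignment
        self.model = model
        codes = np.stack(
            [alignment.row(nd.name) for nd in tree.tips()]
        )  # (ntips, nsites)
        self.patterns, self.pattern_index, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True
        )
        self.weights = counts.astype(float)
        self.n_patterns = self.patterns.shape[1]
        self._tip_row = {nd.index: i for i, nd in enumerate(tree.tips())}
        self.lengths = np.array([nd.length for nd in tree.nodes])
        self._cache_valid = False

    # -- core passes --------------------------------------------------------

    def _tip_partial(self, node_index: int) -> np.ndarray:
        codes = self.patterns[self._tip_row[node_index]]
        part = np.zeros((self.n_patterns, 20))
        obs = codes >= 0
        part[obs, codes[obs]] = 1.0
        part[~obs, :] = 1.0
        K = self.model.K
        return np.broadcast_to(part, (K, self.n_patterns, 20)).copy()

    @staticmethod
    def _rescale(part: np.ndarray, scale: np.ndarray) -> None:
        mx = part.max(axis=2)
        safe = np.where(mx > 0, mx, 1.0)
        part /= safe[:, :, None]
        with np.errstate(divide="ignore"):
            scale += np.where(mx > 0, np.log(safe), -np.inf)

    def _down_pass(self) -> None:
        """Tipward partials for every node, in postorder."""
        K, S = self.model.K, self.n_patterns
        n = len(self.tree.nodes)
        self.down = [None] * n
        self.down_scale = [None] * n
        self.msg = [None] * n  # P(t_c) @ down_c, child -> parent message
        self.P = [None] * n
        for nd in self.tree.nodes:
            i = nd.index
            if nd.is_tip:
                part = self._tip_partial(i)
                scale = np.zeros((K, S))
            else:
                part = np.ones((K, S, 20))
                scale = np.zeros((K, S))
                for ch in nd.children:
                    part *= self.msg[ch.index]
                    scale += self.down_scale[ch.index]
                self._rescale(part, scale)
            self.down[i] = part
            self.down_scale[i] = scale
            if nd is not self.tree.root:
                self.P[i] = self.model.transition_matrices(self.lengths[i])
                self.msg[i] = np.einsum("kij,ksj->ksi", self.P[i], part)

    def _up_pass(self) -> None:
        """Rootward partials: up[i] is the likelihood of everything outside
        node i's subtree, as seen at node i's parent, with the root prior
        folded in. up_node[i] moves that through branch i down to node i."""
        K, S = self.model.K, self.n_patterns
        n = len(self.tree.nodes)
        self.up = [None] * n  # at the parent, excluding subtree i
        self.up_scale = [None] * n
        self.up_node = [None] * n  # at node i itself
        self.up_node_scale = [None] * n
        root = self.tree.root
        self.up_node[root.index] = np.broadcast_to(
            self.model.pi, (K, S, 20)
        ).copy()
        self.up_node_scale[root.index] = np.zeros((K, S))
        for nd in reversed(self.tree.nodes):  # preorder
            if nd.is_tip:
                continue
            base = self.up_node[nd.index]
            base_scale = self.up_node_scale[nd.index]
            for ch in nd.children:
                part = base.copy()
                scale = base_scale.copy()
                for sib in nd.children:
                    if sib is not ch:
                        part = part * self.msg[sib.index]
                        scale = scale + self.down_scale[sib.index]
                self._rescale(part, scale)
                self.up[ch.index] = part
                self.up_scale[ch.index] = scale
                j = ch.index
                self.up_node[j] = np.einsum("kij,ksi->ksj", self.P[j], part)
                self.up_node_scale[j] = scale.copy()

    def _refresh(self) -> None:
        if not self._cache_valid:
            self._down_pass()
            self._up_pass()
            self._cache_valid = True

    def set_length(self, node_index: int, t: float) -> None:
        self.lengths[node_index] = t
        self._cache_valid = False

    def set_lengths(self, lengths: np.ndarray) -> None:
        self.lengths = np.asarray(lengths, dtype=float).copy()
        self._cache_valid = False

    def set_model(self, model: ReplacementModel) -> None:
        self.model = model
        self._cache_valid = False

    # -- likelihood ---------------------------------------------------------

    def site_log_likelihoods(self) -> np.ndarray:
        """Per-site (not per-pattern) log-likelihoods."""
        self._refresh()
        r = self.tree.root.index
        raw = np.einsum("j,ksj->ks", self.model.pi, self.down[r])
        with np.errstate(divide="ignore"):
            logL_k = np.log(raw) + self.down_scale[r]  # (K, S)
        m = logL_k.max(axis=0)
        pat = m + np.log(np.exp(logL_k - m[None, :]).mean(axis=0))
        return pat[self.pattern_index]

    def log_likelihood(self) -> float:
        self._refresh()
        r = self.tree.root.index
        raw = np.einsum("j,ksj->ks", self.model.pi, self.down[r])
        with np.errstate(divide="ignore"):
            logL_k = np.log(raw) + self.down_scale[r]
        m = logL_k.max(axis=0)
        pat = m + np.log(np.exp(logL_k - m[None, :]).mean(axis=0))
        return float(pat @ self.weights)

    def branch_lnl_function(self, node_index: int):
        """Return lnL(t) for one branch, cheap per evaluation.

        Uses the cached up/down partials at the current lengths; only the
        transition matrix of the focal branch is recomputed per call.
        """
        self._refresh()
        up, up_scale = self.up[node_index], self.up_scale[node_index]
        down, down_scale = self.down[node_index], self.down_scale[node_index]
        scale = up_scale + down_scale
        w, K = self.weights, self.model.K

        def lnl(t: float) -> float:
            P = self.model.transition_matrices(t)
            raw = np.einsum("ksi,kij,ksj->ks", up, P, down)
            with np.errstate(divide="ignore"):
                logL_k = np.log(np.maximum(raw, 0.0)) + scale
            m = logL_k.max(axis=0)
            pat = m + np.log(np.exp(logL_k - m[None, :]).mean(axis=0))
            return float(pat @ w)

        return lnl

    def node_posteriors(self, node: Node) -> np.ndarray:
        """Marginal posterior over the 20 states at an internal node,
        shape (nsites, 20); rate categories mixed by their per-site
        posterior weight."""
        if node.is_tip:
            raise PruningError("marginal reconstruction is defined at internal nodes")
        self._refresh()
        i = node.index
        joint = self.up_node[i] * self.down[i]  # (K, S, 20)
        scale = self.up_node_scale[i] + self.down_scale[i]
        m = scale.max(axis=0)
        joint = joint * np.exp(scale - m[None, :])[:, :, None]
        summed = joint.sum(axis=0)  # (S, 20)
        pp = summed / summed.sum(axis=1, keepdims=True)
        return pp[self.pattern_index]


def log_likelihood(
    tree: Phylogeny, alignment: Alignment, model: ReplacementModel
) -> LikelihoodResult:
    """Alignment log-likelihood at the tree's current branch lengths."""
    engine = PruningEngine(tree, alignment, model)
    site = engine.site_log_likelihoods()
    return LikelihoodResult(
        lnl=float(site.sum()),
        site_lnl=site,
        alpha=model.alpha,
        lengths={nd.index: nd.length for nd in tree.branches()},
        tree=tree,
    )


def _optimize_engine(
    engine: PruningEngine,
    optimize_alpha: bool,
    shared: list[list[int]] | None = None,
    fixed: dict[int, float] | None = None,
    max_cycles: int = 100,
    lnl_tol: float = 1e-6,
    xtol: float = 1e-8,
) -> tuple[float, float, bool, int]:
    """Coordinate-wise branch-length (and alpha) optimization in place.

    ``shared`` lists groups of node indices constrained to one common
    length; ``fixed`` pins node indices to a given length.
    """
    fixed = fixed or {}
    shared = shared or []
    in_group = {i for g in shared for i in g}
    for i, t in fixed.items():
        engine.set_length(i, t)
    free_nodes = [
        nd.index
        for nd in engine.tree.branches()
        if nd.index not in fixed and nd.index not in in_group
    ]
    prev = engine.log_likelihood()
    alpha = engine.model.alpha
    converged = False
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        for i in free_nodes:
            f = engine.branch_lnl_function(i)
            res = minimize_scalar(
                lambda t: -f(t),
                bounds=(BL_MIN, BL_MAX),
                method="bounded",
                options={"xatol": xtol},
            )
            if f(res.x) >= f(engine.lengths[i]):
                engine.set_length(i, float(res.x))
        for group in shared:
            def g(t: float) -> float:
                for i in group:
                    engine.set_length(i, t)
                return engine.log_likelihood()

            cur = engine.lengths[group[0]]
            res = minimize_scalar(
                lambda t: -g(t),
                bounds=(BL_MIN, BL_MAX),
                method="bounded",
                options={"xatol": xtol},
            )
            best = float(res.x) if g(res.x) >= g(cur) else float(cur)
            for i in group:
                engine.set_length(i, best)
        if optimize_alpha:
            base = engine.model

            def h(a: float) -> float:
                engine.set_model(base.with_alpha(a))
                return engine.log_likelihood()

            res = minimize_scalar(
                lambda a: -h(a),
                bounds=(ALPHA_MIN, ALPHA_MAX),
                method="bounded",
                options={"xatol": 1e-4},
            )
            if h(res.x) >= h(alpha):
                alpha = float(res.x)
            engine.set_model(base.with_alpha(alpha))
        cur = engine.log_likelihood()
        if cur - prev < lnl_tol:
            prev = max(cur, prev)
            converged = True
            break
        prev = cur
    if not converged:
        warnings.warn(
            f"branch-length optimization did not converge in {max_cycles} cycles"
        )
    return prev, alpha, converged, cycle


def optimize(
    tree: Phylogeny,
    alignment: Alignment,
    model: ReplacementModel,
    optimize_alpha: bool = True,
    shared: list[list[str]] | None = None,
    fixed: dict[str, float] | None = None,
    max_cycles: int = 100,
) -> LikelihoodResult:
    """Maximum-likelihood branch lengths (and optionally gamma shape).

    Branch groups in ``shared`` (lists of node labels) are constrained to a
    single common length; ``fixed`` pins labelled branches. The input tree
    is not modified; the fitted copy is returned on the result.
    """
    work = tree.copy()
    shared_idx = [[work.find(n).index for n in grp] for grp in (shared or [])]
    fixed_idx = {work.find(n).index: t for n, t in (fixed or {}).items()}
    engine = PruningEngine(work, alignment, model)
    lnl, alpha, converged, cycles = _optimize_engine(
        engine, optimize_alpha, shared_idx, fixed_idx, max_cycles
    )
    for nd in work.branches():
        nd.length = float(engine.lengths[nd.index])
    engine.set_model(model.with_alpha(alpha))
    site = engine.site_log_likelihoods()
    return LikelihoodResult(
        lnl=float(site.sum()),
        site_lnl=site,
        alpha=alpha,
        lengths={nd.index: nd.length for nd in work.branches()},
        converged=converged,
        n_cycles=cycles,
        tree=work,
    )


def branch_support(
    tree: Phylogeny,
    alignment: Alignment,
    model: ReplacementModel,
    branch: str,
    optimize_alpha: bool = False,
) -> LRTResult:
    """Support for an internal branch by the branch-collapse LRT.

    The constrained model pins the branch at zero length and re-optimizes
    everything else; the statistic is referred to the boundary-case
    half-and-half mixture of a point mass at zero and chi-square(1).
    Support is reported as 1 - p.
    """
    node = tree.find(branch)
    if node.is_tip:
        raise PruningError("branch support is defined for internal branches")
    fixed = {branch: BL_MIN}
    if node.parent is tree.root and len(tree.root.children) == 2:
        # degree-two root: the unrooted edge under test is split across the
        # two root children (pulley principle), so both must collapse
        sibling = next(c for c in tree.root.children if c is not node)
        if sibling.name is None:
            raise PruningError(
                "cannot collapse a root-adjacent branch whose sibling is unlabelled"
            )
        fixed[sibling.name] = BL_MIN
    free = optimize(tree, alignment, model, optimize_alpha=optimize_alpha)
    constrained = optimize(
        tree, alignment, model, optimize_alpha=optimize_alpha, fixed=fixed,
    )
    return LRTResult(
        lnl_free=free.lnl, lnl_constrained=constrained.lnl, df=1, mixture_null=True
    )


def rate_equality_lrt(
    tree: Phylogeny,
    alignment: Alignment,
    model: ReplacementModel,
    branch_a: str,
    branch_b: str,
    optimize_alpha: bool = False,
) -> LRTResult:
    """Test whether two branches share a common length (equal-rate test).

    Free model: every branch length independent. Constrained model: the two
    named branches share one length parameter, all others free. Because the
    two branches span the same time interval, a shared length means a
    shared substitution rate; the statistic is referred to chi-square with
    one degree of freedom.
    """
    if branch_a == branch_b:
        raise PruningError("the two branches must be distinct")
    tree.find(branch_a), tree.find(branch_b)  # raise early if unknown
    free = optimize(tree, alignment, model, optimize_alpha=optimize_alpha)
    constrained = optimize(
        tree, alignment, model,
        optimize_alpha=optimize_alpha, shared=[[branch_a, branch_b]],
    )
    return LRTResult(lnl_free=free.lnl, lnl_constrained=constrained.lnl, df=1)


def mixture_p_value(statistic: float) -> float:
    """Tail probability of the half chi-square(0) / half chi-square(1) mix."""
    if statistic <= 0:
        return 1.0
    return 0.5 * float(chi2.sf(statistic, 1))


def reroot_at_edge(tree: Phylogeny, below: str, fraction: float = 0.5) -> Phylogeny:
    """Reroot a copy of ``tree`` on the branch above node ``below``.

    ``fraction`` places the new root that far down the branch from the
    parent. Under a reversible model the likelihood is invariant to this
    operation (the pulley principle), which the test suite exercises.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    work = tree.copy()
    child = work.find(below)
    if child is work.root:
        raise ValueError("cannot reroot on the root's (absent) branch")
    parent = child.parent
    L = child.length
    parent.children.remove(child)
    child.parent = None

    # reverse the parent chain so `parent` heads the remainder of the tree;
    # the branch that used to hang node i below node i+1 now hangs i+1
    # below i, keeping its original length
    chain: list[Node] = []
    cur: Node | None = parent
    while cur is not None:
        chain.append(cur)
        cur = cur.parent
    orig_lengths = [nd.length for nd in chain]
    for nd in chain:
        nd.parent = None
    for i in range(len(chain) - 1):
        lower, upper = chain[i], chain[i + 1]
        upper.children.remove(lower)
        lower.children.append(upper)
        upper.parent = lower
        upper.length = orig_lengths[i]
        upper.length_missing = False
    rest = parent

    new_root = Node(name=None)
    child.length = (1.0 - fraction) * L
    rest.length = fraction * L
    child.length_missing = rest.length_missing = False
    new_root.add(child)
    new_root.add(rest)

    # splice out degree-two nodes (the old root becomes one), merging the
    # two incident branch lengths
    stack = [new_root]
    while stack:
        nd = stack.pop()
        for idx, c in enumerate(list(nd.children)):
            while len(c.children) == 1:
                only = c.children[0]
                only.length += c.length
                only.parent = nd
                nd.children[nd.children.index(c)] = only
                c = only
        stack.extend(nd.children)
    return Phylogeny(new_root)
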