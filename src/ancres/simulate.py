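"""Synthetic data generators with known ground truth.

Every stage of the pipeline is testable without external data: sequences
are evolved forward along a known tree under the package's own
replacement model (so true ancestral states are retained), reporter-assay
curves are drawn from a four-parameter logistic with Gaussian noise, and
stability/sensitivity point sets come from a known line. All generators
are deterministic given (spec, seed).

Defaults are sized like the real study: a 12-taxon tree with 240
alignment sites (the scale of a nuclear-receptor ligand-binding domain),
gamma shape 1 with four rate categories, triplicate responses on a
1e-12 to 1e-5 M half-log dose grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .dose_response import DoseResponseDataset, hill_curve
from .io import AMINO_ACIDS, Alignment, Node, Phylogeny
from .substitution_models import ReplacementModel, build_model

DEFAULT_DOSE_GRID = tuple(10.0 ** e for e in np.arange(-12.0, -4.5, 0.5))


@dataclass
class SimulationSpec:
    """Ground-truth parameters for all generators; seed fixes everything."""

    seed: int = 0
    # alignment / tree
    ntaxa: int = 12
    nsites: int = 240
    branch_length_mean: float = 0.15
    alpha: float = 1.0
    K: int = 4
    matrix: str = "JTT"
    # dose-response truth
    logec50: float = -9.0
    basal: float = 100.0
    maximum: float = 2000.0
    hill_slope: float = 1.0
    noise_sd_fraction: float = 0.05  # of the basal..max range
    replicates: int = 3
    dose_grid: tuple[float, ...] = DEFAULT_DOSE_GRID
    # stability-line truth
    stability_slope: float = 0.5
    stability_intercept: float = -10.870
    stability_noise_sd: float = 0.3
    stability_n: int = 10

    def describe(self) -> dict:
        return asdict(self)


def _rng(spec: SimulationSpec, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, salt]))


def random_tree(spec: SimulationSpec, rng: np.random.Generator | None = None) -> Phylogeny:
    """Random rooted binary tree over t1..tN with exponential branch lengths.

    Built by successive random coalescence of lineages; internal nodes are
    labelled n1, n2, ... in coalescence order (root label last).
    """
    rng = rng if rng is not None else _rng(spec, salt=1)
    lineages: list[Node] = [Node(name=f"t{i+1}") for i in range(spec.ntaxa)]
    counter = 0
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        counter += 1
        parent = Node(name=f"n{counter}")
        for k in (j, i):  # pop larger index first
            child = lineages.pop(k)
            child.length = float(rng.exponential(spec.branch_length_mean))
            parent.children.insert(0, child)
            child.parent = parent
        lineages.append(parent)
    return Phylogeny(lineages[0])


def simulate_alignment(
    spec: SimulationSpec,
    tree: Phylogeny | None = None,
    model: ReplacementModel | None = None,
) -> tuple[Alignment, dict[str, str], Phylogeny]:
    """Evolve sequences along a tree; return (alignment, true ancestors, tree).

    Root states are drawn from the equilibrium frequencies, each site gets
    one of the K rate categories uniformly, and states evolve down every
    branch by the model's transition probabilities. True states at every
    internal node are returned keyed by node label.
    """
    rng = _rng(spec, salt=2)
    if tree is None:
        tree = random_tree(spec, rng)
    if model is None:
        model = build_model(spec.matrix, alpha=spec.alpha, K=spec.K)
    nsites = spec.nsites
    categories = rng.integers(0, model.K, size=nsites)
    states: dict[int, np.ndarray] = {}
    root = tree.root
    states[root.index] = rng.choice(20, size=nsites, p=model.pi)
    for nd in reversed(tree.nodes):  # preorder: parents before children
        if nd is root:
            continue
        P = model.transition_matrices(nd.length)  # (K, 20, 20)
        parent_states = states[nd.parent.index]
        child = np.empty(nsites, dtype=np.int64)
        # vectorized multinomial draw via the inverse-CDF trick
        probs = P[categories, parent_states, :]  # (nsites, 20)
        u = rng.random(nsites)
        child = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        np.clip(child, 0, 19, out=child)
        states[nd.index] = child
    to_seq = np.array(list(AMINO_ACIDS))
    names, rows = [], []
    for tip in tree.tips():
        names.append(tip.name)
        rows.append("".join(to_seq[states[tip.index]]))
    ancestors = {
        nd.name: "".join(to_seq[states[nd.index]])
        for nd in tree.internal_nodes()
        if nd.name
    }
    return Alignment.from_sequences(names, rows), ancestors, tree


def simulate_dose_response(
    spec: SimulationSpec, receptor: str = "sim", hormone: str = "sim-hormone"
) -> DoseResponseDataset:
    """Triplicate logistic responses plus vehicle wells with Gaussian noise."""
    rng = _rng(spec, salt=3)
    grid = np.asarray(spec.dose_grid, dtype=float)
    conc = np.repeat(grid, spec.replicates)
    clean = hill_curve(
        np.log10(conc), spec.basal, spec.maximum, spec.logec50, spec.hill_slope
    )
    sd = spec.noise_sd_fraction * (spec.maximum - spec.basal)
    response = clean + rng.normal(0.0, sd, size=clean.shape) if sd > 0 else clean
    vehicle = spec.basal + (
        rng.normal(0.0, sd, size=spec.replicates) if sd > 0 else 0.0
    )
    return DoseResponseDataset(
        receptor=receptor,
        hormone=hormone,
        conc=conc,
        response=response,
        vehicle=np.atleast_1d(vehicle),
    )


def simulate_stability_points(spec: SimulationSpec) -> dict[str, tuple[float, float]]:
    """(ddG, logEC50) pairs on a known line with Gaussian noise in y.

    ddG values are drawn from a mixture emulating the empirical shape of
    mutational stability effects: mostly small perturbations around zero
    with a destabilizing tail.
    """
    rng = _rng(spec, salt=4)
    n = spec.stability_n
    small = rng.normal(0.25, 0.35, size=n)
    tail = rng.gamma(2.0, 1.25, size=n)
    ddg = np.where(rng.random(n) < 0.7, small, tail)
    y = (
        spec.stability_slope * ddg
        + spec.stability_intercept
        + (rng.normal(0.0, spec.stability_noise_sd, size=n)
           if spec.stability_noise_sd > 0 else 0.0)
    )
    return {f"m{i+1}": (float(ddg[i]), float(y[i])) for i in range(n)}


def simulate_ddg_runs(
    spec: SimulationSpec, n_runs: int = 5, run_sd: float = 0.1
) -> "np.ndarray":
    """Per-run ddG table rows for the stability schema, shape (n, n_runs)."""
    rng = _rng(spec, salt=5)
    points = simulate_stability_points(spec)
    means = np.array([v[0] for v in points.values()])
    return means[:, None] + rng.normal(0.0, run_sd, size=(len(means), n_runs))
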