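# Methods

This note documents the models implemented in `ancres`, the choices made
where conventions differ, and what the synthetic-data generators do and do
not emulate.

## Replacement model

The substitution process is a reversible continuous-time Markov chain on
the 20 amino acids. Given symmetric exchangeabilities S and equilibrium
frequencies π, the generator is Q = S·diag(π) with diagonal entries set so
rows sum to zero, rescaled so −Σᵢ πᵢQᵢᵢ = 1. With that normalization a
branch length is the expected number of substitutions per site. Transition
matrices P(t) = exp(Qt) come from one symmetric eigendecomposition of
diag(√π)·Q·diag(1/√π), so arbitrary t are cheap and exact to machine
precision (cross-checked against scaling-and-squaring in the tests).

The packaged matrix is JTT (Jones–Taylor–Thornton 1992), stored as plain
text (19-row lower triangle plus 20 frequencies, residue order
ARNDCQEGHILKMFPSTWYV) in `src/ancres/data/jtt.dat`. Frequencies default to
the model's own; a +F mode counts them from the alignment with a 0.5
pseudocount.

Among-site rate variation uses Yang's discrete-gamma approximation: K
equal-probability categories (default K = 4), category rate = the mean of
the gamma(α, rate α) density on its quantile bin, computed in closed form
from regularized incomplete gamma functions. The mean convention (rather
than the median) is used because it preserves Σ r_k/K = 1 exactly; the two
conventions differ numerically and the choice is stated here for that
reason. α > 0 is a free parameter, estimated by maximum likelihood when
requested.

## Likelihood, optimization, and rate tests

Per-site likelihoods are computed by the pruning algorithm over unique
site patterns, averaging rate categories with equal prior weight. Gap and
'X' characters are missing data (all-ones tip partials). Each node's
partials are rescaled to a maximum of one with the log factor accumulated
per category and pattern, so underflow cannot occur on large trees. A
complementary rootward ("up") pass yields, for any branch, the likelihood
as a function of that branch length alone at O(sites·20²) per evaluation;
the same quantities give marginal ancestral posteriors.

Branch lengths are optimized coordinate-wise with bounded derivative-free
scalar minimization (bounds [1e−8, 20], parameter tolerance 1e−8), cycling
over branches, then α (bounds [0.02, 100]), until the cycle improves lnL
by less than 1e−6 or 100 cycles elapse; non-convergence is flagged, never
silent. Proposals are only accepted when they do not decrease lnL, making
the cycle monotone.

Two likelihood-ratio procedures are built on this:

* **Branch support.** The constrained model pins the branch at zero
  (lower bound) and re-optimizes everything else. Because zero lies on the
  boundary of the parameter space, the statistic is referred to the
  ½χ²₀ + ½χ²₁ mixture; support is reported as 1 − p. When the tested
  branch is a child of a degree-two root, the unrooted edge is split
  across the two root children (pulley principle), so both are pinned.
  This collapse-based test targets the same question as the common
  rearrangement-based approximate LRT but needs no tree-rearrangement
  machinery; that substitution is a deliberate design choice.
* **Equal-rate test.** Two branches that span the same time interval are
  constrained to one shared length; since length = rate × time, equal
  lengths mean equal rates. The statistic is referred to χ² with 1 df
  (p = 0.090 at statistic 2.874).

Topologies are never searched: trees are inputs.

## Ancestral reconstruction

Reconstruction is empirical-Bayes marginal at fixed ML parameters:
posterior ∝ π × (product of subtree likelihoods at the node), rate
categories mixed by per-site posterior weight. Branch-length uncertainty
is not integrated over, matching standard practice. ML-state ties break
alphabetically by one-letter code (deterministic). Reconstructions over
several candidate topologies are combined as the weight-averaged posterior
per site; weights are user-supplied tree posterior probabilities, with a
helper that approximates them from relative likelihoods under an equal
topology prior. Alternate states are non-ML states with posterior strictly
greater than the threshold (default 0.20); the strict inequality matters
at the boundary and is tested. Gap placement in ancestors is out of scope:
posteriors are always over the 20 residues.

Reconstruction comparison reports ML-sequence differences, mean posterior
of the ML states, sites at effectively 100% posterior (within 5e−3, i.e.
printing precision), and ambiguous sites (≥1 alternate).

## Candidate-substitution screen

Substitutions between two sequences are labelled A<site>B with 1-based
sites (position 1 = first residue of the LBD alignment, so labels align
with mutant names like V43A). The filter cascade: (1) drop substitutions
whose derived state is shared with an independent reconstruction of the
same ancestor; (2) partition the rest into biochemically conservative vs
radical; (3) flag ligand-contacting positions (an external structural
annotation; the packaged fixture lists site 36). The final partition is
order-independent; every input substitution appears exactly once with its
fate.

The conservative rule defaults to BLOSUM62 score ≥ +1, which classifies
D/E, I/L, K/R and S/T as conservative and V/A, R/H and C/S as radical —
the behaviour required of the worked pairs — and can be replaced by an
explicit pair list. Contact shells are never computed from coordinates
here.

## Dose-response

The four-parameter logistic is fit by trust-region nonlinear least squares
over all replicate points in log₁₀-molar dose space. Initialisation: basal
and max at the extreme mean responses, logEC50 at the mid-response
concentration, slope 1. The Hill slope is free within [0.3, 5] by default
(the fitting software used for the original measurements is not documented
at that level), with an option to fix it; the mode is recorded on the fit.
SE(logEC50) is the asymptotic value from the Jacobian at the optimum.
Vehicle (zero-concentration) wells are excluded from the logistic and used
as the fold-activation reference; when absent, the fitted basal stands in
and the fit says so. Degenerate designs — flat responses, or a fitted
EC50 far outside the sampled dose range — are flagged unreliable rather
than reported bare.

The nonresponder rule is interpreted as: predicted activation at 1 µM
below 2-fold over vehicle. The alternative reading (EC50 beyond 1 µM as a
separate criterion) is obtainable by changing `conc_limit`/`fold_limit`.
Fold change is 10^(logEC50_x − logEC50_ref), tabulated at one decimal.

## Stability–sensitivity regression

ΔΔG values are inputs (means ± sample SD over prediction runs, default
five); the energy function itself is out of scope. Exclusions (e.g.
prediction failures, gap-bordering sites, ligand-contacting sites) are
configured by label, always carry a reason, and are always listed in
output. The regression of logEC50 on mean ΔΔG has two modes: plain OLS
with the unmutated reference included as the point (0, logEC50_ref) —
the default — or a line constrained through that reference. In anchored
mode r² is computed about the reference point (1 − SSres/Σ(y−y₀)²), since
the usual mean-centred definition does not apply to a constrained fit;
in OLS mode r² equals the squared Pearson correlation. The ΔΔG
distribution is emitted as a histogram with configurable bin width
(default 0.5 kcal/mol).

## Synthetic data

Generators are deterministic given (spec, seed); one seed sequence is
salted per generator so the alignment, dose-response and stability draws
are independent. Defaults describe a study-scale problem: 12 taxa, 240
sites (LBD scale), α = 1 with K = 4, random coalescent-style trees with
exponential branch lengths (mean 0.15 substitutions/site); triplicate
responses on a 10⁻¹²–10⁻⁵ M half-log grid with Gaussian noise at 5% of
the response range; 10 stability points on a line of slope 0.5 through
(0, −10.870) with y-noise SD 0.3 and ΔΔG drawn from a mixture (70% small
effects near zero, 30% destabilizing gamma tail) emulating the empirically
observed shape of mutational stability effects.

What the simulations do **not** emulate: indels (ancestors are gap-free),
alignment error, model misspecification (data are generated under the
fitted model family), plate effects or heteroscedastic assay noise, and
correlated errors between ΔΔG runs. Passing recovery and calibration tests
therefore demonstrates internal correctness and statistical calibration
under the assumed models, not robustness to violations of them.

## Problem sizes in the checks

The oracle comparisons use exhaustive enumeration over all internal-state
assignments, feasible to five tips, on 50 random trees with 10-site
alignments. Reconstruction calibration pools internal nodes over repeated
12-taxon/240-site simulations until at least 500 sites exceed posterior
0.95. The rate-test type-I error uses 500 replicates of a four-taxon,
100-site, single-rate-category configuration — small enough to fit a free
and a constrained model a thousand times while leaving the binomial
tolerance at ±3 standard errors meaningful. Dose-response bias uses 200
replicates; regression slope recovery uses 500.

## Known limitations

* Branch-length SEs are not reported by the optimizer (curvature-based
  SEs are computed in the tests where needed).
* The branch-support test refits all other branches per tested branch;
  on large trees this is O(branches²) per support profile.
* Tree weights for multi-topology reconstruction are taken as given; the
  likelihood-based helper assumes an equal prior over the supplied
  topologies only.
* The pipeline's incremental re-execution is checksum-based at stage
  granularity, not a full dependency graph.
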