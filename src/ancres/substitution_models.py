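"""Reversible amino-acid replacement models with discrete-gamma rate classes.

The model is the standard general time-reversible CTMC on the 20 amino
acids: a symmetric exchangeability matrix S and equilibrium frequencies pi
give the rate matrix Q = S.diag(pi), with the diagonal set so rows sum to
zero and the whole matrix rescaled so the expected substitution rate at
stationarity is one. Branch lengths are then expected substitutions per
site. Among-site rate variation uses Yang's discrete-gamma approximation:
K equal-probability categories whose relative rate is the mean of the
gamma(alpha, rate=alpha) density on that quantile bin.

The packaged JTT matrix (Jones, Taylor & Thornton 1992) is the default; its
exchangeabilities and frequencies ship as a documented plain-text data file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.special import gammainc, gammaincinv

from .io import AMINO_ACIDS, Alignment

N_STATES = 20


class ModelError(ValueError):
    pass


def load_exchangeability_data(name_or_path: str = "JTT") -> tuple[np.ndarray, np.ndarray]:
    """Load (S, pi) from a packaged matrix name or a PAML-style .dat file.

    Layout: 19 lines with the lower triangle of S (rows 2..20), then the 20
    equilibrium frequencies. Lines starting with '#' are comments. Residue
    order is ARNDCQEGHILKMFPSTWYV.
    """
    if name_or_path.upper() == "JTT":
        text = (resources.files("ancres") / "data" / "jtt.dat").read_text()
    else:
        text = Path(name_or_path).read_text()
    rows = [
        [float(x) for x in line.split()]
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    tri, freqs = rows[:-1], np.asarray(rows[-1], dtype=float)
    if len(tri) != N_STATES - 1 or any(len(r) != i + 1 for i, r in enumerate(tri)):
        raise ModelError("malformed exchangeability file: expected 19 triangle rows")
    if freqs.shape != (N_STATES,):
        raise ModelError("malformed exchangeability file: expected 20 frequencies")
    S = np.zeros((N_STATES, N_STATES))
    for i, row in enumerate(tri, start=1):
        S[i, : len(row)] = row
    S = S + S.T
    return S, freqs


def discrete_gamma_rates(alpha: float, K: int) -> np.ndarray:
    """Relative rates of K equal-probability discrete-gamma categories.

    Each category's rate is the conditional mean of gamma(alpha, rate=alpha)
    on the quantile interval ((k-1)/K, k/K]; the mean-one normalisation
    Sum r_k / K = 1 holds exactly by construction.
    """
    if alpha <= 0:
        raise ModelError(f"gamma shape must be positive, got {alpha}")
    if K < 1:
        raise ModelError(f"need at least one rate category, got {K}")
    if K == 1:
        return np.ones(1)
    # bin edges on the gamma(alpha, scale=1/alpha) scale
    probs = np.arange(1, K) / K
    edges = gammaincinv(alpha, probs) / alpha
    edges = np.concatenate([[0.0], edges, [np.inf]])
    # integral of x * f(x) over a bin equals the gamma(alpha+1) CDF increment
    upper = gammainc(alpha + 1, alpha * edges[1:])
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    return K * (upper - lower)


@dataclass
class ReplacementModel:
    """Normalised reversible rate matrix plus discrete-gamma rate classes.

    Attributes
    ----------
    S : symmetric exchangeabilities, zero diagonal.
    pi : equilibrium frequencies (length 20, sums to one).
    Q : rate matrix S.diag(pi), zero row sums, mean rate one.
    alpha : gamma shape of among-site rate variation.
    K : number of discrete rate categories.
    rates : per-category relative rates, mean one.
    """

    S: np.ndarray
    pi: np.ndarray
    alpha: float = 1.0
    K: int = 4
    Q: np.ndarray = field(init=False)
    rates: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if S.shape != (N_STATES, N_STATES):
            raise ModelError(f"exchangeability matrix must be 20x20, got {S.shape}")
        if not np.allclose(S, S.T):
            raise ModelError("exchangeability matrix must be symmetric")
        if (S < 0).any():
            raise ModelError("exchangeabilities must be non-negative")
        if (pi <= 0).any():
            raise ModelError("all equilibrium frequencies must be positive")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -(pi * np.diag(Q)).sum()
        self.S, self.pi, self.Q = S, pi, Q / mean_rate
        self.rates = discrete_gamma_rates(self.alpha, self.K)
        self._decompose()

    def _decompose(self) -> None:
        # symmetrise: B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric for
        # a reversible Q, so exp(Qt) comes from one eigendecomposition
        sq = np.sqrt(self.pi)
        B = (sq[:, None] * self.Q) / sq[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eigvals = w
        self._left = U / sq[:, None]  # diag(1/sqrt(pi)) U
        self._right = U.T * sq[None, :]  # U' diag(sqrt(pi))

    def with_alpha(self, alpha: float) -> "ReplacementModel":
        return ReplacementModel(self.S, self.pi, alpha=alpha, K=self.K)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) via the spectral decomposition of the reversible Q."""
        if t < 0:
            raise ModelError(f"branch length must be non-negative, got {t}")
        P = (self._left * np.exp(self._eigvals * t)) @ self._right
        np.clip(P, 0.0, 1.0, out=P)
        return P

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(r_k * t) over the K rate categories, shape (K, 20, 20)."""
        if t < 0:
            raise ModelError(f"branch length must be non-negative, got {t}")
        expd = np.exp(self._eigvals[None, :] * (self.rates[:, None] * t))
        P = np.einsum("ij,kj,jl->kil", self._left, expd, self._right)
        np.clip(P, 0.0, 1.0, out=P)
        return P


def build_model(
    matrix: str | np.ndarray = "JTT",
    freqs: str | np.ndarray = "model",
    alpha: float = 1.0,
    K: int = 4,
    alignment: Alignment | None = None,
) -> ReplacementModel:
    """Assemble a ReplacementModel.

    Parameters
    ----------
    matrix : packaged matrix name ("JTT"), a .dat path, or an explicit
        symmetric 20x20 exchangeability array.
    freqs : "model" (frequencies shipped with the matrix), "empirical"
        (+F, counted from `alignment`), or an explicit length-20 array.
    alpha, K : discrete-gamma shape and category count.
    """
    if isinstance(matrix, str):
        S, model_pi = load_exchangeability_data(matrix)
    else:
        S, model_pi = np.asarray(matrix, dtype=float), None
    if isinstance(freqs, str):
        if freqs == "model":
            if model_pi is None:
                raise ModelError("custom matrix given without frequencies")
            pi = model_pi
        elif freqs == "empirical":
            if alignment is None:
                raise ModelError("empirical frequencies need an alignment")
            pi = empirical_frequencies(alignment)
        else:
            raise ModelError(f"unknown frequency mode {freqs!r}")
    else:
        pi = np.asarray(freqs, dtype=float)
    return ReplacementModel(S, pi, alpha=alpha, K=K)


def empirical_frequencies(alignment: Alignment, pseudocount: float = 0.5) -> np.ndarray:
    """Observed residue frequencies (+F), with a pseudocount so none is zero."""
    counts = np.bincount(
        alignment.codes[alignment.codes >= 0].ravel(), minlength=N_STATES
    ).astype(float)
    counts += pseudocount
    return counts / counts.sum()


def state_index(residue: str) -> int:
    try:
        return AMINO_ACIDS.index(residue.upper())
    except ValueError:
        raise ModelError(f"unknown residue {residue!r}") from None
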