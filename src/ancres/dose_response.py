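"""Sigmoidal dose-response fitting for reporter-gene hormone assays.

The model is the four-parameter logistic (Hill) curve in log-dose space,

    R(c) = basal + (max - basal) / (1 + 10^((logEC50 - log10 c) * h)),

fit by nonlinear least squares over all replicate points. EC50 is the
hormone concentration giving half-maximal activation; its log10 is the
natural fitting scale and is reported with the asymptotic standard error
from the Jacobian at the optimum. Fold activation is measured against the
vehicle-control mean; receptors whose predicted activation at 1 uM stays
below 2-fold are classified nonresponsive. Sensitivity differences
between receptors are expressed as EC50 fold changes, 10^(logEC50_x -
logEC50_ref).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

HILL_SLOPE_BOUNDS = (0.3, 5.0)


class FitError(ValueError):
    pass


@dataclass
class DoseResponseDataset:
    """Replicate responses over a concentration grid for one receptor/hormone.

    ``conc`` is molar and strictly positive; zero-concentration rows in the
    input tables are vehicle controls and land in ``vehicle``.
    """

    receptor: str
    hormone: str
    conc: np.ndarray  # molar, one entry per replicate point
    response: np.ndarray
    vehicle: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.vehicle = np.asarray(self.vehicle, dtype=float)
        if self.conc.shape != self.response.shape:
            raise FitError("concentration and response arrays must align")
        if (self.conc <= 0).any():
            raise FitError("concentrations must be strictly positive")

    @property
    def n_concentrations(self) -> int:
        return len(np.unique(self.conc))

    @property
    def vehicle_mean(self) -> float | None:
        return float(self.vehicle.mean()) if self.vehicle.size else None

    @staticmethod
    def from_table(df: pd.DataFrame, receptor: str, hormone: str) -> "DoseResponseDataset":
        sel = df[(df["receptor"] == receptor) & (df["hormone"] == hormone)]
        if sel.empty:
            raise FitError(f"no rows for {receptor!r} / {hormone!r}")
        dosed = sel[sel["conc_M"] > 0]
        vehicle = sel[sel["conc_M"] == 0]
        return DoseResponseDataset(
            receptor=receptor,
            hormone=hormone,
            conc=dosed["conc_M"].to_numpy(),
            response=dosed["response"].to_numpy(),
            vehicle=vehicle["response"].to_numpy(),
        )


@dataclass
class HillFit:
    """Fitted four-parameter logistic curve."""

    logec50: float
    se_logec50: float
    basal: float
    maximum: float
    slope: float
    fold_activation: float
    converged: bool = True
    fold_vs_basal: bool = False  # vehicle data absent; basal stood in
    message: str = ""

    @property
    def ec50(self) -> float:
        return 10.0 ** self.logec50

    def predict(self, conc: float | np.ndarray) -> np.ndarray:
        return hill_curve(
            np.log10(np.asarray(conc, dtype=float)),
            self.basal,
            self.maximum,
            self.logec50,
            self.slope,
        )


def hill_curve(
    log_conc: np.ndarray, basal: float, maximum: float, logec50: float, slope: float
) -> np.ndarray:
    return basal + (maximum - basal) / (1.0 + 10.0 ** ((logec50 - log_conc) * slope))


def fit_hill(dataset: DoseResponseDataset, fix_slope: float | None = None) -> HillFit:
    """Least-squares Hill fit over all replicate points.

    Initialisation: basal and max from the extreme mean responses, logEC50
    at the concentration whose mean response is nearest mid-range, slope 1.
    ``fix_slope`` pins the Hill coefficient (e.g. at 1.0); otherwise it is
    free within a sanity range.
    """
    if dataset.n_concentrations < 4:
        raise FitError(
            f"need >=4 distinct concentrations, got {dataset.n_concentrations}"
        )
    x = np.log10(dataset.conc)
    y = dataset.response
    uniq = np.unique(dataset.conc)
    means = np.array([y[dataset.conc == c].mean() for c in uniq])
    lo, hi = float(means.min()), float(means.max())
    span = hi - lo
    mid_idx = int(np.argmin(np.abs(means - (lo + hi) / 2.0)))
    p0_logec50 = float(np.log10(uniq[mid_idx]))

    flat = span < 1e-12 or (y.std() > 0 and span < 0.05 * (abs(hi) + abs(lo) + 1e-30))
    xmin, xmax = float(x.min()), float(x.max())
    if fix_slope is None:
        def f(xx, basal, maximum, logec50, slope):
            return hill_curve(xx, basal, maximum, logec50, slope)

        p0 = [lo, hi, p0_logec50, 1.0]
        bounds = (
            [-np.inf, -np.inf, xmin - 6.0, HILL_SLOPE_BOUNDS[0]],
            [np.inf, np.inf, xmax + 6.0, HILL_SLOPE_BOUNDS[1]],
        )
    else:
        def f(xx, basal, maximum, logec50):
            return hill_curve(xx, basal, maximum, logec50, fix_slope)

        p0 = [lo, hi, p0_logec50]
        bounds = ([-np.inf, -np.inf, xmin - 6.0], [np.inf, np.inf, xmax + 6.0])

    converged, message = True, ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                f, x, y, p0=p0, bounds=bounds, maxfev=20000, method="trf"
            )
    except (RuntimeError, ValueError) as exc:
        converged, message = False, str(exc)
        popt = np.asarray(p0, dtype=float)
        pcov = np.full((len(p0), len(p0)), np.nan)

    basal, maximum, logec50 = float(popt[0]), float(popt[1]), float(popt[2])
    slope = fix_slope if fix_slope is not None else float(popt[3])
    se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.inf
    if basal > maximum:
        # falling curve: renormalise so basal <= max and the slope flips
        basal, maximum, slope = maximum, basal, -slope

    reference = dataset.vehicle_mean
    fold_vs_basal = reference is None
    if fold_vs_basal:
        reference = basal
        message = (message + " fold activation computed against fitted basal "
                   "(no vehicle data)").strip()
    fold = maximum / reference if reference else np.inf

    # degenerate designs: flat data, or EC50 pushed outside the dose range
    if flat or not (xmin - 3.0 <= logec50 <= xmax + 3.0) or not np.isfinite(se):
        converged = converged and not flat
        if flat:
            message = (message + " response is flat; logEC50 unreliable").strip()
        elif not (xmin - 3.0 <= logec50 <= xmax + 3.0):
            message = (message + " fitted logEC50 outside the sampled dose "
                       "range; estimate unreliable").strip()
    return HillFit(
        logec50=logec50,
        se_logec50=se,
        basal=basal,
        maximum=maximum,
        slope=slope,
        fold_activation=float(fold),
        converged=converged,
        fold_vs_basal=fold_vs_basal,
        message=message,
    )


def classify_responsive(
    fit: HillFit,
    dataset: DoseResponseDataset | None = None,
    conc_limit: float = 1e-6,
    fold_limit: float = 2.0,
) -> bool:
    """True if the receptor responds: predicted activation at ``conc_limit``
    (default 1 uM) reaches ``fold_limit`` times the vehicle mean (or the
    fitted basal when no vehicle data exist)."""
    reference = None
    if dataset is not None:
        reference = dataset.vehicle_mean
    if reference is None:
        reference = fit.basal
    if reference <= 0:
        return bool(fit.fold_activation >= fold_limit)
    predicted = float(fit.predict(conc_limit))
    return predicted >= fold_limit * reference


def fold_change(logec50_ref: float, logec50_x: float) -> float:
    """EC50 ratio of receptor x to the reference: 10^(logEC50_x - ref).

    Values above one mean reduced sensitivity relative to the reference.
    """
    if not (np.isfinite(logec50_ref) and np.isfinite(logec50_x)):
        raise FitError("fold change needs finite logEC50 values")
    return float(10.0 ** (logec50_x - logec50_ref))


def sensitivity_table(
    fits: dict[str, HillFit], reference: str, decimals: int = 1
) -> pd.DataFrame:
    """Tabulate logEC50 +/- SE and EC50 fold change against one reference."""
    if reference not in fits:
        raise FitError(f"reference receptor {reference!r} not among fits")
    ref = fits[reference].logec50
    rows = []
    for name, fit in fits.items():
        rows.append(
            {
                "receptor": name,
                "logEC50": fit.logec50,
                "SE": fit.se_logec50,
                "fold_change": (
                    np.nan if name == reference
                    else round(fold_change(ref, fit.logec50), decimals)
                ),
            }
        )
    return pd.DataFrame(rows)
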