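"""Linking predicted stability loss to observed sensitivity loss.

Per-mutant folding free-energy changes (ddG, kcal/mol, positive =
destabilizing) predicted by an external energy function are summarized
across independent runs (mean +/- sample SD), optionally excluding
mutants for documented reasons, and regressed against the mutants'
fitted logEC50 values. A strong positive slope means destabilizing
substitutions track the loss of hormone sensitivity. Two regression
modes exist: plain ordinary least squares with the unmutated reference
included as the (0, logEC50_ref) point, and an anchored fit constrained
to pass through that reference point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class StabilityError(ValueError):
    pass


@dataclass
class StabilityRecord:
    """Mean +/- SD of one mutant's per-run ddG predictions (kcal/mol)."""

    mutant: str
    runs: np.ndarray
    excluded: bool = False
    reason: str = ""
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.runs = np.asarray(self.runs, dtype=float)
        self.runs = self.runs[~np.isnan(self.runs)]
        if self.runs.size == 0:
            raise StabilityError(f"mutant {self.mutant!r} has no run values")
        if self.excluded and not self.reason:
            raise StabilityError(f"excluded mutant {self.mutant!r} needs a reason")
        self.mean = float(self.runs.mean())
        self.sd = float(self.runs.std(ddof=1)) if self.runs.size > 1 else 0.0


def summarize_runs(
    table: pd.DataFrame, exclusions: dict[str, str] | None = None
) -> list[StabilityRecord]:
    """Collapse a per-run ddG table (columns mutant, run1..runN) to records.

    ``exclusions`` maps mutant labels to the reason they are left out of
    downstream regressions (e.g. "segmentation fault", "borders gap",
    "contacts ligand"); excluded records are kept, flagged, and reported.
    """
    exclusions = exclusions or {}
    run_cols = [c for c in table.columns if str(c).startswith("run")]
    if not run_cols:
        raise StabilityError("no run columns (run1..runN) in ddG table")
    records = []
    for _, row in table.iterrows():
        label = str(row["mutant"])
        records.append(
            StabilityRecord(
                mutant=label,
                runs=row[run_cols].to_numpy(dtype=float),
                excluded=label in exclusions,
                reason=exclusions.get(label, ""),
            )
        )
    return records


@dataclass
class RegressionResult:
    """Stability-sensitivity line: logEC50 = slope * ddG + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    anchored: bool = False
    excluded_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise StabilityError("regression needs at least two points")
        if not (-1e-9 <= self.r_squared <= 1.0 + 1e-9):
            raise StabilityError(f"r^2 out of range: {self.r_squared}")
        self.r_squared = float(min(max(self.r_squared, 0.0), 1.0))

    def predict(self, x: float | np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def _fit(x: np.ndarray, y: np.ndarray, anchor: tuple[float, float] | None):
    if anchor is None:
        if np.ptp(x) == 0:
            raise StabilityError("degenerate x values: no variance to regress on")
        res = stats.linregress(x, y)
        return float(res.slope), float(res.intercept), float(res.rvalue) ** 2
    x0, y0 = anchor
    dx, dy = x - x0, y - y0
    denom = float((dx * dx).sum())
    if denom == 0:
        raise StabilityError("degenerate x values: no variance to regress on")
    slope = float((dx * dy).sum()) / denom
    # goodness of fit about the anchored line: residual sum of squares
    # against total variation measured about the anchor point
    ss_res = float(((dy - slope * dx) ** 2).sum())
    ss_tot = float((dy * dy).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, y0 - slope * x0, r2


def stability_sensitivity_regression(
    points: dict[str, tuple[float, float]],
    reference: tuple[float, float] = (0.0, -10.870),
    exclude: set[str] | None = None,
    anchor: bool = False,
) -> RegressionResult:
    """Regress logEC50 on mean ddG across mutants.

    ``points`` maps mutant labels to (ddG, logEC50). The unmutated
    reference receptor enters as the point ``reference`` (ddG 0 by
    definition); with ``anchor=True`` the line is constrained through it
    instead. ``exclude`` drops labelled mutants (always reported on the
    result, never silent).
    """
    exclude = exclude or set()
    unknown = exclude - set(points)
    if unknown:
        raise StabilityError(f"cannot exclude unknown mutants: {sorted(unknown)}")
    kept = {k: v for k, v in points.items() if k not in exclude}
    x = np.array([v[0] for v in kept.values()], dtype=float)
    y = np.array([v[1] for v in kept.values()], dtype=float)
    if anchor:
        if len(kept) < 2:
            raise StabilityError("regression needs at least two points")
        slope, intercept, r2 = _fit(x, y, reference)
        n = len(kept)
    else:
        x = np.concatenate([[reference[0]], x])
        y = np.concatenate([[reference[1]], y])
        if len(x) < 2:
            raise StabilityError("regression needs at least two points")
        slope, intercept, r2 = _fit(x, y, None)
        n = len(x)
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n=n,
        anchored=anchor,
        excluded_labels=sorted(exclude),
    )


def regression_with_and_without(
    points: dict[str, tuple[float, float]],
    exclude: set[str],
    reference: tuple[float, float] = (0.0, -10.870),
    anchor: bool = False,
) -> tuple[RegressionResult, RegressionResult]:
    """The full-data and exclusion-set regressions in one call."""
    full = stability_sensitivity_regression(points, reference, set(), anchor)
    reduced = stability_sensitivity_regression(points, reference, exclude, anchor)
    return full, reduced


def ddg_histogram(records: list[StabilityRecord], bin_width: float = 0.5) -> pd.DataFrame:
    """Distribution of single-mutant stability effects as a binned table."""
    if bin_width <= 0:
        raise StabilityError("bin width must be positive")
    values = np.array([r.mean for r in records if not r.excluded])
    if values.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
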