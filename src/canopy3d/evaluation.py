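"""Scoring of height estimates against reference measurements.

Estimates are compared with manual reference heights by RMSE, bias (mean of
estimate minus reference; negative means underestimation) and R-squared
(the squared Pearson correlation, which separates precision from the bias
that is reported alongside it). Percentile ladders are scored per grid
level, and the optimal percentile of a method category is the level whose
heights minimize RMSE over the category's plots. Derived comparison
statistics — percent RMSE reduction from pre-processing, percent excess of
a pooled category over per-method categories, and the average RMSE increase
from ignoring plot position — follow the printed-precision rounding of
field reports (two decimals for percentages, four for meters, half up).

Campaigns map to manual methods by growth stage: campaigns 1-2 were
measured to the top of the stem (method A, vegetative), campaigns 3-5 to
the top of the spike excluding awns (method B, reproductive).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .heights import PercentileLadder

#: Campaign index -> manual measurement method.
CAMPAIGN_METHODS = {1: "A", 2: "A", 3: "B", 4: "B", 5: "B"}


@dataclass(frozen=True)
class CampaignInfo:
    """One data collection campaign and its manual method."""

    campaign_index: int
    method: str
    date: str | None = None

    def __post_init__(self) -> None:
        expected = CAMPAIGN_METHODS.get(self.campaign_index)
        if expected is None:
            raise ValueError("campaign_index must lie in 1..5")
        if self.method != expected:
            raise ValueError(
                f"campaign {self.campaign_index} uses method {expected}, "
                f"not {self.method}"
            )


@dataclass
class EvaluationResult:
    """RMSE / bias / R^2 for one set of (estimate, reference) pairs."""

    rmse: float
    bias: float
    r_squared: float | None
    n: int
    category: str = "all"
    position: str = "pooled"
    optimal_percentile: float | None = None


def round_half_up(value: float, decimals: int) -> float:
    """Round half away from zero at a fixed decimal count (printed style)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _paired(est, ref) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(est, dtype=float).ravel()
    r = np.asarray(ref, dtype=float).ravel()
    if e.size != r.size:
        raise ValueError(f"length mismatch: {e.size} estimates vs {r.size} references")
    if e.size == 0:
        raise ValueError("need at least one pair")
    return e, r


def rmse(est, ref) -> float:
    """Root-mean-square error of estimates against references."""
    e, r = _paired(est, ref)
    return float(np.sqrt(np.mean((e - r) ** 2)))


def bias(est, ref) -> float:
    """Mean signed error (estimate - reference); negative = underestimation."""
    e, r = _paired(est, ref)
    return float(np.mean(e - r))


def r_squared(est, ref) -> float:
    """Squared Pearson correlation between estimates and references."""
    e, r = _paired(est, ref)
    if e.size < 2:
        raise ValueError("R^2 needs at least two pairs")
    if np.ptp(e) == 0 or np.ptp(r) == 0:
        raise ValueError("R^2 undefined for a constant vector")
    c = np.corrcoef(e, r)[0, 1]
    return float(c * c)


def evaluate(est, ref, category: str = "all", position: str = "pooled") -> EvaluationResult:
    """Bundle RMSE, bias and (when defined) R^2 for a pair set."""
    e, r = _paired(est, ref)
    try:
        r2 = r_squared(e, r)
    except ValueError:
        r2 = None
    return EvaluationResult(
        rmse=rmse(e, r), bias=bias(e, r), r_squared=r2, n=e.size,
        category=category, position=position,
    )


def ladder_rmse_curve(ladders: list[PercentileLadder], ref) -> tuple[np.ndarray, np.ndarray]:
    """RMSE against the references at every grid percentile.

    All ladders must share the same percentile grid; references align with
    the ladder list. Returns ``(grid, rmse_per_level)``.
    """
    if not ladders:
        raise ValueError("empty ladder selection")
    grid = ladders[0].percentiles
    for lad in ladders[1:]:
        if lad.percentiles.shape != grid.shape or not np.allclose(lad.percentiles, grid):
            raise ValueError("ladders do not share a percentile grid")
    refs = np.asarray(ref, dtype=float).ravel()
    if refs.size != len(ladders):
        raise ValueError("one reference per ladder required")
    h = np.vstack([lad.heights for lad in ladders])  # (n_plots, n_levels)
    err = h - refs[:, None]
    return grid, np.sqrt(np.mean(err**2, axis=0))


def optimal_percentile(ladders: list[PercentileLadder], ref) -> tuple[float, float]:
    """Grid percentile minimizing RMSE over the selected plots.

    Ties break toward the lowest percentile. Returns
    ``(percentile, min_rmse)``.
    """
    grid, curve = ladder_rmse_curve(ladders, ref)
    i = int(np.argmin(curve))  # argmin returns the first minimum: lowest percentile
    return float(grid[i]), float(curve[i])


def optimal_r2_percentile(ladders: list[PercentileLadder], ref) -> tuple[float, float]:
    """Grid percentile maximizing R^2 (reported alongside the RMSE optimum;
    the two need not agree). Ties break toward the lowest percentile."""
    grid = ladders[0].percentiles
    refs = np.asarray(ref, dtype=float).ravel()
    h = np.vstack([lad.heights for lad in ladders])
    best = (-np.inf, None)
    for j, p in enumerate(grid):
        col = h[:, j]
        if np.ptp(col) == 0 or np.ptp(refs) == 0:
            continue
        c = np.corrcoef(col, refs)[0, 1] ** 2
        if c > best[0]:
            best = (c, float(p))
    if best[1] is None:
        raise ValueError("R^2 undefined at every percentile")
    return best[1], float(best[0])


def percent_reduction(rmse_raw: float, rmse_processed: float) -> float:
    """Percent decrease of an error statistic, printed to two decimals."""
    if rmse_raw <= 0:
        raise ValueError("rmse_raw must be positive")
    return round_half_up((rmse_raw - rmse_processed) / rmse_raw * 100.0, 2)


def percent_exceed(a: float, b: float) -> float:
    """How much larger ``a`` is than ``b``, in percent of ``b`` (two decimals)."""
    if b <= 0:
        raise ValueError("the reference value must be positive")
    return round_half_up((a / b - 1.0) * 100.0, 2)


def average_rmse_increase(categories) -> float:
    """Average RMSE penalty for pooling plot positions within categories.

    Each entry provides the combined (positions pooled) minimum RMSE and the
    side / middle minimum RMSEs; the penalty per category is the combined
    value minus the unweighted mean of the two position values, and the
    result is the mean penalty over categories, printed to four decimals.
    """
    cats = list(categories)
    if not cats:
        raise ValueError("empty category list")
    increases = []
    for cat in cats:
        if isinstance(cat, dict):
            combined, side, middle = cat["combined_rmse"], cat["side_rmse"], cat["middle_rmse"]
        else:
            combined, side, middle = cat
        if min(combined, side, middle) <= 0:
            raise ValueError("RMSE values must be positive")
        increases.append(combined - 0.5 * (side + middle))
    return round_half_up(float(np.mean(increases)), 4)
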