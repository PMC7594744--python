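"""Coupling between exit time and division timing.

The central question: does the time at which a cell downregulates its
naive-pluripotency reporter (tau) track the time of its latest cell
division?  The pipeline assigns each cell its latest division (the
largest division time at most ``grace`` hours after tau, the grace
window absorbing the experimental uncertainty in tau), regresses tau on
it, and asks how often the observed R^2 would arise by chance under a
reassignment bootstrap: each cell's tau is re-paired with the division
time(s) of a uniformly drawn cell (with replacement, self-pairing
allowed); where a drawn cell has two divisions, the one closest to tau
is used.  The empirical p is the fraction of replicates whose R^2
reaches the observed value.

Note the two distinct division-selection rules, kept deliberately
separate: the *observed* regression uses the latest-division/grace rule,
while *bootstrap replicates* use the closest-to-tau rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ExitDivisionPair", "CouplingResult", "latest_division",
           "regress_exit_vs_division", "bootstrap_null",
           "classify_exit_division", "pairs_from_tables"]

DEFAULT_GRACE_H = 2.5


@dataclass(frozen=True)
class ExitDivisionPair:
    """One cell's exit time and division history (hours from trigger)."""

    cell_id: str
    tau: float
    division_times: tuple[float, ...]
    latest_division: float | None = None

    def __post_init__(self):
        if not self.division_times:
            raise ValueError("division_times must be non-empty")
        object.__setattr__(self, "division_times",
                           tuple(sorted(self.division_times)))
        if self.latest_division is not None and \
                self.latest_division not in self.division_times:
            raise ValueError("latest_division must be one of division_times")


@dataclass(frozen=True)
class CouplingResult:
    r_squared: float
    slope: float
    intercept: float
    n_cells: int
    boot_r_squared: np.ndarray
    p_empirical: float
    n_boot: int
    seed: int


def latest_division(tau: float, division_times, grace: float = DEFAULT_GRACE_H
                    ) -> float | None:
    """Largest division time <= tau + grace, or None if none qualifies."""
    division_times = list(division_times)
    if not division_times:
        raise ValueError("division_times must be non-empty")
    qualifying = [d for d in division_times if d <= tau + grace]
    return max(qualifying) if qualifying else None


def assign_latest_divisions(pairs: list[ExitDivisionPair],
                            grace: float = DEFAULT_GRACE_H
                            ) -> tuple[list[ExitDivisionPair], int]:
    """Fill in latest_division for every pair; cells with no qualifying
    division are dropped.  Returns (retained pairs, number excluded)."""
    kept, excluded = [], 0
    for p in pairs:
        d = latest_division(p.tau, p.division_times, grace)
        if d is None:
            excluded += 1
        else:
            kept.append(ExitDivisionPair(p.cell_id, p.tau, p.division_times,
                                         latest_division=d))
    return kept, excluded


def regress_exit_vs_division(pairs: list[ExitDivisionPair]
                             ) -> tuple[float, float, float]:
    """OLS of tau on latest division; returns (slope, intercept, R^2)."""
    usable = [p for p in pairs if p.latest_division is not None]
    if len(usable) < 3:
        raise ValueError("need >= 3 pairs with a defined latest division")
    x = np.array([p.latest_division for p in usable])
    y = np.array([p.tau for p in usable])
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all latest divisions equal")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def _r_squared_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise simple-regression R^2 of y (1-D) on each row of x."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxy = xc @ yc
    sxx = np.einsum("ij,ij->i", xc, xc)
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where((sxx > 0) & (syy > 0), (sxy ** 2) / (sxx * syy), 0.0)
    return r2


def bootstrap_null(pairs: list[ExitDivisionPair], n_boot: int = 1000,
                   seed: int = 0, grace: float = DEFAULT_GRACE_H,
                   corrected: bool = False) -> CouplingResult:
    """Reassignment bootstrap for the exit-division correlation.

    One-sided: p_empirical is the fraction of replicates whose R^2 is at
    least the observed R^2 (raw exceedance by default; ``corrected``
    switches to (1 + count) / (1 + n_boot)).
    """
    if n_boot < 1:
        raise ValueError("config error: n_boot must be >= 1")
    usable, _ = assign_latest_divisions(pairs, grace)
    slope, intercept, r2_obs = regress_exit_vs_division(usable)

    n = len(usable)
    tau = np.array([p.tau for p in usable])
    d1 = np.array([p.division_times[0] for p in usable])
    d2 = np.array([p.division_times[1] if len(p.division_times) > 1
                   else np.nan for p in usable])

    rng = np.random.default_rng(seed)
    J = rng.integers(0, n, size=(n_boot, n))
    a, b = d1[J], d2[J]
    # closest-to-tau rule within each replicate
    use_b = ~np.isnan(b) & (np.abs(b - tau) < np.abs(a - tau))
    x = np.where(use_b, b, a)
    boot_r2 = _r_squared_rows(x, tau)

    count = int(np.sum(boot_r2 >= r2_obs))
    p = (1 + count) / (1 + n_boot) if corrected else count / n_boot
    return CouplingResult(r2_obs, slope, intercept, n, boot_r2, float(p),
                          n_boot, seed)


def classify_exit_division(taus, division_lists, window_h: float = 4.0,
                           boundary_h: float = 12.0
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify each cell's exit relative to its divisions.

    Category: "first" if tau is within ``window_h`` of the first
    division, "second" if within ``window_h`` of the second, else
    "between"; a tau within the window of both divisions goes to the
    nearer one (exact ties to the second).  Stage: "early-cycle" if the
    first division came strictly more than ``boundary_h`` after the
    trigger, otherwise "late-cycle" (a first division exactly at the
    boundary counts as late-cycle).

    Returns (per-cell table, per-stage category percentages).
    """
    rows = []
    for tau, divs in zip(taus, division_lists):
        divs = sorted(divs)
        if not 1 <= len(divs) <= 2:
            raise ValueError("each cell needs 1 or 2 division times")
        dist1 = abs(tau - divs[0])
        dist2 = abs(tau - divs[1]) if len(divs) > 1 else np.inf
        if dist1 <= window_h and dist2 <= window_h:
            category = "second" if dist2 <= dist1 else "first"
        elif dist1 <= window_h:
            category = "first"
        elif dist2 <= window_h:
            category = "second"
        else:
            category = "between"
        stage = "early-cycle" if divs[0] > boundary_h else "late-cycle"
        rows.append(dict(tau_h=tau, category=category, stage=stage))
    per_cell = pd.DataFrame(rows)
    pct = (per_cell.groupby("stage")["category"]
           .value_counts(normalize=True).mul(100.0)
           .rename("percent").reset_index())
    return per_cell, pct


def pairs_from_tables(fits: pd.DataFrame, lineage: pd.DataFrame,
                      kept_only: bool = True) -> list[ExitDivisionPair]:
    """Join a fit table with a lineage table into ExitDivisionPairs."""
    from .synthetic import parse_division_times

    div_map = {r.cell_id: parse_division_times(r.division_times_h)
               for r in lineage.itertuples()}
    pairs = []
    for r in fits.itertuples():
        if kept_only and not r.kept:
            continue
        divs = div_map.get(r.cell_id, [])
        if divs:
            pairs.append(ExitDivisionPair(r.cell_id, float(r.tau_h),
                                          tuple(divs)))
    return pairs
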