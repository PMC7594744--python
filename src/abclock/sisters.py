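"""Sister-pair correlation statistics for reporter downregulation.

Three complementary measures of how alike two sister cells are while
exiting the naive state:

* variance: the time-averaged population ("global") variance of
  first-point-normalized reporter curves versus the time-averaged
  variance within a sister pair ("local"); their ratio quantifies the
  sister correlation (2-3-fold reduction in the imaging dataset),
* exit-time differences |delta tau| for sister pairs versus pairs of
  unrelated cells,
* division asymmetry: correlation of the daughter volume ratio
  (smaller/larger) with the exit-time ratio and with the ratio of the
  early post-division reporter decrease.

Both variance statistics use the population (divide-by-n) convention at
every time point, so a sister pair and a two-cell population give
identical numbers — the two are compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["VarianceResult", "global_variance", "pair_variance",
           "variance_report", "exit_time_differences",
           "asymmetry_correlation", "sister_pairs_from_lineage",
           "reporter_decrease"]


@dataclass(frozen=True)
class VarianceResult:
    global_variance: float
    pair_variances: np.ndarray
    fold_reduction: float  # global / mean(pair)


def _as_matrix(trajs) -> np.ndarray:
    m = np.asarray(trajs, dtype=float)
    if m.ndim != 2:
        raise ValueError("schema error: expected (n_cells, n_times) matrix "
                         "on a common time grid")
    return m


def global_variance(trajs) -> float:
    """Time-averaged population variance across all cells.

    ``trajs`` is an (n_cells, n_times) array of normalized intensities
    on a common grid.  At each time point the variance across cells is
    taken with the n denominator, then averaged over time.
    """
    m = _as_matrix(trajs)
    if m.shape[0] < 2:
        raise ValueError("need >= 2 cells")
    return float(np.mean(np.var(m, axis=0, ddof=0)))


def pair_variance(a, b) -> float:
    """Time-averaged variance between two sister curves (n denominator).

    Identical convention to :func:`global_variance`, so for two constant
    curves at 0 and 2 both statistics give 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("schema error: sisters must share a time grid")
    return float(np.mean((a - b) ** 2) / 4.0)


def variance_report(trajs, pairs: list[tuple[int, int]]) -> VarianceResult:
    """Global vs sister-pair variance and their fold reduction.

    ``pairs`` indexes sister rows of ``trajs``.  ``fold_reduction`` is
    global_variance / mean(pair variances).
    """
    m = _as_matrix(trajs)
    g = global_variance(m)
    pv = np.array([pair_variance(m[i], m[j]) for i, j in pairs])
    mean_pv = float(np.mean(pv)) if pv.size else np.nan
    fold = g / mean_pv if pv.size and mean_pv > 0 else np.inf
    return VarianceResult(g, pv, float(fold))


def exit_time_differences(sister_tau_pairs, all_taus, sister_index_pairs=None,
                          n_random: int | None = None, seed: int = 0):
    """|delta tau| for sister pairs vs uniformly drawn non-sister pairs.

    Random pairs are drawn without repetition among distinct unordered
    non-sister pairs; ``n_random`` defaults to the number of sister
    pairs.  Returns (sister |dtau|, random |dtau|, rank-sum p) where the
    p-value is a two-sided Mann-Whitney U comparison.
    """
    sister_tau_pairs = [(float(a), float(b)) for a, b in sister_tau_pairs]
    all_taus = np.asarray(all_taus, dtype=float)
    n_cells = all_taus.size
    if n_random is None:
        n_random = len(sister_tau_pairs)
    sister_set = {frozenset(p) for p in (sister_index_pairs or [])}
    candidates = [(i, j) for i in range(n_cells) for j in range(i + 1, n_cells)
                  if frozenset((i, j)) not in sister_set]
    if len(candidates) < n_random:
        raise ValueError("fewer non-sister pairs than requested random pairs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_random, replace=False)
    random_d = np.array([abs(all_taus[candidates[k][0]] -
                             all_taus[candidates[k][1]]) for k in chosen])
    sister_d = np.array([abs(a - b) for a, b in sister_tau_pairs])
    if sister_d.size and random_d.size:
        p = float(stats.mannwhitneyu(sister_d, random_d,
                                     alternative="two-sided").pvalue)
    else:
        p = np.nan
    return sister_d, random_d, p


def asymmetry_correlation(volume_ratios, outcome_ratios
                          ) -> tuple[float, float, bool]:
    """Pearson correlation of division asymmetry with an outcome ratio.

    ``volume_ratios`` follow the smaller/larger convention; the outcome
    ratio (exit-time or reporter-decrease) is ordered the same way
    (smaller cell's value over larger cell's).  Returns (r, p, defined);
    zero variance in either variable makes the correlation undefined and
    is flagged rather than raised.
    """
    x = np.asarray(volume_ratios, dtype=float)
    y = np.asarray(outcome_ratios, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, False
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), True


def reporter_decrease(times, intensities, division_h: float,
                      horizon_h: float = 6.0) -> float:
    """Drop in reporter intensity over the first ``horizon_h`` hours
    after a division (intensity at division minus intensity at
    division + horizon, by nearest sample)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    i0 = int(np.argmin(np.abs(t - division_h)))
    i1 = int(np.argmin(np.abs(t - (division_h + horizon_h))))
    return float(y[i0] - y[i1])


def sister_pairs_from_lineage(lineage: pd.DataFrame
                              ) -> list[tuple[str, str]]:
    """Terminal sister pairs (cells sharing a parent and carrying a
    reporter trajectory, i.e. a true_tau_h) from a lineage table."""
    cells = lineage[lineage["true_tau_h"].notna()]
    pairs = []
    for _, grp in cells.groupby("parent_id", sort=True):
        ids = sorted(grp["cell_id"])
        if len(ids) == 2:
            pairs.append((ids[0], ids[1]))
    return pairs


def trajectory_matrix(trajectories: pd.DataFrame, cell_ids=None,
                      normalize: bool = True, t_max: float | None = None
                      ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Pivot a long trajectory table to (cells x times), optionally
    first-point-normalized and truncated at ``t_max`` (used to restrict
    analysis to before a cell's next division)."""
    wide = trajectories.pivot(index="cell_id", columns="t_h",
                              values="intensity_au")
    if cell_ids is not None:
        wide = wide.loc[list(cell_ids)]
    if wide.isna().any().any():
        raise ValueError("schema error: trajectories not on a common grid")
    if t_max is not None:
        wide = wide.loc[:, wide.columns <= t_max]
    m = wide.to_numpy()
    if normalize:
        first = m[:, :1]
        if np.any(first <= 0):
            raise ValueError("cannot normalize: first intensity must be > 0")
        m = m / first
    return m, list(wide.index), wide.columns.to_numpy()
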