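"""Intercellular-bridge abscission kinetics.

Bridge width after cytokinesis decays exponentially towards a plateau::

    w(t) = w_inf + (w0 - w_inf) * exp(-t / tau_c)

The characteristic time tau_c is the quantity of interest: bridges of
naive ES cells thin slowly (tau_c ~ 45 min) while bridges of cells
exiting the naive state thin fast (~15 min).  Two tests of the
between-condition difference are provided, because the comparison can
be framed either way: an extra-sum-of-squares F test on the pooled
point clouds (nested models sharing tau_c versus one tau_c per
condition, the standard curve-fitting comparison) and a label
permutation test on |log(tau_A / tau_B)|.

Also here: abscission-duration summaries (mean, sd over events timed
from cytokinesis end to microtubule-bridge dissolution), the per-frame
fraction of cells with bridges, and the rank-correlation trend of that
fraction against a covariate such as cell density.  Midbody-remnant
densities (count per cell per frame) reuse the same fraction machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

__all__ = ["BridgeTrace", "ExpFit", "fit_exponential", "compare_conditions",
           "abscission_durations", "bridge_fraction", "density_trend",
           "fit_bridge_table"]

MIN_POINTS = 4
SPARSE_POINTS = 6  # below this, w_inf may be fixed at 0 on request


@dataclass(frozen=True)
class BridgeTrace:
    """One bridge's width time course (minutes from cytokinesis end)."""

    bridge_id: str
    times: np.ndarray
    widths: np.ndarray
    condition: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.widths, dtype=float)
        if t.shape != w.shape or t.ndim != 1:
            raise ValueError("times and widths must be equal-length 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(w < 0):
            raise ValueError("widths must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "widths", w)


@dataclass(frozen=True)
class ExpFit:
    bridge_id: str
    w0: float
    w_inf: float
    tau_c: float  # min
    rss: float
    converged: bool


def _exp_model(t, w0, w_inf, tau_c):
    return w_inf + (w0 - w_inf) * np.exp(-t / tau_c)


def fit_exponential(trace: BridgeTrace, fix_winf: bool = False) -> ExpFit:
    """Bounded least-squares exponential-decay fit of one width course.

    ``fix_winf`` pins the plateau at zero (useful for sparse traces,
    < 6 points, where three free parameters overfit).
    """
    t, w = trace.times, trace.widths
    if t.size < MIN_POINTS:
        raise ValueError("too few samples: need >= 4 points")
    if np.ptp(w) == 0:
        raise ValueError("no decay: constant trace")
    span = t[-1] - t[0]
    tau0 = max(span / 3.0, 1e-3)
    if fix_winf:
        def resid(p):
            return _exp_model(t, p[0], 0.0, p[1]) - w
        p0 = [max(w[0], 1e-6), tau0]
        lb, ub = [0.0, 1e-6], [np.inf, np.inf]
    else:
        def resid(p):
            return _exp_model(t, p[0], p[1], p[2]) - w
        p0 = [max(w[0], 1e-6), max(np.min(w), 0.0), tau0]
        lb, ub = [0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]
    sol = least_squares(resid, p0, bounds=(lb, ub), max_nfev=10000)
    rss = float(sol.fun @ sol.fun)
    if fix_winf:
        w0, w_inf, tau_c = float(sol.x[0]), 0.0, float(sol.x[1])
    else:
        w0, w_inf, tau_c = (float(v) for v in sol.x)
    return ExpFit(trace.bridge_id, w0, w_inf, tau_c, rss,
                  converged=bool(sol.success))


def fit_bridge_table(bridges: pd.DataFrame, fix_winf: bool = False
                     ) -> pd.DataFrame:
    """Fit every bridge of a long ``bridge_id, condition, t_min,
    width_um`` table; returns one row per bridge."""
    rows = []
    for bid, grp in bridges.groupby("bridge_id", sort=True):
        grp = grp.sort_values("t_min")
        f = fit_exponential(BridgeTrace(
            str(bid), grp["t_min"].to_numpy(), grp["width_um"].to_numpy(),
            condition=str(grp["condition"].iloc[0])), fix_winf=fix_winf)
        rows.append(dict(bridge_id=f.bridge_id,
                         condition=str(grp["condition"].iloc[0]),
                         w0=f.w0, w_inf=f.w_inf, tau_c_min=f.tau_c,
                         rss=f.rss, converged=f.converged))
    return pd.DataFrame(rows)


def _traces_from(obj) -> list[BridgeTrace]:
    if isinstance(obj, pd.DataFrame):
        out = []
        for bid, grp in obj.groupby("bridge_id", sort=True):
            grp = grp.sort_values("t_min")
            cond = str(grp["condition"].iloc[0]) if "condition" in grp else ""
            out.append(BridgeTrace(str(bid), grp["t_min"].to_numpy(),
                                   grp["width_um"].to_numpy(), cond))
        return out
    return list(obj)


def _rss_shared_tau(traces_a, traces_b) -> float:
    """RSS of the null model: per-condition w0/w_inf, shared tau_c."""
    ta = np.concatenate([tr.times for tr in traces_a])
    wa = np.concatenate([tr.widths for tr in traces_a])
    tb = np.concatenate([tr.times for tr in traces_b])
    wb = np.concatenate([tr.widths for tr in traces_b])

    def resid(p):
        w0a, wia, w0b, wib, tau = p
        return np.concatenate([_exp_model(ta, w0a, wia, tau) - wa,
                               _exp_model(tb, w0b, wib, tau) - wb])

    p0 = [wa.max(), wa.min(), wb.max(), wb.min(),
          max((ta.max() + tb.max()) / 6.0, 1e-3)]
    sol = least_squares(resid, p0, bounds=([0, 0, 0, 0, 1e-6], np.inf),
                        max_nfev=20000)
    return float(sol.fun @ sol.fun)


def _rss_separate(traces) -> tuple[float, float]:
    """(tau_c, RSS) of a per-condition fit evaluated on the raw points."""
    t = np.concatenate([tr.times for tr in traces])
    w = np.concatenate([tr.widths for tr in traces])

    def resid(p):
        return _exp_model(t, p[0], p[1], p[2]) - w

    p0 = [w.max(), max(w.min(), 0.0), max(t.max() / 3.0, 1e-3)]
    sol = least_squares(resid, p0, bounds=([0, 0, 1e-6], np.inf),
                        max_nfev=20000)
    return float(sol.x[2]), float(sol.fun @ sol.fun)


def compare_conditions(traces_a, traces_b, method: str = "F",
                       n_perm: int = 1000, seed: int = 0) -> dict:
    """Test whether two conditions share a bridge-thinning tau_c.

    method="F": extra-sum-of-squares F test on the pooled point clouds,
    null = per-condition amplitudes with one shared tau_c (5 params),
    alternative = separate tau_c per condition (6 params).

    method="permutation": statistic |log(tau_A / tau_B)| from pooled
    per-condition fits, null built by shuffling condition labels across
    whole traces.

    Returns a dict with per-condition tau_c, the p-value and method
    metadata.
    """
    traces_a, traces_b = _traces_from(traces_a), _traces_from(traces_b)
    if not traces_a or not traces_b:
        raise ValueError("both conditions must be non-empty")

    tau_a, rss_a = _rss_separate(traces_a)
    tau_b, rss_b = _rss_separate(traces_b)

    if method == "F":
        rss1 = rss_a + rss_b
        rss0 = _rss_shared_tau(traces_a, traces_b)
        n_points = sum(tr.times.size for tr in traces_a + traces_b)
        df1 = n_points - 6
        f_stat = max(rss0 - rss1, 0.0) / (rss1 / df1)
        p = float(stats.f.sf(f_stat, 1, df1))
        return dict(tau_a=tau_a, tau_b=tau_b, method="F", statistic=f_stat,
                    p_value=p, n_a=len(traces_a), n_b=len(traces_b))
    if method == "permutation":
        if len(traces_a) < 2 or len(traces_b) < 2:
            raise ValueError("permutation method needs >= 2 traces per "
                             "condition")
        obs = abs(np.log(tau_a / tau_b))
        pool = traces_a + traces_b
        n_a = len(traces_a)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            idx = rng.permutation(len(pool))
            ga = [pool[i] for i in idx[:n_a]]
            gb = [pool[i] for i in idx[n_a:]]
            ta, _ = _rss_separate(ga)
            tb, _ = _rss_separate(gb)
            if abs(np.log(ta / tb)) >= obs:
                count += 1
        p = (1 + count) / (1 + n_perm)
        return dict(tau_a=tau_a, tau_b=tau_b, method="permutation",
                    statistic=obs, p_value=float(p), n_a=len(traces_a),
                    n_b=len(traces_b), n_perm=n_perm, seed=seed)
    raise ValueError(f"unknown method: {method!r}")


def abscission_durations(durations) -> dict:
    """Sample mean and sd (n-1 denominator) of abscission durations."""
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("no events")
    if np.any(d < 0):
        raise ValueError("durations must be >= 0")
    sd = float(np.std(d, ddof=1)) if d.size > 1 else None
    return dict(mean=float(np.mean(d)), sd=sd, n=int(d.size))


def bridge_fraction(counts: pd.DataFrame) -> dict:
    """Per-frame bridge fractions and their pooled mean +/- sem.

    Expects ``frame_id, n_cells, n_bridges``; frames with zero cells are
    excluded with a warning.
    """
    counts = counts.copy()
    empty = counts["n_cells"] < 1
    if empty.any():
        warnings.warn(f"excluding {int(empty.sum())} frame(s) with 0 cells")
        counts = counts[~empty]
    if counts.empty:
        raise ValueError("no usable frames")
    frac = counts["n_bridges"] / counts["n_cells"]
    sem = float(frac.std(ddof=1) / np.sqrt(len(frac))) if len(frac) > 1 \
        else None
    return dict(fractions=frac.to_numpy(), mean=float(frac.mean()), sem=sem,
                n_frames=int(len(frac)))


def density_trend(fractions, covariate) -> tuple[float, float, bool]:
    """Spearman rank correlation of bridge fraction vs a covariate
    (e.g. cell density).  Returns (rho, p, defined)."""
    f = np.asarray(fractions, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if f.size < 3:
        raise ValueError("need >= 3 bins")
    if np.ptp(c) == 0 or np.ptp(f) == 0:
        # no rank information in a constant variable
        return (0.0, 1.0, False) if np.ptp(f) == 0 else (np.nan, np.nan, False)
    rho, p = stats.spearmanr(f, c)
    return float(rho), float(p), True
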