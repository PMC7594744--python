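"""Sigmoidal-decay fitting of single-cell reporter trajectories.

The exit time tau of a cell is defined as the inflection of a
four-parameter logistic decay fitted to its reporter intensity time
course::

    I(t) = lo + (hi - lo) / (1 + exp((t - tau) / steepness))

A logistic has exactly one inflection, at the midpoint parameter tau;
an earlier "decay onset" reading (tau - 2 * steepness) is exposed as
``SigmoidFit.onset`` for sensitivity checks but is never the default.

Fits whose tau uncertainty is on the order of tau itself, or whose tau
falls outside the observed time window, are discarded by
:func:`filter_fits` — mirroring the quality criterion applied to the
live-imaging dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = ["Trajectory", "SigmoidFit", "fit_sigmoid", "filter_fits",
           "normalize_trajectory", "fit_table"]

MIN_SAMPLES = 6


@dataclass(frozen=True)
class Trajectory:
    """One cell's reporter intensity time course (hours, arbitrary units)."""

    cell_id: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and intensities must be equal-length 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("schema error: times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted logistic-decay parameters and quality flags for one cell."""

    cell_id: str
    hi: float
    lo: float
    tau: float          # h, inflection = exit time
    steepness: float    # h
    sigma_tau: float    # h, standard error of tau
    rss: float          # a.u.^2
    converged: bool
    kept: bool = False
    window: tuple[float, float] = (np.nan, np.nan)  # observed time span

    @property
    def onset(self) -> float:
        """Decay-onset reading of the exit time (tau - 2*steepness)."""
        return self.tau - 2.0 * self.steepness


def _model(t, hi, lo, tau, steepness):
    return lo + (hi - lo) / (1.0 + np.exp((t - tau) / steepness))


def fit_sigmoid(traj: Trajectory) -> SigmoidFit:
    """Least-squares logistic-decay fit; never raises on non-convergence.

    Initialization: hi from the first three points, lo from the last
    three, tau at the half-crossing, steepness at 10% of the span.
    sigma_tau comes from the Jacobian-based parameter covariance at the
    optimum; a singular covariance yields sigma_tau = inf (such fits are
    always filtered out).
    """
    if len(traj) < MIN_SAMPLES:
        raise ValueError("too few samples")
    t, y = traj.times, traj.intensities
    window = (float(t[0]), float(t[-1]))
    span = t[-1] - t[0]

    hi0 = float(np.max(y[:3]))
    lo0 = float(np.min(y[-3:]))
    half = (hi0 + lo0) / 2.0
    below = np.nonzero(y <= half)[0]
    tau0 = float(t[below[0]]) if below.size else float(t[t.size // 2])
    p0 = [hi0, max(lo0, 0.0), tau0, max(0.1 * span, 1e-3)]
    bounds = ([0.0, 0.0, t[0] - span, 1e-6],
              [np.inf, np.inf, t[-1] + span, np.inf])
    p0 = np.clip(p0, bounds[0], bounds[1])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(_model, t, y, p0=p0, bounds=bounds,
                                   maxfev=20000)
    except (RuntimeError, ValueError):
        return SigmoidFit(traj.cell_id, np.nan, np.nan, np.nan, np.nan,
                          np.inf, np.nan, converged=False, window=window)

    hi, lo, tau, steep = (float(v) for v in popt)
    if hi < lo:  # reparameterize a fitted rise as its decay mirror
        hi, lo = lo, hi
    resid = y - _model(t, *popt)
    rss = float(resid @ resid)
    var_tau = float(pcov[2, 2])
    sigma_tau = float(np.sqrt(var_tau)) if np.isfinite(var_tau) and \
        var_tau >= 0 else np.inf
    return SigmoidFit(traj.cell_id, hi, lo, tau, steep, sigma_tau, rss,
                      converged=True, window=window)


def filter_fits(fits: list[SigmoidFit], max_ratio: float = 1.0
                ) -> list[SigmoidFit]:
    """Apply the exit-time quality criterion; order preserved.

    A fit is kept iff it converged, sigma_tau < max_ratio * tau, and tau
    lies inside the observed time window.  The default max_ratio of 1
    discards fits whose tau uncertainty is on the order of tau itself.
    """
    if max_ratio <= 0:
        raise ValueError("config error: max_ratio must be > 0")
    out = []
    for f in fits:
        keep = (f.converged
                and np.isfinite(f.sigma_tau)
                and f.sigma_tau < max_ratio * f.tau
                and f.window[0] <= f.tau <= f.window[1])
        out.append(f if f.kept == keep else
                   SigmoidFit(f.cell_id, f.hi, f.lo, f.tau, f.steepness,
                              f.sigma_tau, f.rss, f.converged, kept=keep,
                              window=f.window))
    return out


def normalize_trajectory(traj: Trajectory) -> Trajectory:
    """Divide a trajectory by its first intensity (first point becomes 1)."""
    first = traj.intensities[0]
    if first <= 0:
        raise ValueError("cannot normalize: first intensity must be > 0")
    return Trajectory(traj.cell_id, traj.times, traj.intensities / first)


def fit_table(trajectories: pd.DataFrame, max_ratio: float = 1.0
              ) -> pd.DataFrame:
    """Fit and filter every cell of a long trajectory table.

    Expects columns ``cell_id, t_h, intensity_au``; returns one row per
    cell with the fitted parameters and the ``kept`` flag.
    """
    fits = []
    for cid, grp in trajectories.groupby("cell_id", sort=True):
        grp = grp.sort_values("t_h")
        fits.append(fit_sigmoid(Trajectory(
            str(cid), grp["t_h"].to_numpy(), grp["intensity_au"].to_numpy())))
    fits = filter_fits(fits, max_ratio=max_ratio)
    return pd.DataFrame([dict(
        cell_id=f.cell_id, hi=f.hi, lo=f.lo, tau_h=f.tau,
        steepness_h=f.steepness, sigma_tau_h=f.sigma_tau, rss=f.rss,
        converged=f.converged, kept=f.kept) for f in fits])
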