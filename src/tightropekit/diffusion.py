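"""Mean-squared-displacement analysis of tightrope trajectories.

The time-averaged MSD of a phase of N frames at lag n is

    MSD(n*dt) = 1/(N-n) * sum_{i=1..N-n} (x_{i+n} - x_i)^2,

using all overlapping pairs. Two fits are derived from it:

* a linear 1D-diffusion fit MSD = 2 D (n dt) + y over the first part of
  the curve, giving the diffusion coefficient D (um^2/s) and an
  intercept y that absorbs static localization noise (~2 sigma^2);
* a log-log fit log MSD = alpha * log(n dt) + log(2 D_alpha), giving the
  anomalous diffusion exponent alpha (1 = Brownian, >1 superdiffusive)
  and the generalized coefficient D_alpha (um^2/s^alpha).

Fits with R^2 < 0.8 or using < 10% of the MSD plot are flagged as
rejected — flagged, never silently dropped. Lags averaged over fewer
than 3 pairs are excluded from fitting (the MSD estimator variance
explodes at large lag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitFailureError, InvalidParameterError, TooShortError
from .kymo import Trajectory


@dataclass
class MSDCurve:
    """Time-averaged MSD of one trajectory phase."""

    lags: np.ndarray       # frame counts n = 1..N-1
    lag_times: np.ndarray  # seconds, n * dt
    msd_values: np.ndarray  # um^2
    n_pairs: np.ndarray    # pairs averaged per lag, N - n

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=int)
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.msd_values = np.asarray(self.msd_values, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise InvalidParameterError("lags must be strictly increasing")
        if np.any(self.msd_values < 0):
            raise InvalidParameterError("MSD values must be >= 0")


@dataclass
class DiffusionFit:
    """Linear 1D-diffusion fit of an MSD curve, with rejection flags."""

    diff_coeff: float         # um^2/s
    intercept: float          # um^2
    r_squared: float
    fraction_of_plot_used: float
    accepted: bool
    alpha: float | None = None  # filled by fit_alpha when requested
    particle_id: str = ""

    def __post_init__(self):
        should_accept = (self.r_squared >= 0.8
                         and self.fraction_of_plot_used >= 0.10)
        if self.accepted != should_accept:
            raise InvalidParameterError(
                "accepted flag inconsistent with R^2/fraction rules")


@dataclass
class AlphaFit:
    """Log-log (power-law) fit of an MSD curve."""

    alpha: float
    d_generalized: float  # um^2/s^alpha, from the intercept 2*D*t^alpha
    r_squared: float
    n_lags_used: int


def compute_msd(traj, max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD over lags 1..N-1 of a trajectory phase.

    Accepts a Trajectory (positions in um) or a bare position array
    with uniform sampling; frame spacing comes from the trajectory's
    times. ``max_lag`` truncates the curve (the tail is pure noise and
    quadratic to compute on long phases).
    """
    if isinstance(traj, Trajectory):
        x = traj.positions_um
        dt = traj.frame_interval
        if np.any(np.diff(traj.frames) != 1):
            raise InvalidParameterError("MSD needs contiguous frames")
    else:
        x = np.asarray(traj, dtype=float)
        dt = 1.0
    n = len(x)
    if n < 4:
        raise TooShortError(f"phase of {n} frames is too short for MSD (need >= 4)")
    top = n if max_lag is None else min(n, max_lag + 1)
    lags = np.arange(1, top)
    msd = np.empty(len(lags))
    for i, lag in enumerate(lags):
        d = x[lag:] - x[:-lag]
        msd[i] = np.mean(d * d)
    return MSDCurve(lags=lags, lag_times=lags * dt, msd_values=msd,
                    n_pairs=n - lags)


def _fit_window(msd: MSDCurve, fit_fraction: float, min_lag: int,
                min_pairs: int):
    """Indices of lags inside the fit window, plus fraction of plot used."""
    n_lags = len(msd.lags)
    n_fit = max(3, int(np.floor(fit_fraction * n_lags)))
    sel = (msd.lags >= min_lag) & (msd.lags <= msd.lags[0] + n_fit - 1)
    sel &= msd.n_pairs >= min_pairs
    idx = np.flatnonzero(sel)
    fraction_used = len(idx) / n_lags
    return idx, fraction_used


def fit_diffusion(msd: MSDCurve, fit_fraction: float = 0.25,
                  min_lag: int = 1, min_pairs: int = 3,
                  particle_id: str = "") -> DiffusionFit:
    """Ordinary least squares of MSD on lag time; D = slope / 2.

    The fit window is the first ``fit_fraction`` of lags (at least 3),
    restricted to lags with >= ``min_pairs`` averaging pairs. The
    acceptance flag applies the R^2 >= 0.8 and >= 10%-of-plot rules.
    """
    idx, fraction_used = _fit_window(msd, fit_fraction, min_lag, min_pairs)
    if len(idx) < 3:
        raise FitFailureError("fewer than 3 usable lags in the fit window")
    t = msd.lag_times[idx]
    y = msd.msd_values[idx]
    if np.ptp(t) == 0 or np.ptp(y) == 0:
        raise FitFailureError("degenerate (zero-variance) fit window")
    slope, intercept, r, _, _ = stats.linregress(t, y)
    r2 = float(r * r) if np.isfinite(r) else 0.0
    accepted = bool(r2 >= 0.8 and fraction_used >= 0.10)
    return DiffusionFit(diff_coeff=float(slope) / 2.0, intercept=float(intercept),
                        r_squared=r2, fraction_of_plot_used=float(fraction_used),
                        accepted=accepted, particle_id=particle_id)


def fit_alpha(msd: MSDCurve, fit_fraction: float = 0.25,
              min_lag: int = 1, min_pairs: int = 3) -> AlphaFit:
    """Anomalous exponent from a log-log regression of the MSD.

    Slope of log(MSD) on log(lag time) over the fit window; the
    intercept gives the generalized coefficient via MSD = 2 D t^alpha.
    ``min_lag`` can skip the first lags when a localization-noise floor
    dominates them.
    """
    idx, _ = _fit_window(msd, fit_fraction, min_lag, min_pairs)
    if len(idx) < 3:
        raise FitFailureError("fewer than 3 usable lags in the fit window")
    y = msd.msd_values[idx]
    if np.any(y <= 0):
        raise InvalidParameterError(
            "non-positive MSD in fit window (stationary phase?)")
    lt = np.log(msd.lag_times[idx])
    ly = np.log(y)
    slope, intercept, r, _, _ = stats.linregress(lt, ly)
    return AlphaFit(alpha=float(slope), d_generalized=float(np.exp(intercept) / 2.0),
                    r_squared=float(r * r), n_lags_used=len(idx))


def ensemble_msd(curves, n_lags: int | None = None) -> MSDCurve:
    """Average time-averaged MSD curves across trajectories.

    Lags present in every curve (up to ``n_lags``) are averaged with
    equal weight per trajectory; ``n_pairs`` reports the summed pair
    counts. Ensemble averaging shrinks the single-trajectory MSD noise
    that biases per-trajectory log-log fits.
    """
    curves = list(curves)
    if not curves:
        raise InvalidParameterError("no MSD curves")
    max_common = min(len(c.lags) for c in curves)
    if n_lags is not None:
        max_common = min(max_common, n_lags)
    lags = curves[0].lags[:max_common]
    dt = curves[0].lag_times[0] / curves[0].lags[0]
    vals = np.mean([c.msd_values[:max_common] for c in curves], axis=0)
    pairs = np.sum([c.n_pairs[:max_common] for c in curves], axis=0)
    return MSDCurve(lags=lags, lag_times=lags * dt, msd_values=vals,
                    n_pairs=pairs)


def summarize_diffusion(fits, labels) -> dict:
    """Group means of alpha and log10 D over accepted fits, plus a
    two-tailed two-sample Student's t-test between the first two groups.

    ``fits`` is a list of DiffusionFit (with ``alpha`` populated);
    ``labels`` assigns each fit to a condition. Rejected fits are
    excluded; a group with < 2 accepted fits raises an error naming it.
    """
    fits = list(fits)
    labels = list(labels)
    if len(fits) != len(labels):
        raise InvalidParameterError("fits and labels must align")
    groups: dict[str, list] = {}
    for f, lab in zip(fits, labels):
        if f.accepted:
            groups.setdefault(lab, []).append(f)
    rows = []
    for lab in dict.fromkeys(labels):
        g = groups.get(lab, [])
        if len(g) < 2:
            raise InvalidParameterError(
                f"group {lab!r} has {len(g)} accepted fits (need >= 2)")
        alphas = np.array([f.alpha for f in g], dtype=float)
        logd = np.log10([f.diff_coeff for f in g])
        rows.append({
            "group": lab, "n_accepted": len(g),
            "alpha_mean": float(np.nanmean(alphas)),
            "alpha_sd": float(np.nanstd(alphas, ddof=1)),
            "log10D_mean": float(np.mean(logd)),
            "log10D_sd": float(np.std(logd, ddof=1)),
        })
    summary = pd.DataFrame(rows)
    out = {"summary": summary}
    names = list(dict.fromkeys(labels))
    if len(names) >= 2:
        ga, gb = groups[names[0]], groups[names[1]]
        t_a, p_a = stats.ttest_ind([f.alpha for f in ga], [f.alpha for f in gb])
        t_d, p_d = stats.ttest_ind(np.log10([f.diff_coeff for f in ga]),
                                   np.log10([f.diff_coeff for f in gb]))
        out["comparison"] = {
            "groups": (names[0], names[1]),
            "alpha": {"t": float(t_a), "p": float(p_a)},
            "log10D": {"t": float(t_d), "p": float(p_d)},
        }
    return out


__all__ = [
    "MSDCurve", "DiffusionFit", "AlphaFit", "compute_msd", "fit_diffusion",
    "fit_alpha", "ensemble_msd", "summarize_diffusion",
]
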