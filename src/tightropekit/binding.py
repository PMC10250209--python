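"""Tight-binding (ligand-depletion) isotherm model and apparent-Kd fitting.

Electrophoretic mobility shift assays here are run with the DNA probe at
8 nM — the same order as the dissociation constants being measured — so
the usual hyperbolic (Langmuir) isotherm is invalid: bound protein
depletes the free pool. The quadratic tight-binding solution of the
mass-action equilibrium is used instead,

    % bound = 100 * ((D + P + Kd) - sqrt((D + P + Kd)^2 - 4 D P)) / (2 D)

with D the total DNA concentration, P the total protein concentration
and Kd the apparent equilibrium dissociation constant (all nM). Fits
constrain D to its known value and the saturation plateau to 100%,
leaving Kd as the single free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InvalidParameterError


@dataclass
class IsothermData:
    """Concentration series of percent DNA bound.

    ``pct_bound`` is a (n_replicates, n_concs) matrix; a 1D series is
    accepted and treated as a single replicate.
    """

    protein_concs: np.ndarray
    pct_bound: np.ndarray
    dna_conc_total: float = 8.0

    def __post_init__(self):
        self.protein_concs = np.asarray(self.protein_concs, dtype=float)
        self.pct_bound = np.atleast_2d(np.asarray(self.pct_bound, dtype=float))
        if self.protein_concs.ndim != 1:
            raise InvalidParameterError("protein_concs must be 1D")
        if np.any(self.protein_concs < 0):
            raise InvalidParameterError("concentrations must be non-negative")
        if np.any(np.diff(self.protein_concs) <= 0):
            raise InvalidParameterError("concentrations must be strictly increasing")
        if self.pct_bound.shape[1] != self.protein_concs.size:
            raise InvalidParameterError("pct_bound shape does not match concentrations")
        if np.any(self.pct_bound < 0) or np.any(self.pct_bound > 100):
            raise InvalidParameterError("pct_bound must lie in [0, 100]")
        if self.dna_conc_total <= 0:
            raise InvalidParameterError("dna_conc_total must be > 0")


@dataclass
class BindingFit:
    """Result of a one-parameter quadratic-isotherm fit."""

    kd_apparent: float
    kd_stderr: float
    r_squared: float
    constraints_record: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kd_apparent <= 0:
            raise InvalidParameterError("kd_apparent must be > 0")


def fraction_bound_model(p_total, d_total, kd):
    """Percent DNA bound under the quadratic tight-binding model.

    Parameters are total protein, total DNA and apparent Kd, all in the
    same concentration unit (nM throughout this package). Vectorized
    over ``p_total``.
    """
    p = np.asarray(p_total, dtype=float)
    if np.any(p < 0):
        raise InvalidParameterError("p_total must be non-negative")
    if d_total <= 0:
        raise InvalidParameterError("d_total must be > 0")
    if kd < 0:
        raise InvalidParameterError("kd must be non-negative")
    s = d_total + p + kd
    disc = s * s - 4.0 * d_total * p
    # exact arithmetic keeps disc >= (D-P)^2 + Kd*(...) >= 0; trap rounding
    if np.any(disc < -1e-9 * np.maximum(s * s, 1.0)):
        raise FitFailureError("negative discriminant in quadratic model")
    disc = np.maximum(disc, 0.0)
    out = 100.0 * (s - np.sqrt(disc)) / (2.0 * d_total)
    return float(out) if np.isscalar(p_total) else out


def fit_kd(data: IsothermData, p0: float | None = None) -> BindingFit:
    """Fit the apparent Kd by nonlinear least squares.

    Only Kd floats: DNA is fixed at ``data.dna_conc_total`` and the
    plateau at 100% bound. Replicates enter the fit jointly (every point
    weighted equally) rather than being averaged first. Positivity of Kd
    is enforced by fitting log(Kd). The initial guess is the protein
    concentration nearest half-maximal binding unless given.
    """
    concs = data.protein_concs
    if np.unique(concs).size < 4:
        raise InvalidParameterError("need >= 4 distinct protein concentrations")
    y = data.pct_bound
    n_rep = y.shape[0]
    x = np.tile(concs, n_rep)
    yy = y.ravel()
    if np.all(yy == 0):
        raise FitFailureError("all observed binding is zero; nothing to fit")

    if p0 is None:
        mean_y = y.mean(axis=0)
        p0 = float(concs[np.argmin(np.abs(mean_y - 0.5 * mean_y.max()))])
        p0 = max(p0, 1e-6)

    d = data.dna_conc_total

    def model(p, log_kd):
        return fraction_bound_model(p, d, np.exp(log_kd))

    try:
        popt, pcov = curve_fit(model, x, yy, p0=[np.log(p0)], maxfev=10000)
    except RuntimeError as exc:
        raise FitFailureError(f"Kd fit did not converge: {exc}") from exc

    kd = float(np.exp(popt[0]))
    se_log = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    kd_se = kd * se_log  # delta method on the log parameterization
    pred = model(x, popt[0])
    ss_res = float(np.sum((yy - pred) ** 2))
    ss_tot = float(np.sum((yy - yy.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return BindingFit(
        kd_apparent=kd,
        kd_stderr=kd_se,
        r_squared=r2,
        constraints_record={"dna_conc_nM": d, "plateau_pct": 100.0,
                            "n_points": int(yy.size), "initial_guess_nM": p0},
    )


def specificity_ratio(kd_a: float, kd_b: float) -> float:
    """Fold difference between two dissociation constants, one decimal."""
    if kd_a <= 0 or kd_b <= 0:
        raise InvalidParameterError("dissociation constants must be > 0")
    return round(kd_a / kd_b, 1)


def fraction_bound_from_bands(bound_intensities, total_intensity: float,
                              background: float = 0.0) -> float:
    """Percent bound from native-gel band intensities.

    Sums the shifted (bound) band intensities, subtracts a per-lane
    background from both the bound sum and the lane total, and reports
    the bound share of the lane, clipped to [0, 100].
    """
    if background < 0:
        raise InvalidParameterError("background must be non-negative")
    if total_intensity <= background:
        raise InvalidParameterError("total intensity must exceed background")
    bound = float(np.sum(np.asarray(bound_intensities, dtype=float)))
    pct = 100.0 * (bound - background) / (total_intensity - background)
    return float(np.clip(pct, 0.0, 100.0))


def displacement_curve(competitor_concs, fraction_tables) -> "pandas.DataFrame":
    """Species-bound percentage versus competitor concentration.

    ``fraction_tables`` maps species name -> per-concentration bound
    fractions (0..1), aligned with ``competitor_concs``. Returns a tidy
    table (competitor_nM, species, pct_bound). Monotonicity is not
    enforced — the curve reports the data as observed.
    """
    import pandas as pd

    concs = np.asarray(competitor_concs, dtype=float)
    rows = []
    for species, fracs in fraction_tables.items():
        fracs = np.asarray(fracs, dtype=float)
        if fracs.size != concs.size:
            raise InvalidParameterError(
                f"species {species!r}: {fracs.size} fractions for {concs.size} concentrations")
        if np.any(fracs < 0) or np.any(fracs > 1):
            raise InvalidParameterError("fractions must lie in [0, 1]")
        for c, f in zip(concs, fracs):
            rows.append({"competitor_nM": c, "species": species,
                         "pct_bound": 100.0 * f})
    return pd.DataFrame(rows)


__all__ = [
    "IsothermData", "BindingFit", "fraction_bound_model", "fit_kd",
    "specificity_ratio", "fraction_bound_from_bands", "displacement_curve",
]
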