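"""Single-site affinity estimation and affinity-group comparison.

The one-site saturation model y = Bmax*x/(Kd + x) is fit by weighted nonlinear
least squares to mobility-shift binding curves (y = fraction of complexed DNA)
and, with Bmax reinterpreted as Rmax in response units, to steady-state SPR
responses.  Both routes share one fitting core, so identical inputs give
identical estimates.

Also provided: the active-fraction determination from a stoichiometric-binding
experiment (DNA in molar excess, so every active protein molecule is driven
into a 1:1 complex and the bound-complex/total-protein ratio reads out the
active fraction of the preparation), and fixed-effects group comparisons of
replicate Kd values (one-way ANOVA or two-sample t test; raw p-values, no
multiplicity correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "BindingCurve",
    "HyperbolaFit",
    "SPRSeries",
    "ActiveFraction",
    "HyperbolicBindingModel",
    "fit_hyperbola",
    "fit_spr_steady_state",
    "active_fraction",
    "compare_affinity_groups",
]


@dataclass(frozen=True)
class BindingCurve:
    """One titration replicate: protein concentrations x (uM) vs bound fraction y."""

    x: np.ndarray
    y: np.ndarray
    replicate: object = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.any(self.x < 0):
            raise ValueError("concentrations must be >= 0")
        if not np.any(self.x > 0):
            raise ValueError("at least one concentration must be > 0")


@dataclass(frozen=True)
class SPRSeries:
    """Steady-state SPR responses Req (RU) at analyte concentrations (uM)."""

    conc: np.ndarray
    Req: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "conc", np.asarray(self.conc, dtype=float))
        object.__setattr__(self, "Req", np.asarray(self.Req, dtype=float))
        if self.conc.shape != self.Req.shape or self.conc.ndim != 1:
            raise ValueError("conc and Req must be 1-D arrays of equal length")
        if len(np.unique(self.conc)) != len(self.conc):
            raise ValueError("analyte concentrations must be distinct")


@dataclass(frozen=True)
class HyperbolaFit:
    """One-site saturation fit: Kd (uM) and Bmax (fraction, or RU for SPR)."""

    Kd: float
    Bmax: float
    se_Kd: float
    se_Bmax: float
    rss: float
    converged: bool
    poorly_constrained: bool = False


def _hyperbola(x: np.ndarray, kd: float, bmax: float) -> np.ndarray:
    return bmax * x / (kd + x)


class HyperbolicBindingModel(RegressorMixin, BaseEstimator):
    """One-site saturation binding estimator, y(x) = Bmax*x/(Kd + x).

    Parameters
    ----------
    fix_bmax : float or None
        Fix the plateau at this value instead of fitting it (e.g. 1.0 when
        the bound fraction is known to saturate completely).
    weights : array-like or None
        Per-point weights (inverse variances); unit weights when None.

    Attributes
    ----------
    Kd_ : float
        Half-saturation concentration, same units as x (uM here).
    Bmax_ : float
        Fitted (or fixed) plateau.
    se_Kd_, se_Bmax_ : float
        Asymptotic standard errors (se_Bmax_ is 0 when Bmax is fixed).
    rss_ : float
    converged_ : bool
    poorly_constrained_ : bool
        True when Kd_ falls outside (min positive x / 100, 100 * max x),
        i.e. the grid barely brackets the half-saturation point.
    """

    def __init__(self, fix_bmax: float | None = None, weights=None):
        self.fix_bmax = fix_bmax
        self.weights = weights

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(x) != len(y):
            raise ValueError("X and y have different lengths")
        if len(np.unique(x)) < 3:
            raise ValueError("need at least 3 distinct concentrations")
        if np.max(y) <= 0:
            raise ValueError("all responses are zero: nothing to fit")
        sigma = None
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            sigma = 1.0 / np.sqrt(w)
        # Moment-style initial guesses: plateau from the top of the curve,
        # Kd from the concentration nearest half-plateau.
        b0 = float(np.max(y)) * 1.05 if self.fix_bmax is None else self.fix_bmax
        kd0 = float(x[np.argmin(np.abs(y - b0 / 2.0))])
        kd0 = kd0 if kd0 > 0 else float(np.median(x[x > 0]))

        if self.fix_bmax is None:
            popt, pcov = curve_fit(
                _hyperbola, x, y, p0=[kd0, b0], sigma=sigma,
                absolute_sigma=False, maxfev=20000,
            )
            kd, bmax = popt
            se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
            se_kd, se_bmax = float(se[0]), float(se[1])
        else:
            fixed = float(self.fix_bmax)
            popt, pcov = curve_fit(
                lambda xx, kd: _hyperbola(xx, kd, fixed), x, y, p0=[kd0],
                sigma=sigma, absolute_sigma=False, maxfev=20000,
            )
            kd, bmax = float(popt[0]), fixed
            se_kd, se_bmax = float(np.sqrt(max(pcov[0, 0], 0.0))), 0.0
        if not (np.isfinite(kd) and kd > 0 and bmax > 0):
            raise RuntimeError(f"fit did not converge to positive parameters: "
                               f"Kd={kd}, Bmax={bmax}")
        self.Kd_ = float(kd)
        self.Bmax_ = float(bmax)
        self.se_Kd_ = se_kd
        self.se_Bmax_ = se_bmax
        resid = y - _hyperbola(x, kd, bmax)
        self.rss_ = float(np.sum(resid**2 if sigma is None else (resid / sigma) ** 2))
        self.converged_ = True
        xpos = x[x > 0]
        self.poorly_constrained_ = not (
            np.min(xpos) / 100.0 < self.Kd_ < 100.0 * np.max(x)
        )
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return _hyperbola(x, self.Kd_, self.Bmax_)

    def _as_result(self) -> HyperbolaFit:
        return HyperbolaFit(
            Kd=self.Kd_, Bmax=self.Bmax_, se_Kd=self.se_Kd_, se_Bmax=self.se_Bmax_,
            rss=self.rss_, converged=self.converged_,
            poorly_constrained=self.poorly_constrained_,
        )


def fit_hyperbola(
    curve: BindingCurve, *, fix_bmax: float | None = None, weights=None
) -> HyperbolaFit:
    """Fit the one-site saturation model to a mobility-shift binding curve."""
    est = HyperbolicBindingModel(fix_bmax=fix_bmax, weights=weights)
    return est.fit(curve.x, curve.y)._as_result()


def fit_spr_steady_state(
    series: SPRSeries, *, fix_bmax: float | None = None, weights=None
) -> HyperbolaFit:
    """Fit the one-site saturation model to steady-state SPR responses.

    Identical core to :func:`fit_hyperbola`; Bmax is the maximal response
    Rmax in response units.
    """
    est = HyperbolicBindingModel(fix_bmax=fix_bmax, weights=weights)
    return est.fit(series.conc, series.Req)._as_result()


@dataclass(frozen=True)
class ActiveFraction:
    fraction: float
    clipped: bool  # True when the raw ratio exceeded 1 and was clipped


def active_fraction(bound_complex: float, protein_total: float) -> ActiveFraction:
    """Active fraction of a protein preparation from stoichiometric binding.

    With DNA in molar excess and 1:1 complex stoichiometry, every active
    protein molecule is complexed, so the ratio bound_complex/protein_total
    (both in uM) is the active fraction.  A ratio above 1 (quantification
    noise) is clipped to 1 and flagged.
    """
    if protein_total <= 0:
        raise ValueError(f"protein_total must be > 0, got {protein_total}")
    if bound_complex < 0:
        raise ValueError(f"bound_complex must be >= 0, got {bound_complex}")
    ratio = bound_complex / protein_total
    if ratio > 1.0:
        return ActiveFraction(fraction=1.0, clipped=True)
    return ActiveFraction(fraction=ratio, clipped=False)


def compare_affinity_groups(
    groups: Sequence[Sequence[float]], mode: str = "anova"
) -> tuple[float, float]:
    """Compare groups of replicate Kd values.

    mode="anova": one-way fixed-effects F test across >= 2 groups.
    mode="ttest": two-sample equal-variance t test (exactly 2 groups);
    mode="welch": the unequal-variance variant.
    Returns (statistic, p_value); p-values are raw (no multiplicity
    correction is applied).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 replicate values")
    if mode == "anova":
        stat, p = stats.f_oneway(*groups)
    elif mode in ("ttest", "welch"):
        if len(groups) != 2:
            raise ValueError(f"mode={mode!r} requires exactly 2 groups")
        stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=(mode == "ttest"))
    else:
        raise ValueError(f"mode must be 'anova', 'ttest' or 'welch', got {mode!r}")
    return float(stat), float(p)
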