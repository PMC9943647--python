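"""Dissociation-chase kinetics with a background floor and censoring rule.

After a large excess of unlabelled competitor DNA is added at t = 0,
rebinding of the labelled probe is suppressed and the labelled complex decays
as f(t) = (f0 - bg)*exp(-koff*t) + bg, where bg is the fraction of probe that
complexes under full competition (measured in a control lane and subtracted,
not fitted).  The half-life is t_half = ln(2)/koff.

Fast-dissociating complexes can be gone by the first post-competition sample;
in that case no rate is identifiable and the honest statement is a censored
upper bound: t_half <= t1, the first sampling time.  The censoring rule takes
precedence — whenever f(t1) <= bg no exponential fit is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = [
    "DecaySeries",
    "DissociationResult",
    "DissociationDecayModel",
    "fit_dissociation",
    "half_life",
]


@dataclass(frozen=True)
class DecaySeries:
    """Chase time course: times t (s) vs fraction of labelled DNA in complex."""

    t: np.ndarray
    f: np.ndarray
    background: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "f", np.asarray(self.f, dtype=float))
        if self.t.shape != self.f.shape or self.t.ndim != 1 or len(self.t) < 1:
            raise ValueError("t and f must be 1-D arrays of equal nonzero length")
        if np.any(self.t < 0) or np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be >= 0 and strictly increasing")
        if np.any(self.f < 0) or np.any(self.f > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 <= self.background < 1.0:
            raise ValueError(f"background must be in [0, 1), got {self.background}")


@dataclass(frozen=True)
class DissociationResult:
    """Either a fitted first-order rate or a censored half-life upper bound."""

    t_half: float  # s; the bound t1 when is_upper_bound
    is_upper_bound: bool
    background_used: float
    koff: float | None = None  # s^-1; absent for censored results


def half_life(koff: float) -> float:
    """First-order half-life ln(2)/koff (s) for a rate koff (s^-1)."""
    if koff <= 0:
        raise ValueError(f"koff must be > 0, got {koff}")
    return math.log(2.0) / koff


class DissociationDecayModel(BaseEstimator):
    """Exponential-decay estimator with background floor and censoring.

    Attributes after fit: ``koff_`` (None when censored), ``t_half_``,
    ``is_upper_bound_``, ``f0_``.
    """

    def __init__(self, background: float = 0.0):
        self.background = background

    def fit(self, X, y):
        series = DecaySeries(np.asarray(X).reshape(-1), np.asarray(y).reshape(-1),
                             background=self.background)
        t, f, bg = series.t, series.f, series.background
        rises = f[1:] - f[:-1]
        prev = np.maximum(f[:-1], 1e-12)
        if np.any(f[1:] / prev > 2.0) and np.any(rises > 0.05):
            raise ValueError(
                "data-quality error: complexed fraction rises more than 2-fold "
                "during the chase"
            )
        if f[0] <= bg:
            if np.all(f <= bg) and len(t) >= 1:
                pass  # censored at the first sample; t1 carries the bound
            self.koff_ = None
            self.f0_ = None
            self.t_half_ = float(t[0])
            self.is_upper_bound_ = True
            return self

        def model(tt, koff, f0):
            return (f0 - bg) * np.exp(-koff * tt) + bg

        koff0 = 1.0 / max(t[-1], 1e-9)
        above = f > bg
        if np.sum(above) >= 2:
            # log-linear slope on background-subtracted points as initial rate
            tt, ff = t[above], np.log(f[above] - bg)
            slope = np.polyfit(tt, ff, 1)[0]
            if slope < 0:
                koff0 = -slope
        popt, _ = curve_fit(model, t, f, p0=[koff0, f[0]], maxfev=20000)
        koff = float(popt[0])
        if not (np.isfinite(koff) and koff > 0):
            raise RuntimeError(f"decay fit returned non-positive rate koff={koff}")
        self.koff_ = koff
        self.f0_ = float(popt[1])
        self.t_half_ = half_life(koff)
        self.is_upper_bound_ = False
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        if self.is_upper_bound_:
            raise ValueError("censored result: no decay curve was fitted")
        bg = self.background
        return (self.f0_ - bg) * np.exp(-self.koff_ * t) + bg


def fit_dissociation(series: DecaySeries) -> DissociationResult:
    """Analyse one chase series.

    If the complexed fraction is already at or below background at the first
    sampling time t1, returns a censored result with t_half = t1 (upper
    bound); otherwise fits the background-floored exponential and returns
    koff with t_half = ln(2)/koff.
    """
    est = DissociationDecayModel(background=series.background)
    est.fit(series.t, series.f)
    return DissociationResult(
        t_half=est.t_half_,
        is_upper_bound=est.is_upper_bound_,
        background_used=series.background,
        koff=est.koff_,
    )
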