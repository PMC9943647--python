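"""Macroscopic-constant estimation from three-site titration fractions.

A mobility-shift titration of a three-site DNA against increasing protein
yields, at each protein concentration, the fractions of DNA in the free state
and in the C1, C2, C3 complexes (exactly 1, 2, 3 sites occupied).  Only the
macroscopic constants (K1, K2, K3) of the binding polynomial are identifiable
from such data; they are estimated here by nonlinear least squares on the
ligation-state fractions, with positivity enforced by fitting log10(Ki) and a
multistart schedule guarding against local minima.

Cooperativity of the second and third binding events is then judged from the
ratio statistics r2 = 3*K2/K1^2 and r3 = 3*K3/(K1*K2): the event is called
cooperative only when the bootstrap lower 2.5% bound of the ratio exceeds 1
(a deliberately conservative rule; comparing the ratio mean to 1 ignores its
sampling noise).  When neither event is cooperative, the identical-site
reduction K1=3Ka, K2=3Ka^2, K3=3Ka^3 condenses the fit into a single per-site
association constant Ka and dissociation constant Kd = 1/Ka.

Free vs total ligand: the fit by default identifies the free protein
concentration with the total (valid when DNA is far below the protein
concentrations, as in the emulated experiment: 20 nM DNA against >= 100 nM
protein, worst-case depletion ~6%).  ``ligand="exact"`` instead solves the
scalar mass balance L + D_tot*(theta1 + 2*theta2 + 3*theta3) = P_tot at every
grid point by bracketed root finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from sklearn.base import BaseEstimator

from .binding_model import (
    CooperativityRatios,
    MacroscopicConstants,
    UndefinedRatioError,
    cooperativity_ratios,
    ka_from_macro,
    species_fractions,
)

__all__ = [
    "TitrationDataset",
    "MultisiteFit",
    "CooperativityReport",
    "MultisiteBindingModel",
    "IdentifiabilityError",
    "ConvergenceError",
    "CooperativeReductionError",
    "fit_macroscopic",
    "bootstrap_uncertainty",
    "assess_cooperativity",
]

FRACTION_SUM_SLACK = 0.02  # gel-quantification tolerance on per-row sum of fractions


class IdentifiabilityError(ValueError):
    """The titration carries no binding signal to constrain the constants."""


class ConvergenceError(RuntimeError):
    """No multistart initialization converged."""


class CooperativeReductionError(ValueError):
    """Identical-site Ka reduction requested despite a cooperative verdict."""


TITRATION_COLUMNS = ("replicate", "protein_uM", "dna_uM", "f0", "f1", "f2", "f3")


@dataclass
class TitrationDataset:
    """Replicated ligation-state fractions over a protein-concentration grid.

    Wraps a DataFrame with columns ``replicate, protein_uM, dna_uM, f0..f3``.
    On construction every fraction must lie in [0, 1] and each row's sum must
    be within ±0.02 of 1; rows are then renormalized to sum exactly to 1.
    Each replicate needs at least 4 distinct protein concentrations.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in TITRATION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"titration table is missing columns: {missing}")
        df = df.loc[:, list(TITRATION_COLUMNS)].reset_index(drop=True).copy()
        fr = df[["f0", "f1", "f2", "f3"]].to_numpy(dtype=float)
        if np.any(fr < 0) or np.any(fr > 1):
            bad = int(np.argwhere((fr < 0) | (fr > 1))[0, 0])
            raise ValueError(f"fraction outside [0, 1] at row {bad}")
        sums = fr.sum(axis=1)
        off = np.abs(sums - 1.0) > FRACTION_SUM_SLACK
        if np.any(off):
            bad = int(np.argmax(off))
            raise ValueError(
                f"row {bad}: fractions sum to {sums[bad]:.4f}, outside "
                f"1 ± {FRACTION_SUM_SLACK}"
            )
        df[["f0", "f1", "f2", "f3"]] = fr / sums[:, None]
        for rep, grp in df.groupby("replicate"):
            if grp["protein_uM"].nunique() < 4:
                raise ValueError(
                    f"replicate {rep!r} has fewer than 4 distinct protein concentrations"
                )
        self.table = df

    @property
    def replicate_ids(self) -> list:
        return list(dict.fromkeys(self.table["replicate"]))

    def replicates(self) -> Iterator[tuple[object, "TitrationDataset"]]:
        for rep in self.replicate_ids:
            yield rep, TitrationDataset(self.table[self.table["replicate"] == rep])

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class MultisiteFit:
    """Result of one macroscopic-constant fit."""

    K: MacroscopicConstants
    rss: float
    converged: bool
    n_restarts: int
    se: tuple[float, float, float]


def _free_ligand(p_tot: float, dna_uM: float, K: MacroscopicConstants) -> float:
    """Solve L + dna*(mean occupied sites)(L) = p_tot for free ligand L."""
    if p_tot == 0.0:
        return 0.0

    def balance(L: float) -> float:
        return L + dna_uM * species_fractions(L, K).bound_sites_per_dna - p_tot

    return brentq(balance, 0.0, p_tot, xtol=1e-14, rtol=1e-14)


class MultisiteBindingModel(BaseEstimator):
    """Least-squares estimator for the three macroscopic binding constants.

    Parameters
    ----------
    ligand : {"total", "exact"}
        How free protein is obtained from total: identified with total
        (default) or solved from the mass balance using ``dna_uM``.
    n_restarts : int
        Number of multistart initializations (log-uniform per-site Ka grid
        plus a data-driven guess).
    weights : array-like or None
        Per-point weights applied to all three complex-fraction residuals
        (e.g. inverse variances); unit weights when None.

    Attributes
    ----------
    K_ : MacroscopicConstants
        Fitted constants (uM^-1, uM^-2, uM^-3).
    se_ : ndarray of shape (3,)
        Delta-method standard errors of (K1, K2, K3).
    rss_ : float
        Residual sum of squares at the optimum.
    converged_ : bool
    n_restarts_used_ : int
    """

    def __init__(self, ligand: str = "total", n_restarts: int = 8, weights=None):
        self.ligand = ligand
        self.n_restarts = n_restarts
        self.weights = weights

    # log10 per-site Ka values seeding the (3a, 3a^2, 3a^3)-shaped starts
    _START_LOG_KA = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)

    def _starts(self, x: np.ndarray) -> list[np.ndarray]:
        starts = []
        with np.errstate(divide="ignore"):
            ka_data = 1.0 / np.median(x[x > 0])
        for log_ka in (*self._START_LOG_KA, np.log10(ka_data)):
            a = 10.0**log_ka
            starts.append(np.log10([3 * a, 3 * a**2, 3 * a**3]))
        return starts[: self.n_restarts]

    def _thetas(self, logK: np.ndarray, p_tot: np.ndarray, dna: np.ndarray) -> np.ndarray:
        K = MacroscopicConstants(*10.0**logK)
        out = np.empty((len(p_tot), 4))
        for i, (p, d) in enumerate(zip(p_tot, dna)):
            L = _free_ligand(p, d, K) if self.ligand == "exact" else p
            out[i] = tuple(species_fractions(L, K))
        return out

    def fit(self, X, y, dna_uM=None):
        """Fit K1..K3 to observed complex fractions.

        Parameters
        ----------
        X : array-like of shape (n,) or (n, 1)
            Total protein concentrations (uM).
        y : array-like of shape (n, 3) or (n, 4)
            Observed fractions (f1, f2, f3) or (f0, f1, f2, f3); f0 is
            dropped (fixed by normalization).
        dna_uM : float, array-like or None
            Total DNA concentration(s), required for ``ligand="exact"``.
        """
        if self.ligand not in ("total", "exact"):
            raise ValueError(f"ligand must be 'total' or 'exact', got {self.ligand!r}")
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] not in (3, 4):
            raise ValueError("y must have shape (n, 3) or (n, 4)")
        f = y[:, -3:]
        if len(x) != len(f):
            raise ValueError("X and y have different lengths")
        if np.any(x < 0):
            raise ValueError("protein concentrations must be >= 0")
        if self.ligand == "exact" and dna_uM is None:
            raise ValueError("ligand='exact' requires dna_uM")
        dna = np.broadcast_to(
            np.asarray(0.0 if dna_uM is None else dna_uM, dtype=float), x.shape
        )
        if np.max(f.sum(axis=1)) < 0.02:
            raise IdentifiabilityError(
                "no binding signal: complex fractions are ~0 at every concentration"
            )
        w = np.ones(len(x)) if self.weights is None else np.asarray(self.weights, float)
        sw = np.sqrt(np.repeat(w, 3))

        def residuals(logK: np.ndarray) -> np.ndarray:
            th = self._thetas(logK, x, dna)
            return sw * (th[:, 1:] - f).ravel()

        # log10-space box keeps K within 1e-12..1e12 of 1 uM^-i; generous for
        # any resolvable affinity while preventing overflow during line search
        bounds = (np.full(3, -12.0), np.full(3, 12.0))
        best = None
        for start in self._starts(x):
            try:
                sol = least_squares(
                    residuals, np.clip(start, -11.9, 11.9), bounds=bounds,
                    method="trf", x_scale="jac", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            if not sol.success or not np.all(np.isfinite(sol.x)):
                continue
            rss = float(2.0 * sol.cost)
            if (
                best is None
                or rss < best.rss - 1e-9
                or (abs(rss - best.rss) < 1e-9
                    and np.linalg.norm(sol.x) < np.linalg.norm(best.sol.x))
            ):
                best = _Best(sol=sol, rss=rss)
        if best is None:
            raise ConvergenceError(
                f"no convergence after {self.n_restarts} multistart initializations"
            )
        sol = best.sol
        self.log10K_ = sol.x
        self.K_ = MacroscopicConstants(*10.0**sol.x)
        self.rss_ = best.rss
        self.converged_ = True
        self.n_restarts_used_ = self.n_restarts
        self.se_ = self._standard_errors(sol, n_res=3 * len(x))
        self._dna_ = dna
        return self

    def _standard_errors(self, sol, n_res: int) -> np.ndarray:
        dof = n_res - len(sol.x)
        if dof <= 0:
            return np.full(3, np.nan)
        J = sol.jac
        try:
            cov_log = np.linalg.inv(J.T @ J) * (2.0 * sol.cost / dof)
        except np.linalg.LinAlgError:
            return np.full(3, np.nan)
        k = 10.0**sol.x
        return k * np.log(10.0) * np.sqrt(np.clip(np.diag(cov_log), 0.0, None))

    def predict(self, X, dna_uM=None):
        """Predicted (theta0..theta3) at total protein concentrations X."""
        x = np.asarray(X, dtype=float).reshape(-1)
        dna = np.broadcast_to(
            np.asarray(0.0 if dna_uM is None else dna_uM, dtype=float), x.shape
        )
        return self._thetas(self.log10K_, x, dna)


@dataclass
class _Best:
    sol: object
    rss: float


def fit_macroscopic(
    data: TitrationDataset,
    *,
    ligand: str = "total",
    n_restarts: int = 8,
    weights=None,
) -> MultisiteFit:
    """Fit (K1, K2, K3) to a single-replicate titration dataset."""
    if len(data.replicate_ids) != 1:
        raise ValueError(
            f"fit_macroscopic takes one replicate at a time, got {data.replicate_ids}"
        )
    df = data.table
    est = MultisiteBindingModel(ligand=ligand, n_restarts=n_restarts, weights=weights)
    est.fit(
        df["protein_uM"].to_numpy(),
        df[["f1", "f2", "f3"]].to_numpy(),
        dna_uM=df["dna_uM"].to_numpy(),
    )
    return MultisiteFit(
        K=est.K_,
        rss=est.rss_,
        converged=est.converged_,
        n_restarts=est.n_restarts_used_,
        se=tuple(est.se_),
    )


def bootstrap_uncertainty(
    data: TitrationDataset,
    n_boot: int = 1000,
    seed: int | None = None,
    *,
    ligand: str = "total",
) -> dict:
    """Case-resampling bootstrap of the reported across-replicate statistics.

    Each iteration resamples concentration points (rows) with replacement
    within every replicate, refits each replicate separately (warm-started at
    its full-data estimate), and records the across-replicate mean of K1, K2,
    K3, r2, r3 and Ka — the same statistics the cooperativity report quotes,
    so their bootstrap spread reflects both point noise and its propagation
    through per-replicate fitting and averaging.  Iterations in which any
    replicate fails to converge are dropped and counted in ``n_failed``;
    undefined ratios or Ka enter an iteration's mean as NaN.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if seed is None:
        raise ValueError("a seed is required (no silent nondeterminism)")
    rng = np.random.default_rng(seed)
    df = data.table
    x = df["protein_uM"].to_numpy()
    f = df[["f1", "f2", "f3"]].to_numpy()
    dna = df["dna_uM"].to_numpy()
    rep_labels = df["replicate"].to_numpy()
    groups = [np.flatnonzero(rep_labels == r) for r in data.replicate_ids]

    starts = []
    for g in groups:
        full = MultisiteBindingModel(ligand=ligand).fit(x[g], f[g], dna_uM=dna[g])
        starts.append(full.log10K_)

    out = {k: [] for k in ("K1", "K2", "K3", "r2", "r3", "Ka")}
    n_failed = 0
    for _ in range(n_boot):
        per_rep = {k: [] for k in out}
        failed = False
        for g, start in zip(groups, starts):
            idx = rng.choice(g, size=len(g), replace=True)
            est = MultisiteBindingModel(ligand=ligand, n_restarts=1)
            est._starts = lambda _x, s=start: [s]  # warm start, this replicate
            try:
                est.fit(x[idx], f[idx], dna_uM=dna[idx])
            except (IdentifiabilityError, ConvergenceError):
                failed = True
                break
            K = est.K_
            per_rep["K1"].append(K.K1)
            per_rep["K2"].append(K.K2)
            per_rep["K3"].append(K.K3)
            ratios = cooperativity_ratios(K)
            for key, attr in (("r2", "_r2"), ("r3", "_r3")):
                v = getattr(ratios, attr)
                per_rep[key].append(np.nan if v is None else v)
            try:
                per_rep["Ka"].append(ka_from_macro(K).Ka)
            except ValueError:
                per_rep["Ka"].append(np.nan)
        if failed:
            n_failed += 1
            continue
        for k in out:
            out[k].append(float(np.mean(per_rep[k])))
    result = {k: np.asarray(v) for k, v in out.items()}
    result["n_failed"] = n_failed
    result["seed"] = seed
    return result


@dataclass(frozen=True)
class CooperativityReport:
    """Across-replicate cooperativity verdict and (if warranted) per-site affinity."""

    r2_mean: float
    r2_sd: float
    r3_mean: float
    r3_sd: float
    verdict2: str  # "cooperative" | "not-inferred"
    verdict3: str
    Ka_mean: float | None  # uM^-1; None when a cooperative verdict blocks reduction
    Ka_sd: float | None
    Kd: float | None  # uM, 1/Ka_mean
    n_replicates: int
    n_bootstrap: int
    r2_boot_lower: float | None = None
    r3_boot_lower: float | None = None
    verdict_rule: str = "bootstrap 2.5% lower bound > 1"

    def to_dict(self) -> dict:
        return {
            "r2": {"mean": self.r2_mean, "sd": self.r2_sd,
                   "boot_lower_2.5%": self.r2_boot_lower},
            "r3": {"mean": self.r3_mean, "sd": self.r3_sd,
                   "boot_lower_2.5%": self.r3_boot_lower},
            "verdicts": {"second_event": self.verdict2, "third_event": self.verdict3,
                         "rule": self.verdict_rule},
            "Ka": {"mean": self.Ka_mean, "sd": self.Ka_sd},
            "Kd": self.Kd,
            "n_replicates": self.n_replicates,
            "n_bootstrap": self.n_bootstrap,
        }


def _spread(values: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0


def assess_cooperativity(
    fits: Sequence[MultisiteFit],
    bootstrap: dict | None = None,
) -> CooperativityReport:
    """Combine per-replicate fits into ratio statistics, verdicts and Ka.

    r2 and r3 are reported as mean ± SD across replicates.  An event is called
    cooperative only when the bootstrap distribution (if supplied) puts its
    2.5% quantile above 1.  When neither event is cooperative, the
    identical-site reduction yields Ka per replicate, reported as mean ± SD
    with Kd = 1/Ka_mean; when a cooperative verdict is issued the reduction is
    refused (its independence premise fails) and the Ka fields are None.
    """
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("assess_cooperativity needs at least one converged fit")
    r2s, r3s = [], []
    for f in fits:
        ratios = cooperativity_ratios(f.K)
        r2s.append(ratios.r2)
        r3s.append(ratios.r3)

    def boot_lower(key: str) -> float | None:
        if bootstrap is None:
            return None
        v = bootstrap[key]
        v = v[np.isfinite(v)]
        return float(np.quantile(v, 0.025)) if len(v) else None

    lo2, lo3 = boot_lower("r2"), boot_lower("r3")
    # 1e-9 guard: a degenerate (noiseless) bootstrap sits at 1 plus float
    # jitter, which must not read as evidence of cooperativity
    verdict2 = "cooperative" if lo2 is not None and lo2 > 1.0 + 1e-9 else "not-inferred"
    verdict3 = "cooperative" if lo3 is not None and lo3 > 1.0 + 1e-9 else "not-inferred"

    ka_mean = ka_sd = kd = None
    if verdict2 == "not-inferred" and verdict3 == "not-inferred":
        kas = [ka_from_macro(f.K).Ka for f in fits]
        ka_mean, ka_sd = float(np.mean(kas)), _spread(kas)
        kd = 1.0 / ka_mean
    return CooperativityReport(
        r2_mean=float(np.mean(r2s)), r2_sd=_spread(r2s),
        r3_mean=float(np.mean(r3s)), r3_sd=_spread(r3s),
        verdict2=verdict2, verdict3=verdict3,
        Ka_mean=ka_mean, Ka_sd=ka_sd, Kd=kd,
        n_replicates=len(fits),
        n_bootstrap=0 if bootstrap is None else len(bootstrap["K1"]),
        r2_boot_lower=lo2, r3_boot_lower=lo3,
    )
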