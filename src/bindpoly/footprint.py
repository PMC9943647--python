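"""Quantitative footprint densitometry: per-base protection and hyperexposure.

Chemical-probing footprints compare a naked-DNA lane with the lane of the
saturated protein-DNA complex.  After scaling the complexed-lane scan so that
its summed intensity over a set of reference bases matches the free lane
(gel loading and scan gain are arbitrary), the signed per-base change

    percent_change = 100 * (I_complex - I_free) / I_free

classifies each base as protected (<= -threshold), hyperexposed
(>= +threshold) or unchanged.  Replicate gels are combined by averaging the
per-base percentages and re-classifying the mean; at least two gels are
required.  The two strands are treated as independent profiles and never
merged.  The reference set for normalization and the classification threshold
(default 20%) are explicit parameters recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LaneProfile",
    "FootprintReport",
    "FootprintQuantifier",
    "normalize_profiles",
    "percent_change",
    "average_replicates",
]

DEFAULT_THRESHOLD = 20.0  # percent


@dataclass
class LaneProfile:
    """Per-base densitometry of one gel lane (one strand, free or complexed DNA)."""

    table: pd.DataFrame  # columns: base_index, base, strand, intensity

    def __post_init__(self) -> None:
        df = self.table
        required = ["base_index", "base", "strand", "intensity"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"lane profile is missing columns: {missing}")
        df = df.loc[:, required].reset_index(drop=True).copy()
        strands = set(df["strand"])
        if not strands <= {"top", "bottom"}:
            raise ValueError(f"strand must be 'top' or 'bottom', got {strands}")
        if len(strands) != 1:
            raise ValueError("a lane profile holds exactly one strand")
        idx = df["base_index"].to_numpy()
        if len(np.unique(idx)) != len(idx) or np.any(np.diff(idx) <= 0):
            raise ValueError("base indices must be unique and increasing")
        inten = df["intensity"].to_numpy(dtype=float)
        if np.any(inten < 0) or not np.any(inten > 0):
            raise ValueError("intensities must be >= 0 and not all zero")
        self.table = df

    @property
    def strand(self) -> str:
        return self.table["strand"].iloc[0]

    @property
    def intensity(self) -> np.ndarray:
        return self.table["intensity"].to_numpy(dtype=float)

    def with_intensity(self, values: np.ndarray) -> "LaneProfile":
        df = self.table.copy()
        df["intensity"] = values
        return LaneProfile(df)


@dataclass
class FootprintReport:
    """Signed per-base percent change with its classification."""

    table: pd.DataFrame  # base_index, base, strand, percent_change, classification
    threshold: float

    def classification_of(self, base_index: int) -> str:
        row = self.table[self.table["base_index"] == base_index]
        if row.empty:
            raise KeyError(f"base_index {base_index} not in report")
        return row["classification"].iloc[0]


def _check_aligned(free: LaneProfile, complexed: LaneProfile) -> None:
    a, b = free.table, complexed.table
    if free.strand != complexed.strand:
        raise ValueError(f"strand mismatch: {free.strand} vs {complexed.strand}")
    if not np.array_equal(a["base_index"].to_numpy(), b["base_index"].to_numpy()):
        raise ValueError("alignment error: base_index sets differ between lanes")


def normalize_profiles(
    free: LaneProfile,
    complexed: LaneProfile,
    reference_bases: Sequence[int] | None = None,
) -> tuple[LaneProfile, LaneProfile, float]:
    """Rescale the complexed lane onto the free lane's intensity scale.

    The scale factor equalizes total intensity over ``reference_bases``
    (all bases by default — appropriate when most of the lane is unreactive;
    pass known unaffected bands to normalize against those instead).
    Returns (free, scaled complexed, scale factor).
    """
    _check_aligned(free, complexed)
    idx = free.table["base_index"].to_numpy()
    mask = (
        np.ones(len(idx), dtype=bool)
        if reference_bases is None
        else np.isin(idx, np.asarray(list(reference_bases)))
    )
    ref_free = float(np.sum(free.intensity[mask]))
    ref_complex = float(np.sum(complexed.intensity[mask]))
    if ref_free <= 0 or ref_complex <= 0:
        raise ValueError("zero total intensity over the reference bases")
    scale = ref_free / ref_complex
    return free, complexed.with_intensity(complexed.intensity * scale), scale


def percent_change(
    free: LaneProfile,
    complexed_scaled: LaneProfile,
    threshold: float = DEFAULT_THRESHOLD,
) -> FootprintReport:
    """Per-base signed percent change of a normalized lane pair.

    Bases with zero free-lane intensity cannot be quantified and are flagged
    ``unquantifiable`` (percent_change NaN) rather than dropped.
    """
    _check_aligned(free, complexed_scaled)
    i_free = free.intensity
    i_cplx = complexed_scaled.intensity
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (i_cplx - i_free) / i_free
    pct = np.where(i_free == 0, np.nan, pct)
    out = free.table[["base_index", "base", "strand"]].copy()
    out["percent_change"] = pct
    out["classification"] = _classify(pct, threshold)
    return FootprintReport(table=out, threshold=threshold)


def _classify(pct: np.ndarray, threshold: float) -> np.ndarray:
    labels = np.where(
        np.isnan(pct),
        "unquantifiable",
        np.where(
            pct <= -threshold,
            "protected",
            np.where(pct >= threshold, "hyperexposed", "unchanged"),
        ),
    )
    return labels


def average_replicates(reports: Sequence[FootprintReport]) -> FootprintReport:
    """Average >= 2 replicate-gel reports per base and re-classify the mean."""
    if len(reports) < 2:
        raise ValueError(
            f"at least two replicate gels are required, got {len(reports)}"
        )
    first = reports[0].table
    threshold = reports[0].threshold
    for r in reports[1:]:
        if not np.array_equal(
            first["base_index"].to_numpy(), r.table["base_index"].to_numpy()
        ):
            raise ValueError("replicate reports cover different base sets")
        if r.threshold != threshold:
            raise ValueError("replicate reports use different thresholds")
    stacked = np.vstack([r.table["percent_change"].to_numpy() for r in reports])
    mean_pct = np.mean(stacked, axis=0)
    out = first[["base_index", "base", "strand"]].copy()
    out["percent_change"] = mean_pct
    out["classification"] = _classify(mean_pct, threshold)
    return FootprintReport(table=out, threshold=threshold)


class FootprintQuantifier(object):
    """Transformer-style wrapper: paired free/complex intensities -> report.

    Parameters mirror the module functions: ``threshold`` (percent) and
    ``reference_bases`` for normalization.  ``transform`` accepts the paired
    lane table (columns strand, base_index, base, intensity_free,
    intensity_complex) and returns the per-base report table; the scale
    factor is kept in ``scale_``.
    """

    def __init__(
        self,
        threshold: float = DEFAULT_THRESHOLD,
        reference_bases: Sequence[int] | None = None,
    ):
        self.threshold = threshold
        self.reference_bases = reference_bases

    def get_params(self, deep: bool = True) -> dict:
        return {"threshold": self.threshold, "reference_bases": self.reference_bases}

    def set_params(self, **params) -> "FootprintQuantifier":
        for k, v in params.items():
            if k not in ("threshold", "reference_bases"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def transform(self, paired: pd.DataFrame) -> pd.DataFrame:
        free = LaneProfile(
            paired.rename(columns={"intensity_free": "intensity"})[
                ["base_index", "base", "strand", "intensity"]
            ]
        )
        cplx = LaneProfile(
            paired.rename(columns={"intensity_complex": "intensity"})[
                ["base_index", "base", "strand", "intensity"]
            ]
        )
        free, scaled, self.scale_ = normalize_profiles(
            free, cplx, reference_bases=self.reference_bases
        )
        report = percent_change(free, scaled, threshold=self.threshold)
        self.report_ = report
        return report.table
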