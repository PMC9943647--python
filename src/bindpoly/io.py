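"""Delimited-table readers/writers and run reports.

One table dialect package-wide: tab-separated, UTF-8, ``.`` decimal.  Column
names carry their units as suffixes (``_uM``, ``_RU``, ``_s``) so the uM
convention is explicit at the file boundary.  Reports are JSON with sorted
keys and no timestamps, so identical inputs and seeds produce byte-identical
output.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from .multisite import TitrationDataset

__all__ = [
    "SCHEMAS",
    "TableFormatError",
    "RunReport",
    "load_table",
    "write_table",
    "load_titration",
]

try:
    PACKAGE_VERSION = _pkg_version("bindpoly")
except PackageNotFoundError:  # pragma: no cover - running from a source tree
    PACKAGE_VERSION = "unknown"


class TableFormatError(ValueError):
    """A table does not conform to its declared schema."""


#: schema name -> (required columns, columns that must be numeric)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "titration": (
        ("replicate", "protein_uM", "dna_uM", "f0", "f1", "f2", "f3"),
        ("protein_uM", "dna_uM", "f0", "f1", "f2", "f3"),
    ),
    "binding_curve": (("replicate", "x_uM", "y"), ("x_uM", "y")),
    "spr": (("conc_uM", "Req_RU"), ("conc_uM", "Req_RU")),
    "decay": (("time_s", "fraction_complex"), ("time_s", "fraction_complex")),
    "footprint": (
        ("strand", "base_index", "base", "intensity_free", "intensity_complex"),
        ("base_index", "intensity_free", "intensity_complex"),
    ),
}

# At the file boundary: row fraction sums within this of 1 pass silently ...
SUM_SLACK_SILENT = 0.02
# ... up to this they are renormalized with a warning; beyond they are rejected.
SUM_SLACK_REJECT = 0.10


def load_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a TSV table against a named schema.

    Raises :class:`TableFormatError` naming the offending column or the
    1-based data line of a non-numeric cell.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; one of {sorted(SCHEMAS)}")
    path = Path(path)
    required, numeric = SCHEMAS[schema]
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise TableFormatError(f"{path}: no data rows")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise TableFormatError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at data line {line}"
            )
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 1
            raise TableFormatError(
                f"{path}: missing value in column {col!r} at data line {line}"
            )
        df[col] = converted
    return df


def load_titration(path: str | Path) -> TitrationDataset:
    """Load a titration TSV, applying the fraction-sum slack rule.

    Row sums within ±0.02 of 1 are renormalized silently; within ±0.10 they
    are renormalized with a warning; beyond that the row is rejected.
    """
    df = load_table(path, "titration")
    fr = df[["f0", "f1", "f2", "f3"]].to_numpy(dtype=float)
    sums = fr.sum(axis=1)
    dev = np.abs(sums - 1.0)
    if np.any(dev > SUM_SLACK_REJECT):
        bad = int(np.argmax(dev > SUM_SLACK_REJECT))
        raise TableFormatError(
            f"{path}: fractions at data line {bad + 1} sum to {sums[bad]:.3f}, "
            f"beyond the ±{SUM_SLACK_REJECT} rejection bound"
        )
    loose = dev > SUM_SLACK_SILENT
    if np.any(loose):
        warnings.warn(
            f"{np.sum(loose)} row(s) with fraction sums outside "
            f"1 ± {SUM_SLACK_SILENT} were renormalized",
            stacklevel=2,
        )
    df[["f0", "f1", "f2", "f3"]] = fr / sums[:, None]
    return TitrationDataset(df)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


@dataclass
class RunReport:
    """Serializable record of one pipeline stage run."""

    stage: str
    parameters: dict
    results: dict
    input_digest: str | None = None
    warnings: list[str] = field(default_factory=list)
    package_version: str = PACKAGE_VERSION

    @classmethod
    def for_run(cls, stage: str, parameters: dict, results: dict,
                input_path: str | Path | None = None,
                warnings_: list[str] | None = None) -> "RunReport":
        return cls(
            stage=stage,
            parameters=_jsonify(parameters),
            results=_jsonify(results),
            input_digest=None if input_path is None else _digest(input_path),
            warnings=list(warnings_ or []),
        )

    def to_json(self) -> str:
        payload = {
            "stage": self.stage,
            "input_digest": self.input_digest,
            "parameters": self.parameters,
            "results": self.results,
            "warnings": self.warnings,
            "package_version": self.package_version,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        d = json.loads(text)
        return cls(
            stage=d["stage"], parameters=d["parameters"], results=d["results"],
            input_digest=d["input_digest"], warnings=d["warnings"],
            package_version=d["package_version"],
        )
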