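"""Spectra table format, validation, and report serialization.

The on-disk format is a flat "spectra CSV": one row per leaf sample, with
columns ``sample_id``, ``nitrogen_pct``, an optional ``gradient`` label,
and then one numeric column per frequency point, headed by the frequency
value in THz. A single file therefore carries both the spectral matrix X
and the reference nitrogen vector y through every pipeline stage.

Model evaluation reports are serialized as JSON Lines (one JSON object per
line) so repeated runs can be appended to one file and read back.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "FitReport",
    "SpectraFormatError",
    "read_spectra",
    "write_spectra",
    "write_report",
    "read_report",
]

FREQ_MAX_THZ = 1.4  # working range of the instrument band considered here

_META_COLUMNS = ("sample_id", "nitrogen_pct", "gradient")


class SpectraFormatError(ValueError):
    """Raised when a spectra table violates the format contract."""


@dataclass
class SpectraSet:
    """Frequency grid plus per-sample power spectra and nitrogen references.

    Parameters
    ----------
    frequencies_thz : ndarray, shape (P,)
        Strictly increasing frequency grid in THz, within [0, 1.4].
    power : ndarray, shape (N, P)
        Power-spectrum values, one row per sample (arbitrary power units).
    nitrogen_pct : ndarray, shape (N,)
        Reference nitrogen content in % dry mass; finite and non-negative.
    sample_ids : list of str
        Unique sample identifiers.
    gradient_labels : list of str, optional
        Nitrogen-stress group label per sample.
    """

    frequencies_thz: np.ndarray
    power: np.ndarray
    nitrogen_pct: np.ndarray
    sample_ids: list[str]
    gradient_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.frequencies_thz = np.asarray(self.frequencies_thz, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        self.nitrogen_pct = np.asarray(self.nitrogen_pct, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.gradient_labels is not None:
            self.gradient_labels = [str(g) for g in self.gradient_labels]
        self.validate()

    # -- container protocol -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.power.shape[0]

    @property
    def n_frequencies(self) -> int:
        return self.power.shape[1]

    def __len__(self) -> int:
        return self.n_samples

    def validate(self) -> None:
        """Check every structural invariant; raise SpectraFormatError on violation."""
        f = self.frequencies_thz
        if f.ndim != 1 or f.size == 0:
            raise SpectraFormatError("frequency grid must be a non-empty 1-D vector")
        if np.any(np.diff(f) <= 0):
            raise SpectraFormatError("frequencies must be strictly increasing")
        if f[0] < 0 or f[-1] > FREQ_MAX_THZ + 1e-9:
            raise SpectraFormatError(
                f"frequencies must lie within [0, {FREQ_MAX_THZ}] THz, got "
                f"[{f[0]:g}, {f[-1]:g}]"
            )
        n, p = self.power.shape
        if p != f.size:
            raise SpectraFormatError(
                f"power has {p} columns but the grid has {f.size} frequencies"
            )
        if self.nitrogen_pct.shape != (n,):
            raise SpectraFormatError("nitrogen_pct length must equal the number of spectra")
        if len(self.sample_ids) != n:
            raise SpectraFormatError("sample_ids length must equal the number of spectra")
        if len(set(self.sample_ids)) != n:
            raise SpectraFormatError("sample ids must be unique")
        if self.gradient_labels is not None and len(self.gradient_labels) != n:
            raise SpectraFormatError("gradient_labels length must equal the number of spectra")
        if not np.all(np.isfinite(self.nitrogen_pct)):
            raise SpectraFormatError("nitrogen_pct must be finite")
        if np.any(self.nitrogen_pct < 0):
            raise SpectraFormatError("nitrogen_pct must be non-negative")

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        """Row-subset by sample indices, preserving order of ``indices``."""
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            frequencies_thz=self.frequencies_thz.copy(),
            power=self.power[idx].copy(),
            nitrogen_pct=self.nitrogen_pct[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            gradient_labels=None
            if self.gradient_labels is None
            else [self.gradient_labels[i] for i in idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectraSet):
            return NotImplemented
        return (
            np.array_equal(self.frequencies_thz, other.frequencies_thz)
            and np.array_equal(self.power, other.power)
            and np.array_equal(self.nitrogen_pct, other.nitrogen_pct)
            and self.sample_ids == other.sample_ids
            and self.gradient_labels == other.gradient_labels
        )


@dataclass
class FitReport:
    """Calibration/prediction metrics for one trained model on one split.

    RMSEC/RMSEP are in % nitrogen; the determination coefficients are
    dimensionless and bounded above by 1.
    """

    rmsec_pct: float
    rmsep_pct: float
    r2_cal: float
    r2_pred: float
    model_name: str
    selection_name: str
    n_cal: int
    n_pred: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rmsec_pct < 0 or self.rmsep_pct < 0:
            raise ValueError("RMSE values must be non-negative")
        if self.r2_cal > 1 + 1e-12 or self.r2_pred > 1 + 1e-12:
            raise ValueError("R^2 values cannot exceed 1")


def read_spectra(path: str | Path) -> SpectraSet:
    """Read a spectra CSV into a validated :class:`SpectraSet`.

    Raises
    ------
    SpectraFormatError
        On a non-monotone frequency header, row-length mismatch, duplicate
        sample id, or any other invariant violation.
    """
    try:
        df = pd.read_csv(path, dtype={"sample_id": str})
    except pd.errors.ParserError as exc:  # ragged rows
        raise SpectraFormatError(f"malformed spectra CSV: {exc}") from exc
    if df.columns[0] != "sample_id" or df.columns[1] != "nitrogen_pct":
        raise SpectraFormatError(
            "spectra CSV must start with columns 'sample_id', 'nitrogen_pct'"
        )
    has_gradient = len(df.columns) > 2 and df.columns[2] == "gradient"
    freq_cols = list(df.columns[3 if has_gradient else 2 :])
    try:
        frequencies = np.array([float(c) for c in freq_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric frequency header: {exc}") from exc
    power = df[freq_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(power)):
        raise SpectraFormatError("power values must be finite numbers")
    return SpectraSet(
        frequencies_thz=frequencies,
        power=power,
        nitrogen_pct=df["nitrogen_pct"].to_numpy(dtype=float),
        sample_ids=df["sample_id"].tolist(),
        gradient_labels=df["gradient"].astype(str).tolist() if has_gradient else None,
    )


def write_spectra(data: SpectraSet, path: str | Path) -> None:
    """Write a SpectraSet as a spectra CSV readable by :func:`read_spectra`.

    Frequencies are serialized with enough digits (repr precision) for a
    lossless float round-trip. Refuses to write an empty sample set.
    """
    data.validate()
    if data.n_samples == 0:
        raise SpectraFormatError("refusing to write a spectra CSV with no samples")
    cols: dict[str, object] = {
        "sample_id": data.sample_ids,
        "nitrogen_pct": data.nitrogen_pct,
    }
    if data.gradient_labels is not None:
        cols["gradient"] = data.gradient_labels
    df = pd.DataFrame(cols)
    spectra = pd.DataFrame(
        data.power, columns=[repr(float(f)) for f in data.frequencies_thz], index=df.index
    )
    pd.concat([df, spectra], axis=1).to_csv(path, index=False)


def write_report(report: FitReport, path: str | Path, append: bool = True) -> None:
    """Serialize a FitReport as one JSON object per line (JSON Lines).

    With ``append=True`` (default) successive reports accumulate in the
    same file and are all retrievable with :func:`read_report`.
    """
    payload = asdict(report)
    mode = "a" if append else "w"
    with open(path, mode, encoding="utf-8") as fh:
        fh.write(json.dumps(payload) + "\n")


def read_report(path: str | Path) -> list[FitReport]:
    """Read every FitReport from a JSON Lines report file."""
    reports = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                reports.append(FitReport(**json.loads(line)))
    return reports
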