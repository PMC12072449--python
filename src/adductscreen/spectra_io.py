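"""Centroided peak-list containers and extracted-ion chromatography.

The native interchange format is a long-form CSV with columns
``scan_time_min, cone_voltage_V, polarity, mz, intensity`` — one row per
centroid peak — matching what a unit-resolution quadrupole exports after
centroiding. Centroided mzML is read through :mod:`pyteomics.mzml`.

Times are minutes throughout; m/z tolerances are absolute Da, defaulting to
0.5 Da (unit resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MZ_TOL",
    "PeakList",
    "Run",
    "Chromatogram",
    "read_run",
    "write_run",
    "extract_intensity",
    "xic",
    "integrate_window",
    "apex_in_window",
]

#: Default extraction half-window in Da (single-quadrupole unit resolution).
DEFAULT_MZ_TOL = 0.5

_TABULAR_COLUMNS = ("scan_time_min", "cone_voltage_V", "polarity", "mz", "intensity")


@dataclass
class PeakList:
    """One centroided scan: (m/z, intensity) pairs at a scan time."""

    scan_time: float                  # minutes
    polarity: str                     # "+" or "-"
    cone_voltage: float               # V
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.polarity not in {"+", "-"}:
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(np.isnan(self.mz)) or np.any(np.isnan(self.intensity)):
            raise ValueError("NaN in peak list")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity in peak list")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]


@dataclass
class Run:
    """A time-ordered sequence of peak lists plus instrument metadata."""

    peak_lists: list[PeakList]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [pl.scan_time for pl in self.peak_lists]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("scan times must be non-decreasing")

    @property
    def scan_times(self) -> np.ndarray:
        return np.array([pl.scan_time for pl in self.peak_lists])


@dataclass
class Chromatogram:
    """Extracted-ion trace: intensity at target_mz ± tolerance vs time."""

    times: np.ndarray
    intensities: np.ndarray
    target_mz: float
    tolerance: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("chromatogram times must be strictly increasing")


def read_run(path: str | Path, dialect: str = "tabular") -> Run:
    """Read a run from the tabular CSV dialect or centroided mzML."""
    path = Path(path)
    if dialect == "tabular":
        return _read_tabular(path)
    if dialect == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown dialect {dialect!r} (use 'tabular' or 'mzml')")


def _read_tabular(path: Path) -> Run:
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty peak-list file") from None
    missing = [c for c in _TABULAR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(table) == 0:
        raise ValueError(f"{path}: no peaks")
    for col in ("scan_time_min", "cone_voltage_V", "mz", "intensity"):
        bad = table.index[pd.to_numeric(table[col], errors="coerce").isna()]
        if len(bad):
            # +2: header line plus 1-based numbering.
            raise ValueError(
                f"{path}: malformed {col} at line {bad[0] + 2}"
            )
        table[col] = pd.to_numeric(table[col])
    neg = table.index[table["intensity"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative intensity at line {neg[0] + 2}")
    peak_lists = []
    for (time, voltage, polarity), group in table.groupby(
        ["scan_time_min", "cone_voltage_V", "polarity"], sort=True
    ):
        peak_lists.append(
            PeakList(
                scan_time=float(time),
                polarity=str(polarity),
                cone_voltage=float(voltage),
                mz=group["mz"].to_numpy(),
                intensity=group["intensity"].to_numpy(),
            )
        )
    peak_lists.sort(key=lambda pl: pl.scan_time)
    return Run(peak_lists=peak_lists, metadata={"source": str(path)})


def _read_mzml(path: Path) -> Run:
    from pyteomics import mzml as _mzml

    peak_lists = []
    with _mzml.read(str(path)) as reader:
        for spectrum in reader:
            if spectrum.get("ms level", 1) != 1:
                continue
            scan = spectrum["scanList"]["scan"][0]
            time = float(scan["scan start time"])
            polarity = "-" if "negative scan" in spectrum else "+"
            peak_lists.append(
                PeakList(
                    scan_time=time,
                    polarity=polarity,
                    cone_voltage=float(spectrum.get("cone voltage", 0.0)),
                    mz=spectrum["m/z array"],
                    intensity=spectrum["intensity array"],
                )
            )
    if not peak_lists:
        raise ValueError(f"{path}: no MS1 centroid spectra found")
    peak_lists.sort(key=lambda pl: pl.scan_time)
    return Run(peak_lists=peak_lists, metadata={"source": str(path)})


def write_run(run: Run, path: str | Path) -> None:
    """Write a run in the tabular CSV dialect (lossless round trip)."""
    rows = {
        "scan_time_min": np.concatenate(
            [np.full(len(pl.mz), pl.scan_time) for pl in run.peak_lists]
        ),
        "cone_voltage_V": np.concatenate(
            [np.full(len(pl.mz), pl.cone_voltage) for pl in run.peak_lists]
        ),
        "polarity": np.concatenate(
            [np.full(len(pl.mz), pl.polarity, dtype=object) for pl in run.peak_lists]
        ),
        "mz": np.concatenate([pl.mz for pl in run.peak_lists]),
        "intensity": np.concatenate([pl.intensity for pl in run.peak_lists]),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def extract_intensity(
    pl: PeakList, target_mz: float, tol: float = DEFAULT_MZ_TOL
) -> float:
    """Summed intensity of peaks with |mz − target_mz| ≤ tol (0 if none)."""
    if tol <= 0:
        raise ValueError(f"tolerance must be > 0, got {tol}")
    lo = np.searchsorted(pl.mz, target_mz - tol, side="left")
    hi = np.searchsorted(pl.mz, target_mz + tol, side="right")
    return float(pl.intensity[lo:hi].sum())


def xic(run: Run, target_mz: float, tol: float = DEFAULT_MZ_TOL) -> Chromatogram:
    """Extracted-ion chromatogram of *target_mz* ± *tol* across all scans."""
    if not run.peak_lists:
        raise ValueError("cannot extract a chromatogram from an empty run")
    return Chromatogram(
        times=run.scan_times,
        intensities=np.array(
            [extract_intensity(pl, target_mz, tol) for pl in run.peak_lists]
        ),
        target_mz=target_mz,
        tolerance=tol,
    )


def integrate_window(c: Chromatogram, rt_min: float, rt_max: float) -> float:
    """Trapezoidal integral of the trace over [rt_min, rt_max] (counts·min).

    Returns 0 when fewer than two scans fall inside the window.
    """
    if not rt_min < rt_max:
        raise ValueError(f"rt_min ({rt_min}) must be < rt_max ({rt_max})")
    mask = (c.times >= rt_min) & (c.times <= rt_max)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(c.intensities[mask], c.times[mask]))


def apex_in_window(c: Chromatogram, rt_min: float, rt_max: float) -> float:
    """Apex (maximum) intensity inside [rt_min, rt_max]; 0 if no scans."""
    if not rt_min < rt_max:
        raise ValueError(f"rt_min ({rt_min}) must be < rt_max ({rt_max})")
    mask = (c.times >= rt_min) & (c.times <= rt_max)
    if not mask.any():
        return 0.0
    return float(c.intensities[mask].max())
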