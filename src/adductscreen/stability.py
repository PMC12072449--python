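"""Adduct-survival statistics: ratio curves, midpoint fits, and ranking.

The stability of a non-covalent phenolic–nucleoside adduct [M+dG/G+H]+ is
read out as the abundance ratio [M+dG/G+H]+ / [M+H]+ per cone voltage.
Plotted against the DOF-corrected center-of-mass energy E_comδ, the decay
of that ratio compares gas-phase stabilities across compounds of different
size. A three-parameter logistic

    r(E) = r0 / (1 + exp(slope · (E − e50)))

summarizes each curve; the half-survival energy e50 gives a reproducible
single-number ranking, complementing the direct point-wise comparison of
ratios on a shared energy grid.

Curves obtained with deoxyguanosine are never ranked against curves
obtained with guanosine: the two nucleosides are infused from different
solvents, so their absolute adduct yields are not comparable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .energetics import CollisionSettings, EnergyPoint, delta_factor, ecom
from .formulas import (
    Attachment,
    Compound,
    NUCLEOSIDES_BY_NAME,
    make_adduct,
)
from .spectra_io import (
    DEFAULT_MZ_TOL,
    Run,
    apex_in_window,
    integrate_window,
    xic,
)

__all__ = [
    "NUCLEOSIDES",
    "UndefinedRatioError",
    "SigmoidFit",
    "StabilityCurve",
    "survival_ratio",
    "build_curve",
    "fit_sigmoid",
    "rank_compounds",
    "curve_table",
]

logger = logging.getLogger(__name__)

#: Supported post-column reagents by short name (re-exported convenience).
NUCLEOSIDES = NUCLEOSIDES_BY_NAME


class UndefinedRatioError(ZeroDivisionError):
    """Survival ratio requested with zero free-ion intensity."""


def survival_ratio(i_adduct: float, i_free: float) -> float:
    """Adduct-survival ratio i_adduct / i_free.

    The free-ion intensity must be positive: a vanished [M+H]+ signal makes
    the ratio undefined and raises :class:`UndefinedRatioError` rather than
    returning an infinity.
    """
    if i_adduct < 0:
        raise ValueError(f"adduct intensity must be ≥ 0, got {i_adduct}")
    if i_free <= 0:
        raise UndefinedRatioError(
            f"free-ion intensity must be > 0 for a defined ratio, got {i_free}"
        )
    return i_adduct / i_free


@dataclass
class SigmoidFit:
    """Logistic summary r(E) = r0 / (1 + exp(slope·(E − e50))) of a curve."""

    r0: float
    e50: float
    slope: float
    rss: float
    converged: bool = True
    message: str = ""

    def predict(self, e_com: np.ndarray) -> np.ndarray:
        return _logistic(np.asarray(e_com, dtype=float), self.r0, self.e50, self.slope)


@dataclass
class StabilityCurve:
    """Survival-ratio series of one compound with one nucleoside."""

    compound: str
    nucleoside: str
    points: list[EnergyPoint]
    fit: SigmoidFit | None = None
    dropped_voltages: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError(
                f"{self.compound}/{self.nucleoside}: a stability curve needs "
                f"≥ 2 defined points, got {len(self.points)}"
            )
        e = [p.e_com for p in self.points]
        if any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("e_com must be strictly increasing along a curve")
        if any(p.ratio is None or p.ratio < 0 for p in self.points):
            raise ValueError("all curve points need a ratio ≥ 0")

    @property
    def e_com(self) -> np.ndarray:
        return np.array([p.e_com for p in self.points])

    @property
    def ratios(self) -> np.ndarray:
        return np.array([p.ratio for p in self.points])

    @property
    def flagged(self) -> bool:
        return bool(self.dropped_voltages)


def build_curve(
    run_set: Mapping[float, Run],
    compound: Compound,
    nucleoside: str,
    settings: CollisionSettings,
    tol: float = DEFAULT_MZ_TOL,
    mode: str = "area",
) -> StabilityCurve:
    """Assemble the survival curve of *compound* from per-voltage runs.

    For each configured cone voltage the [M+H]+ and [M+nucleoside+H]+
    traces are extracted and integrated (trapezoidal area by default, apex
    height with ``mode="apex"``) over the compound's retention-time window;
    their ratio is paired with E_comδ computed from the nucleoside adduct's
    DOF and monoisotopic mass.

    Voltages whose free-ion signal vanishes are dropped with a warning and
    recorded in ``dropped_voltages``; a curve with < 2 surviving points is
    rejected.
    """
    if nucleoside not in NUCLEOSIDES:
        raise ValueError(
            f"unknown nucleoside {nucleoside!r}; expected one of "
            f"{sorted(NUCLEOSIDES)}"
        )
    if mode not in {"area", "apex"}:
        raise ValueError(f"mode must be 'area' or 'apex', got {mode!r}")
    missing = [v for v in settings.cone_voltages if v not in run_set]
    if missing:
        raise ValueError(
            f"{compound.name}: runs missing for cone voltages {missing}"
        )
    free_ion = make_adduct(compound.formula, Attachment.PROTON_ADD)
    adduct = make_adduct(
        compound.formula,
        Attachment.NUCLEOSIDE_PROTON_ADD,
        NUCLEOSIDES[nucleoside],
    )
    delta = delta_factor(adduct.dof, settings.reference_dof)
    measure = integrate_window if mode == "area" else apex_in_window

    points: list[EnergyPoint] = []
    dropped: list[float] = []
    for voltage in settings.cone_voltages:
        run = run_set[voltage]
        i_free = measure(
            xic(run, free_ion.mz_mono, tol), compound.rt_min, compound.rt_max
        )
        i_adduct = measure(
            xic(run, adduct.mz_mono, tol), compound.rt_min, compound.rt_max
        )
        try:
            ratio = survival_ratio(i_adduct, i_free)
        except UndefinedRatioError:
            logger.warning(
                "%s/%s: undefined ratio at %g V (free-ion signal absent); "
                "point dropped",
                compound.name, nucleoside, voltage,
            )
            dropped.append(voltage)
            continue
        points.append(
            EnergyPoint(
                e_lab=voltage,
                delta=delta,
                e_com=ecom(voltage, adduct.mz_mono, settings, delta),
                ratio=ratio,
            )
        )
    if len(points) < 2:
        raise ValueError(
            f"{compound.name}/{nucleoside}: no usable curve — ratio undefined "
            f"at voltages {dropped}"
        )
    return StabilityCurve(
        compound=compound.name,
        nucleoside=nucleoside,
        points=points,
        dropped_voltages=dropped,
    )


def _logistic(e: np.ndarray, r0: float, e50: float, slope: float) -> np.ndarray:
    return r0 / (1.0 + np.exp(np.clip(slope * (e - e50), -500, 500)))


def fit_sigmoid(curve: StabilityCurve) -> SigmoidFit:
    """Deterministic bounded least-squares logistic fit of a curve.

    Initializer: r0 = max ratio, e50 = median e_com, slope = 4 / range(e_com).
    A flat curve (no decay to fit) or a failed optimization returns a
    flagged fit (``converged=False``) instead of raising.
    """
    e = curve.e_com
    r = curve.ratios
    if len(e) < 4:
        raise ValueError(
            f"{curve.compound}/{curve.nucleoside}: sigmoid fit needs ≥ 4 "
            f"points, got {len(e)}"
        )
    rmax = float(r.max())
    if rmax <= 0 or (r.max() - r.min()) < 1e-12 * max(rmax, 1.0):
        return SigmoidFit(
            r0=rmax, e50=float(np.median(e)), slope=0.0,
            rss=float(((r - r.mean()) ** 2).sum()),
            converged=False, message="degenerate: flat curve",
        )
    e_range = float(e.max() - e.min())
    p0 = (rmax, float(np.median(e)), 4.0 / e_range)
    bounds = (
        [1e-12, 1e-12, 1e-12],
        [10.0 * rmax, 10.0 * float(e.max()), 1e4 / e_range],
    )
    try:
        popt, _ = curve_fit(
            _logistic, e, r, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        return SigmoidFit(
            r0=p0[0], e50=p0[1], slope=p0[2], rss=math.inf,
            converged=False, message=f"fit failed: {exc}",
        )
    resid = r - _logistic(e, *popt)
    return SigmoidFit(
        r0=float(popt[0]), e50=float(popt[1]), slope=float(popt[2]),
        rss=float((resid ** 2).sum()),
    )


def rank_compounds(
    curves: Sequence[StabilityCurve],
    mode: str = "pointwise",
    grid_size: int = 50,
) -> list[tuple[str, float]]:
    """Rank compounds by adduct stability, most stable first.

    ``pointwise`` mode scores each curve by its mean ratio on the shared
    E_comδ interval (linear interpolation on a common grid, no
    extrapolation); ``e50`` mode scores by the fitted half-survival energy.
    Ties are broken lexicographically by compound name so the ordering is
    deterministic. All curves must share one nucleoside.
    """
    if not curves:
        raise ValueError("no curves to rank")
    nucleosides = {c.nucleoside for c in curves}
    if len(nucleosides) > 1:
        raise ValueError(
            f"cannot rank across nucleosides {sorted(nucleosides)}: dG and G "
            "runs use different infusion solvents and are not comparable"
        )
    if mode == "pointwise":
        lo = max(float(c.e_com.min()) for c in curves)
        hi = min(float(c.e_com.max()) for c in curves)
        if not lo < hi:
            raise ValueError(
                f"no overlapping e_com support for point-wise ranking "
                f"(common interval [{lo:.4g}, {hi:.4g}])"
            )
        grid = np.linspace(lo, hi, grid_size)
        scored = [
            (c.compound, float(np.interp(grid, c.e_com, c.ratios).mean()))
            for c in curves
        ]
    elif mode == "e50":
        scored = []
        for c in curves:
            fit = c.fit if c.fit is not None else fit_sigmoid(c)
            if not fit.converged:
                raise ValueError(
                    f"{c.compound}: no converged sigmoid fit for e50 ranking "
                    f"({fit.message})"
                )
            scored.append((c.compound, fit.e50))
    else:
        raise ValueError(f"mode must be 'pointwise' or 'e50', got {mode!r}")
    return sorted(scored, key=lambda item: (-item[1], item[0]))


def curve_table(curves: Sequence[StabilityCurve]) -> pd.DataFrame:
    """Long-format export of curves (one row per retained energy point)."""
    rows = []
    for c in curves:
        for p in c.points:
            rows.append(
                {
                    "compound": c.compound,
                    "nucleoside": c.nucleoside,
                    "e_lab_V": p.e_lab,
                    "delta": p.delta,
                    "e_com_eV": p.e_com,
                    "ratio": p.ratio,
                }
            )
    return pd.DataFrame(rows)
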