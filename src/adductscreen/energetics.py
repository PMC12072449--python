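"""Center-of-mass collision energies with degrees-of-freedom correction.

In-source CID on a single-quadrupole instrument exposes ions to a laboratory
collision energy E_lab numerically equal to the cone voltage for a singly
charged ion. Only a fraction of E_lab can be converted into internal energy
in a collision with a neutral gas molecule; the classical center-of-mass
limit is E_lab · m_g / (m_p + m_g), with m_g the collision-gas mass (N2,
28 amu) and m_p the ion's mass.

Because a larger ion redistributes internal energy over more vibrational
modes, adducts of different sizes are made comparable by scaling the
center-of-mass energy with δ = DOF_ref / DOF_adduct, where
DOF = 3N − 6 and the reference is the smallest (minimum-DOF) adduct of the
analyzed set, for which δ = 1:

    E_comδ = δ · E_lab · m_g / (m_p + m_g)

Ion masses are monoisotopic masses in Da treated as amu; the electron mass
is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import pandas as pd

from .formulas import AdductIon

__all__ = [
    "NITROGEN_MASS",
    "DEFAULT_CONE_VOLTAGES",
    "CollisionSettings",
    "EnergyPoint",
    "delta_factor",
    "ecom",
    "energy_axis",
    "select_reference",
    "energy_table",
]

logger = logging.getLogger(__name__)

#: Mass of the N2 collision gas in amu.
NITROGEN_MASS = 28.0

#: Cone-voltage ladder used for adduct-survival experiments (V). Above 30 V
#: glycosidic bonds of phenolic glycosides start to cleave in-source.
DEFAULT_CONE_VOLTAGES = (10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass(frozen=True)
class CollisionSettings:
    """Instrument parameters of the in-source CID experiment.

    Parameters
    ----------
    reference_dof:
        DOF of the reference adduct (δ = 1 path). Pick it with
        :func:`select_reference` so the reference is the smallest adduct and
        every δ lies in (0, 1].
    gas_mass:
        Collision-gas mass in amu (N2 by default).
    cone_voltages:
        Strictly increasing laboratory energies in V (≡ eV for z = 1).
    """

    reference_dof: int
    gas_mass: float = NITROGEN_MASS
    cone_voltages: Sequence[float] = DEFAULT_CONE_VOLTAGES

    def __post_init__(self) -> None:
        if self.gas_mass <= 0:
            raise ValueError(f"gas_mass must be > 0, got {self.gas_mass}")
        if self.reference_dof < 3:
            raise ValueError(
                f"reference_dof must be ≥ 3, got {self.reference_dof}"
            )
        voltages = tuple(float(v) for v in self.cone_voltages)
        if not voltages or any(v <= 0 for v in voltages):
            raise ValueError("cone_voltages must be positive")
        if any(b <= a for a, b in zip(voltages, voltages[1:])):
            raise ValueError("cone_voltages must be strictly increasing")
        object.__setattr__(self, "cone_voltages", voltages)


@dataclass
class EnergyPoint:
    """One observation on a stability curve.

    ``ratio`` is filled later by the stability stage; None until measured.
    """

    e_lab: float          # eV (≡ cone voltage in V for z = 1)
    delta: float          # dimensionless DOF correction
    e_com: float          # eV, δ-corrected center-of-mass energy
    ratio: float | None = None


def delta_factor(adduct_dof: int, reference_dof: int) -> float:
    """DOF correction δ = DOF_ref / DOF_adduct; 1 for the reference itself.

    δ > 1 (a reference larger than the adduct) is permitted but logged:
    under the minimum-DOF reference convention it signals a caller error.
    """
    if adduct_dof < 3 or reference_dof < 3:
        raise ValueError(
            f"DOF values must be ≥ 3, got adduct={adduct_dof}, "
            f"reference={reference_dof}"
        )
    delta = reference_dof / adduct_dof
    if delta > 1.0:
        logger.warning(
            "delta = %.4f > 1: reference DOF %d exceeds adduct DOF %d "
            "(reference is not the smallest adduct)",
            delta, reference_dof, adduct_dof,
        )
    return delta


def ecom(
    e_lab: float,
    adduct_mass: float,
    settings: CollisionSettings,
    delta: float,
) -> float:
    """δ-corrected center-of-mass energy δ·E_lab·m_g/(m_p+m_g) in eV."""
    if e_lab <= 0:
        raise ValueError(f"e_lab must be > 0, got {e_lab}")
    if adduct_mass <= 0:
        raise ValueError(f"adduct_mass must be > 0, got {adduct_mass}")
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    return delta * e_lab * settings.gas_mass / (adduct_mass + settings.gas_mass)


def energy_axis(
    adduct: AdductIon, settings: CollisionSettings
) -> list[EnergyPoint]:
    """One :class:`EnergyPoint` per cone voltage for *adduct*.

    m_p is the adduct ion's monoisotopic mass; δ is computed against
    ``settings.reference_dof``.
    """
    delta = delta_factor(adduct.dof, settings.reference_dof)
    return [
        EnergyPoint(
            e_lab=v,
            delta=delta,
            e_com=ecom(v, adduct.mz_mono, settings, delta),
        )
        for v in settings.cone_voltages
    ]


def select_reference(adducts: Iterable[AdductIon]) -> AdductIon:
    """The minimum-DOF (smallest) adduct; ties broken by mass then label."""
    adducts = list(adducts)
    if not adducts:
        raise ValueError("cannot select a reference from an empty adduct set")
    return min(adducts, key=lambda a: (a.dof, a.mz_mono, a.label))


def energy_table(
    entries: Iterable[tuple[str, str, AdductIon]],
    settings: CollisionSettings,
) -> pd.DataFrame:
    """Long-format energy table for (compound, nucleoside, adduct) triples.

    Columns: compound, nucleoside, e_lab_V, delta, e_com_eV.
    """
    rows = []
    for compound, nucleoside, adduct in entries:
        for pt in energy_axis(adduct, settings):
            rows.append(
                {
                    "compound": compound,
                    "nucleoside": nucleoside,
                    "e_lab_V": pt.e_lab,
                    "delta": pt.delta,
                    "e_com_eV": pt.e_com,
                }
            )
    return pd.DataFrame(rows)
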