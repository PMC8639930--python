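"""Functional derivations from M-mode echocardiography measurements.

Raw M-mode measures (parasternal long-axis, papillary-muscle level):
interventricular septum (IVS), LV internal diameter (LVID) and LV posterior
wall (LVPW) thickness, each in diastole (d) and systole (s), in mm, plus the
concurrent heart rate.  Replicate images are averaged in triplicate before
derivation.

Derived quantities (standard M-mode conventions):

* Teichholz LV volume (uL):  V = 1000 * (7.0 / (2.4 + D_cm)) * D_cm^3
* fractional shortening:     FS% = 100 (LVIDd - LVIDs) / LVIDd
* ejection fraction:         EF% = 100 (EDV - ESV) / EDV
* stroke volume / cardiac output:  SV = EDV - ESV (uL); CO = SV*HR/1000 (mL/min)
* LV mass (mg, cubed ASE convention, myocardial density 1.053 g/mL):
  1.053 [ (LVIDd + IVSd + LVPWd)^3 - LVIDd^3 ]  with lengths in mm

Physiologically inverted measurements (LVIDs > LVIDd) emit a warning and
negative FS/EF are still returned, so batch tables survive outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError

LV_MYOCARDIAL_DENSITY = 1.053  # g/mL


@dataclass
class MModeMeasures:
    ivs_d: float
    ivs_s: float
    lvid_d: float
    lvid_s: float
    lvpw_d: float
    lvpw_s: float
    hr_bpm: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise DomainError(f"{f.name} must be positive")
        if self.lvid_s > self.lvid_d:
            warnings.warn(
                f"lvid_s ({self.lvid_s}) > lvid_d ({self.lvid_d}): inverted measures",
                stacklevel=2,
            )


@dataclass
class EchoDerived:
    edv_ul: float
    esv_ul: float
    fs_pct: float
    ef_pct: float
    sv_ul: float
    co_ml_min: float
    lv_mass_mg: float


def average_triplicate(measures: list[MModeMeasures]) -> MModeMeasures:
    """Field-wise mean of exactly three replicate M-mode measurements."""
    if len(measures) != 3:
        raise InsufficientDataError(
            f"triplicate averaging needs exactly 3 replicates, got {len(measures)}"
        )
    return MModeMeasures(
        **{
            f.name: float(np.mean([getattr(m, f.name) for m in measures]))
            for f in fields(MModeMeasures)
        }
    )


def teichholz_volume(d_mm: float) -> float:
    """Teichholz LV volume (uL) from an internal diameter (mm)."""
    if d_mm < 0:
        raise DomainError("diameter must be non-negative")
    d_cm = d_mm / 10.0
    return 1000.0 * (7.0 / (2.4 + d_cm)) * d_cm**3


def derive_echo(m: MModeMeasures) -> EchoDerived:
    """Derive FS, EF, volumes, SV, CO and LV mass from averaged measures."""
    fs = 100.0 * (m.lvid_d - m.lvid_s) / m.lvid_d
    edv = teichholz_volume(m.lvid_d)
    esv = teichholz_volume(m.lvid_s)
    ef = 100.0 * (edv - esv) / edv
    sv = edv - esv
    co = sv * m.hr_bpm / 1000.0
    lv_mass = LV_MYOCARDIAL_DENSITY * (
        (m.lvid_d + m.ivs_d + m.lvpw_d) ** 3 - m.lvid_d**3
    )
    if fs < 0:
        warnings.warn("negative FS/EF (inverted diameters)", stacklevel=2)
    return EchoDerived(
        edv_ul=edv,
        esv_ul=esv,
        fs_pct=fs,
        ef_pct=ef,
        sv_ul=sv,
        co_ml_min=co,
        lv_mass_mg=lv_mass,
    )


def heart_tibia_ratio(heart_mg: float, tibia_mm: float) -> float:
    """Heart weight normalised to tibia length (mg/mm), a body-size proxy."""
    if heart_mg <= 0 or tibia_mm <= 0:
        raise DomainError("heart weight and tibia length must be positive")
    return heart_mg / tibia_mm


MEASURE_COLUMNS = [f.name for f in fields(MModeMeasures)]


def derive_echo_table(df: pd.DataFrame) -> pd.DataFrame:
    """Batch derivation from a measurement table.

    Expects one row per animal per replicate with an ``animal_id`` column and
    the :class:`MModeMeasures` columns; replicates are averaged in triplicate
    per animal (exactly 3 required) before derivation.
    """
    missing = [c for c in ["animal_id", *MEASURE_COLUMNS] if c not in df.columns]
    if missing:
        raise DomainError(f"measurement table missing columns {missing}")
    rows = []
    for animal, grp in df.groupby("animal_id", sort=False):
        reps = [
            MModeMeasures(**{c: float(r[c]) for c in MEASURE_COLUMNS})
            for _, r in grp.iterrows()
        ]
        avg = average_triplicate(reps)
        derived = derive_echo(avg)
        row = {"animal_id": animal}
        row.update({c: getattr(avg, c) for c in MEASURE_COLUMNS})
        row.update(derived.__dict__)
        if "genotype" in grp.columns:
            row["genotype"] = grp["genotype"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
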