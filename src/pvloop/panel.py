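"""Derived hemodynamic indices and group-contrast reproduction.

Implements the derived quantities of the hemodynamic panel: body surface
area from weight, BSA indexing (CO to CI, SV to SVi), systemic and
pulmonary vascular resistance indices (80 x pressure gradient / flow),
arterial elastance (ESP/SV) and the arterio-ventricular coupling ratios,
plus percent contrasts between the banded and control groups in the layout
of the study's baseline characteristics table.

Two conventions in the source protocol are ambiguous and both are exposed
rather than guessed:

* the resistance-index formulas are written per kilogram, but the printed
  magnitudes match the un-indexed formula; ``index_by_weight`` defaults
  OFF;
* coupling is defined in the text as Ees/Ea but tabulated as Ea/Ees; both
  ratios are returned, neither privileged.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "HemoPanel",
    "DerivedPanel",
    "bsa_from_weight",
    "index_to_bsa",
    "svri",
    "pvri",
    "arterial_elastance",
    "coupling",
    "percent_change",
    "load_reference_means",
    "reproduce_table1_contrasts",
    "recompute_control_pvri",
    "CONTRAST_ROWS",
]

#: Default power-law BSA coefficients for juvenile pigs: BSA = a * kg**b.
BSA_COEFF = 0.0734
BSA_EXP = 0.656


@dataclass
class HemoPanel:
    """Measured systemic panel for one subject at one stage.

    MAP/SAP/DAP/CVP in mmHg, CO in L/min, HR in beats/min, SvO2 in %,
    weight in kg, BSA in m²; RV_Pmean and LV_Pmin (mmHg) come from the
    ventricular beat summaries.  NT_proBNP (pg/ml) and lactate (mM) are
    passive fields carried through from sampling, never computed.
    """

    MAP: float
    SAP: float
    DAP: float
    CVP: float
    CO: float
    HR: float
    SvO2: float
    weight: float
    BSA: float
    RV_Pmean: float = np.nan
    LV_Pmin: float = np.nan
    NT_proBNP: float = np.nan
    lactate: float = np.nan

    def __post_init__(self) -> None:
        if not (self.DAP <= self.MAP <= self.SAP):
            raise ValueError(
                f"need DAP <= MAP <= SAP, got {self.DAP}/{self.MAP}/{self.SAP}")
        if self.CO <= 0 or self.weight <= 0 or self.BSA <= 0:
            raise ValueError("CO, weight and BSA must be positive")


@dataclass
class DerivedPanel:
    """Indices derived from a :class:`HemoPanel` and the beat analyses."""

    CI: float
    SVi: float
    SVRI: float
    PVRI: float
    Ea_RV: float = np.nan
    Ea_LV: float = np.nan
    coupling_EesOverEa_RV: float = np.nan
    coupling_EaOverEes_RV: float = np.nan
    coupling_EesOverEa_LV: float = np.nan
    coupling_EaOverEes_LV: float = np.nan


def bsa_from_weight(weight: float, coeff: float = BSA_COEFF,
                    exponent: float = BSA_EXP) -> float:
    """Body surface area (m²) from body weight (kg), power law."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    return coeff * weight ** exponent


def index_to_bsa(value: float, bsa: float) -> float:
    """Index a flow or volume to body surface area (CO→CI, SV→SVi)."""
    if bsa <= 0:
        raise ValueError("BSA must be positive")
    return value / bsa


def svri(MAP: float, CVP: float, CO: float, weight: float = np.nan,
         index_by_weight: bool = False) -> float:
    """Systemic vascular resistance index, 80·(MAP − CVP)/CO [dyn·s/cm⁵].

    ``index_by_weight`` divides by body weight (the formula as written in
    the source protocol); OFF by default because the tabulated magnitudes
    match the un-indexed value.
    """
    if CO <= 0:
        raise ValueError("CO must be positive")
    out = 80.0 * (MAP - CVP) / CO
    if index_by_weight:
        if not weight > 0:
            raise ValueError("weight must be positive when index_by_weight")
        out /= weight
    return out


def pvri(RV_Pmean: float, LV_Pmin: float, CO: float, weight: float = np.nan,
         index_by_weight: bool = False) -> float:
    """Pulmonary vascular resistance index, 80·(RV Pmean − LV Pmin)/CO.

    Uses the ventricular surrogate gradient (mean RV pressure minus
    minimum LV pressure); same optional weight indexing as :func:`svri`.
    """
    if CO <= 0:
        raise ValueError("CO must be positive")
    out = 80.0 * (RV_Pmean - LV_Pmin) / CO
    if index_by_weight:
        if not weight > 0:
            raise ValueError("weight must be positive when index_by_weight")
        out /= weight
    return out


def arterial_elastance(ESP: float, SV: float) -> float:
    """Arterial elastance Ea = ESP/SV, mmHg/ml (lumped afterload)."""
    if SV <= 0:
        raise ValueError("SV must be positive")
    return ESP / SV


def coupling(Ees: float, Ea: float) -> dict:
    """Arterio-ventricular coupling, both conventions.

    Returns ``{"Ees_over_Ea": ..., "Ea_over_Ees": ...}``; their product is
    1 by construction.
    """
    if Ees <= 0 or Ea <= 0:
        raise ValueError("Ees and Ea must be positive")
    return {"Ees_over_Ea": Ees / Ea, "Ea_over_Ees": Ea / Ees}


def percent_change(reference: float, value: float, rounded: bool = False):
    """100·(value/reference − 1); rounded to integer for table layouts."""
    if reference == 0:
        raise ValueError("zero reference")
    pct = 100.0 * (value / reference - 1.0)
    return int(round(pct)) if rounded else pct


# ---------------------------------------------------------------------------
# group-contrast table

#: Rows of the baseline characteristics table whose percent contrasts are
#: quoted in the study results.
CONTRAST_ROWS = ("CI", "SVi", "PVRI", "LV_EDV", "LV_ESV", "LV_EF",
                 "LV_Pmax", "RV_Pmax", "RV_dPdt_max")


def load_reference_means() -> pd.DataFrame:
    """The shipped baseline group means/SDs (control n=6, PAB n=5)."""
    with resources.files("pvloop.data").joinpath(
            "pab_study_group_means.csv").open() as fh:
        return pd.read_csv(fh, comment="#").set_index("variable")


def reproduce_table1_contrasts(means: pd.DataFrame | None = None,
                               rows: Iterable[str] | None = None) -> pd.DataFrame:
    """Percent change PAB vs control for every row of the group-means table.

    ``means`` needs columns ``control_mean`` and ``pab_mean`` indexed by
    variable (defaults to the shipped reference table).  Requested rows
    missing from the table are flagged with NaN contrasts rather than
    silently skipped.  Contrasts are ratios of group means, rounded to
    integer percent in the ``pct_change`` column (``pct_change_raw`` keeps
    full precision).
    """
    if means is None:
        means = load_reference_means()
    rows = list(rows) if rows is not None else list(means.index)
    out = []
    for name in rows:
        if name not in means.index:
            out.append({"variable": name, "control_mean": np.nan,
                        "pab_mean": np.nan, "pct_change_raw": np.nan,
                        "pct_change": np.nan, "missing": True})
            continue
        ref = float(means.loc[name, "control_mean"])
        val = float(means.loc[name, "pab_mean"])
        raw = percent_change(ref, val)
        out.append({"variable": name, "control_mean": ref, "pab_mean": val,
                    "pct_change_raw": raw, "pct_change": int(round(raw)),
                    "missing": False})
    return pd.DataFrame(out).set_index("variable")


def recompute_control_pvri(means: pd.DataFrame | None = None) -> float:
    """Recompute the control-group PVRI from its printed constituents.

    80·(RV_Pmean − LV_Pmin)/(CI·BSA) on group means — a ratio of means,
    which agrees with the tabulated mean of per-animal ratios only
    approximately (documented caveat).
    """
    if means is None:
        means = load_reference_means()
    co = float(means.loc["CI", "control_mean"]) * float(means.loc["BSA", "control_mean"])
    return pvri(float(means.loc["RV_Pmean", "control_mean"]),
                float(means.loc["LV_Pmin", "control_mean"]), co)
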