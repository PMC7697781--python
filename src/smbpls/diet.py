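"""Closed-form dietary and short-chain fatty acid arithmetic.

Covers the study-design side computations: total dietary fiber as the sum
of its measured fractions, relative energy contribution of the macro
components using FAO energy conversion factors (carbohydrate 17 kJ/g,
protein 17 kJ/g, fat 37 kJ/g, total dietary fiber 8 kJ/g), and the
aggregate SCFA panels (total SCFA, total organic acids, branched-chain
fatty acids, the acetic + propionic + butyric subtotal, and per-acid
proportions) for both fecal and plasma compartments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

# FAO energy conversion factors, kJ per g
ENERGY_FACTORS = {"carbohydrate": 17.0, "protein": 17.0, "fat": 37.0, "fiber": 8.0}

FIBER_FRACTIONS = ("total_nsp", "fructans", "resistant_starch", "klason_lignin", "axos")

#: acids entering each fecal aggregate
FECAL_SCFA = (
    "formic", "acetic", "propionic", "isobutyric", "n_butyric",
    "isovaleric", "n_valeric",
)
FECAL_EXTRA_ORGANIC = (
    "isocaproic", "n_caproic", "heptanoic", "sorbic", "benzoic",
    "dl_lactic", "succinic", "hippuric",
)
FECAL_BCFA = ("isobutyric", "isovaleric", "isocaproic")
FECAL_APB = ("acetic", "propionic", "n_butyric")

#: acids entering each plasma aggregate
PLASMA_SCFA = ("acetic", "propionic", "butyric", "valeric", "isobutyric", "isovaleric")
PLASMA_EXTRA_ORGANIC = ("succinic",)
PLASMA_BCFA = ("isobutyric", "isovaleric")
PLASMA_APB = ("acetic", "propionic", "butyric")

ACID_VOCABULARY = frozenset(FECAL_SCFA) | frozenset(FECAL_EXTRA_ORGANIC) | \
    frozenset(PLASMA_SCFA) | frozenset(PLASMA_EXTRA_ORGANIC)


@dataclass(frozen=True)
class DietSpec:
    """Chemical composition of a diet in g/kg dry matter."""

    available_carbohydrates: float
    protein: float
    fat: float
    total_dietary_fiber: float
    total_nsp: Optional[float] = None
    fructans: Optional[float] = None
    resistant_starch: Optional[float] = None
    klason_lignin: Optional[float] = None
    axos: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "available_carbohydrates", "protein", "fat", "total_dietary_fiber",
            *FIBER_FRACTIONS,
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass
class ScfaPanel:
    """Named-acid concentrations per sample.

    ``concentrations``: samples x acids DataFrame (mmol/kg feces or
    umol/L plasma); ``compartment``: ``"fecal"`` or ``"plasma"``.
    """

    concentrations: pd.DataFrame
    compartment: str

    def __post_init__(self) -> None:
        if self.compartment not in {"fecal", "plasma"}:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        unknown = set(self.concentrations.columns) - ACID_VOCABULARY
        if unknown:
            raise ValueError(f"unknown acid name(s): {sorted(unknown)}")
        if (self.concentrations.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative SCFA concentration")


def total_dietary_fiber(spec: DietSpec) -> float:
    """Total dietary fiber = total NSP + fructans + RS + Klason lignin + AXOS."""
    missing = [f for f in FIBER_FRACTIONS if getattr(spec, f) is None]
    if missing:
        raise ValueError(f"missing fiber fraction(s): {missing}")
    return float(sum(getattr(spec, f) for f in FIBER_FRACTIONS))


def diet_energy_contribution(spec: DietSpec) -> dict[str, float]:
    """Relative energy contribution (%) of carbohydrate, fat, protein, fiber.

    Component energies are g/kg DM times the FAO factors; each percentage is
    the component energy over the sum of the four, reported to one decimal.
    """
    energies = {
        "carbohydrate": spec.available_carbohydrates * ENERGY_FACTORS["carbohydrate"],
        "protein": spec.protein * ENERGY_FACTORS["protein"],
        "fat": spec.fat * ENERGY_FACTORS["fat"],
        "fiber": spec.total_dietary_fiber * ENERGY_FACTORS["fiber"],
    }
    total = sum(energies.values())
    if total == 0:
        raise ValueError("zero energy: all diet components are zero")
    return {k: round(100.0 * v / total, 1) for k, v in energies.items()}


def _require(panel: ScfaPanel, acids: tuple[str, ...]) -> pd.DataFrame:
    missing = [a for a in acids if a not in panel.concentrations.columns]
    if missing:
        raise ValueError(
            f"{panel.compartment} panel missing required acid(s): {missing}"
        )
    return panel.concentrations[list(acids)]


def scfa_totals(panel: ScfaPanel) -> pd.DataFrame:
    """Derived sums and proportions per sample for an SCFA panel.

    Returns a DataFrame indexed like the panel with columns
    ``total_scfa``, ``total_organic``, ``bcfa``, ``apb``, per-acid
    ``pct_tscfa_<acid>`` (% of total SCFA) and ``pct_apb_<acid>``
    (% of the acetic+propionic+butyric subtotal).  Proportions are NaN
    where the corresponding total is zero.
    """
    if panel.compartment == "fecal":
        scfa_acids, extra, bcfa_acids, apb_acids = (
            FECAL_SCFA, FECAL_EXTRA_ORGANIC, FECAL_BCFA, FECAL_APB,
        )
    else:
        scfa_acids, extra, bcfa_acids, apb_acids = (
            PLASMA_SCFA, PLASMA_EXTRA_ORGANIC, PLASMA_BCFA, PLASMA_APB,
        )

    scfa = _require(panel, scfa_acids)
    extra_df = _require(panel, extra)
    bcfa = _require(panel, bcfa_acids)
    apb = _require(panel, apb_acids)

    out = pd.DataFrame(index=panel.concentrations.index)
    out["total_scfa"] = scfa.sum(axis=1)
    out["total_organic"] = out["total_scfa"] + extra_df.sum(axis=1)
    out["bcfa"] = bcfa.sum(axis=1)
    out["apb"] = apb.sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        tot = out["total_scfa"].to_numpy()
        for acid in scfa_acids:
            out[f"pct_tscfa_{acid}"] = np.where(
                tot > 0, 100.0 * scfa[acid].to_numpy() / tot, np.nan
            )
        apb_tot = out["apb"].to_numpy()
        for acid in apb_acids:
            out[f"pct_apb_{acid}"] = np.where(
                apb_tot > 0, 100.0 * apb[acid].to_numpy() / apb_tot, np.nan
            )
    return out
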