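"""Biomass consumption, combustion completeness and carbon accounting.

Implements the bottom-up fire emission bookkeeping: per-pixel biomass
consumption as the difference of pre- and post-fire AGB maps, aggregation
to burn-severity strata in teragrams, the Seiler-Crutzen product
``Cr = A * B * f_c * beta`` (area x biomass density x carbon fraction x
combustion completeness), carbon release with the conventional f_c = 0.5
and its CO2-equivalent via the 44/12 molar mass ratio, plus the dilution-
bias correction of model estimates by an observed-vs-estimated linear
regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extrapolation import AGBMap
from .scene import SEVERITY_CODES

__all__ = [
    "EmissionInputs",
    "EmissionReport",
    "bias_correct",
    "consumption_map",
    "aggregate_by_stratum",
    "carbon_release",
    "co2_equivalent",
    "combustion_completeness",
    "seiler_crutzen",
]

log = logging.getLogger(__name__)

CO2_PER_C = 44.0 / 12.0
BURNED_STRATA = ("low", "moderate", "high")


@dataclass
class EmissionInputs:
    """Seiler-Crutzen factors for one stratum."""

    area_ha: float
    biomass_Mg_ha: float
    carbon_fraction: float = 0.5
    combustion_completeness: float = 1.0

    def __post_init__(self) -> None:
        if min(self.area_ha, self.biomass_Mg_ha) < 0:
            raise ValueError("area and biomass must be non-negative")
        for name in ("carbon_fraction", "combustion_completeness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class EmissionReport:
    """Per-stratum and total consumption / carbon rows for one method pair."""

    method_pair: str
    table: pd.DataFrame = field(repr=False)
    by_vegtype: pd.DataFrame | None = field(default=None, repr=False)

    def total(self, column: str = "delta_biomass_Tg") -> float:
        return float(self.table.loc["total", column])


def bias_correct(
    agb_map: AGBMap, observed: np.ndarray, estimated: np.ndarray
) -> AGBMap:
    """Remove dilution bias with an observed-vs-estimated linear fit.

    Model predictions regress toward the mean (high biomass under-, low
    biomass over-estimated); fitting ``observed = a + b * estimated`` on the
    reference pairs and applying ``a + b * x`` per pixel restores the scale.
    Negatives are clipped to zero; the coefficients are stored on the map.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    estimated = np.asarray(estimated, dtype=float).ravel()
    ok = np.isfinite(observed) & np.isfinite(estimated)
    if int(ok.sum()) < 20:
        raise ValueError("need at least 20 reference pairs for bias correction")
    est = estimated[ok]
    if est.std() == 0:
        raise ValueError("zero variance of estimates: bias fit undefined")
    b, a = np.polyfit(est, observed[ok], 1)
    corrected = np.maximum(a + b * agb_map.values, 0.0)
    corrected[~np.isfinite(agb_map.values)] = np.nan
    return AGBMap(corrected, provenance=agb_map.provenance,
                  bias_corrected=True, bias_coefficients=(float(a), float(b)))


def consumption_map(pre: AGBMap, post: AGBMap) -> np.ndarray:
    """Per-pixel consumed biomass, pre minus post (Mg/ha).

    Negative pixels (post above pre, possible when the two maps carry
    independent model noise) are retained so that stratum sums stay
    unbiased; the negative-mass share is logged as a diagnostic.
    """
    if pre.shape != post.shape:
        raise ValueError(f"grid mismatch: {pre.shape} vs {post.shape}")
    delta = pre.values - post.values
    finite = np.isfinite(delta)
    if finite.any():
        neg = float(np.mean(delta[finite] < 0))
        if neg > 0:
            log.info("consumption_map: %.1f%% negative-consumption pixels",
                     100 * neg)
    return delta


def aggregate_by_stratum(
    delta: np.ndarray,
    severity: np.ndarray,
    vegtype: np.ndarray | None = None,
    pixel_area_ha: float = 0.09,
    method_pair: str = "",
) -> EmissionReport:
    """Consumed biomass per burn-severity stratum, in Tg.

    ``delta`` is Mg/ha per pixel; each pixel contributes
    ``delta * pixel_area_ha * 1e-6`` Tg.  The total row covers the burned
    strata only (low + moderate + high).  Unknown severity codes raise.
    """
    severity = np.asarray(severity)
    known = set(SEVERITY_CODES.values())
    present = set(np.unique(severity[np.isfinite(severity)]).astype(int).tolist())
    if not present <= known:
        raise ValueError(f"unknown severity codes {sorted(present - known)}")
    delta = np.asarray(delta, dtype=float)
    rows = {}
    for name, code in SEVERITY_CODES.items():
        m = (severity == code) & np.isfinite(delta)
        mass = float(delta[m].sum()) * pixel_area_ha * 1e-6
        rows[name] = {
            "delta_biomass_Tg": mass,
            "n_pixels": int(m.sum()),
            "area_ha": float(m.sum()) * pixel_area_ha,
        }
    total = {
        "delta_biomass_Tg": sum(rows[s]["delta_biomass_Tg"] for s in BURNED_STRATA),
        "n_pixels": sum(rows[s]["n_pixels"] for s in BURNED_STRATA),
        "area_ha": sum(rows[s]["area_ha"] for s in BURNED_STRATA),
    }
    rows["total"] = total
    table = pd.DataFrame(rows).T
    table["carbon_TgC"] = carbon_release(table["delta_biomass_Tg"].to_numpy())
    table["co2e_Tg"] = co2_equivalent(table["carbon_TgC"].to_numpy())
    report = EmissionReport(method_pair=method_pair, table=table)
    if vegtype is not None:
        report.by_vegtype = _crosstab_vegtype(delta, severity, vegtype,
                                              pixel_area_ha)
    return report


def _crosstab_vegtype(delta, severity, vegtype, pixel_area_ha):
    """Severity x vegetation-type consumption cross-tabulation (Tg)."""
    vegtype = np.asarray(vegtype)
    rows = {}
    for sev_name, sev_code in SEVERITY_CODES.items():
        for veg in np.unique(vegtype[np.isfinite(vegtype)]):
            m = (severity == sev_code) & (vegtype == veg) & np.isfinite(delta)
            rows[(sev_name, int(veg))] = float(delta[m].sum()) \
                * pixel_area_ha * 1e-6
    out = pd.Series(rows).unstack()
    out.columns = [f"vegtype_{c}" for c in out.columns]
    return out


def carbon_release(delta_biomass_Tg, carbon_fraction: float = 0.5):
    """Released carbon (TgC) from consumed biomass (Tg)."""
    return carbon_fraction * np.asarray(delta_biomass_Tg, dtype=float)


def co2_equivalent(carbon_TgC):
    """CO2-equivalent mass (Tg) from released carbon, CO2 stoichiometry only."""
    return CO2_PER_C * np.asarray(carbon_TgC, dtype=float)


def combustion_completeness(
    delta_biomass: float, prefire_biomass: float
) -> float:
    """Fraction of the pre-fire stock consumed, clipped to [0, 1]."""
    if prefire_biomass <= 0:
        raise ValueError("zero pre-fire stock: combustion completeness undefined")
    cc = delta_biomass / prefire_biomass
    if not 0.0 <= cc <= 1.0:
        log.info("combustion_completeness: clipped %.3f into [0, 1]", cc)
    return float(np.clip(cc, 0.0, 1.0))


def seiler_crutzen(inputs: EmissionInputs) -> float:
    """Released carbon in Mg C: ``Cr = A * B * f_c * beta``."""
    return (inputs.area_ha * inputs.biomass_Mg_ha
            * inputs.carbon_fraction * inputs.combustion_completeness)
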