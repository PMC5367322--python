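"""Fire-specific correction of the median canopy height (H50).

Standing dead trees (snags) keep the upper canopy returns while the fire
removes most of the canopy material, so the median height of the surviving
returns stays high while the canopy waveform energy collapses.  A biomass
model that leans on H50 then grossly overestimates post-fire AGB in
high-severity cells.

The correction exploits the tight relationship between H50 and the area
under the canopy waveform (AUCW) over intact forest: a power law
``AUCW = a * H50**b`` is fitted on unburned cells, and every cell inside
the fire perimeter (all severity levels — severity maps understate damage
to mid- and understory vegetation) gets its H50 down-weighted by the ratio
of the observed to the expected canopy energy:

    w = min(1, AUCW_obs / g(H50_obs)),    H50_corr = w * H50_obs.

Cells on the reference curve are untouched; fully defoliated cells go to
zero; the weight never exceeds one because fire only removes canopy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .svr import LSSVRModel

__all__ = [
    "H50AUCWReference",
    "fit_h50_aucw_reference",
    "correct_h50",
    "corrected_agb_map",
]


class DegenerateReferenceError(ValueError):
    """H50 has (near-)zero spread: no curve can be fitted."""


@dataclass
class H50AUCWReference:
    """Power-law reference curve g: H50 -> expected AUCW over intact forest."""

    a: float
    b: float
    n_cells: int
    r2_log: float

    def __call__(self, h50: np.ndarray) -> np.ndarray:
        h50 = np.asarray(h50, dtype=float)
        out = np.zeros_like(h50)
        pos = h50 > 0
        out[pos] = self.a * h50[pos] ** self.b
        return out


def fit_h50_aucw_reference(
    h50: np.ndarray,
    aucw: np.ndarray,
    min_cells: int = 30,
) -> H50AUCWReference:
    """Fit ``AUCW = a * H50**b`` by least squares in log-log space.

    Non-positive values are excluded from the fit; fewer than ``min_cells``
    usable cells, or an H50 spread too small to constrain the exponent,
    raises.
    """
    h50 = np.asarray(h50, dtype=float).ravel()
    aucw = np.asarray(aucw, dtype=float).ravel()
    ok = np.isfinite(h50) & np.isfinite(aucw) & (h50 > 0) & (aucw > 0)
    if int(ok.sum()) < min_cells:
        raise ValueError(f"only {int(ok.sum())} usable unburned cells "
                         f"(need >= {min_cells})")
    lx = np.log(h50[ok])
    ly = np.log(aucw[ok])
    if lx.std() < 1e-6:
        raise DegenerateReferenceError("constant H50: reference curve degenerate")
    A = np.column_stack([np.ones(lx.size), lx])
    coef, *_ = np.linalg.lstsq(A, ly, rcond=None)
    pred = A @ coef
    sst = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - float(((ly - pred) ** 2).sum()) / sst if sst > 0 else 1.0
    return H50AUCWReference(a=float(np.exp(coef[0])), b=float(coef[1]),
                            n_cells=int(ok.sum()), r2_log=r2)


def correct_h50(
    metrics: dict[str, np.ndarray],
    reference: H50AUCWReference,
    burned_mask: np.ndarray,
) -> dict[str, np.ndarray]:
    """Return a metric stack with H50 re-weighted inside the burned mask.

    Where the reference predicts zero canopy energy the weight is 1 (no
    evidence of loss); outside the mask every metric is untouched.
    """
    h50 = np.asarray(metrics["H50"], dtype=float)
    aucw = np.asarray(metrics["AUCW"], dtype=float)
    expected = reference(h50)
    w = np.ones_like(h50)
    ok = burned_mask & np.isfinite(h50) & np.isfinite(aucw) & (expected > 0)
    w[ok] = np.minimum(1.0, aucw[ok] / expected[ok])
    out = dict(metrics)
    out["H50"] = np.where(burned_mask & np.isfinite(h50), w * h50, h50)
    out["h50_weight"] = w
    return out


def corrected_agb_map(
    corrected_metrics: dict[str, np.ndarray],
    model: LSSVRModel,
) -> np.ndarray:
    """Apply the already-trained LiDAR model to the corrected metric stack.

    No refit: the model was calibrated on intact (unburned) structure and is
    reused unchanged, so unburned cells map bit-for-bit to the uncorrected
    prediction.
    """
    missing = [f for f in model.feature_names if f not in corrected_metrics]
    if missing:
        raise KeyError(f"corrected stack lacks model features: {missing}")
    bands = [np.asarray(corrected_metrics[f], dtype=float)
             for f in model.feature_names]
    shape = bands[0].shape
    X = np.stack([b.ravel() for b in bands], axis=1)
    ok = np.all(np.isfinite(X), axis=1)
    out = np.full(X.shape[0], np.nan)
    if ok.any():
        out[ok] = model.predict(X[ok])
    return out.reshape(shape)
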