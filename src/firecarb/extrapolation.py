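"""Spatio-temporal extrapolation of LiDAR biomass with multispectral data.

Second step of the two-step chain: the LiDAR-based AGB map (available only
where LiDAR was flown, and only post-fire) is used as reference to train
optical regression models, which then predict wall-to-wall AGB maps from
the pre-fire and post-fire reflectance feature stacks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .svr import LSSVRModel

__all__ = ["build_training_table", "predict_agb_map", "AGBMap"]

log = logging.getLogger(__name__)


class AGBMap:
    """A gridded biomass map (Mg/ha) with provenance bookkeeping."""

    PROVENANCES = ("lidar", "lidar_corrected", "landsat_pre", "landsat_post")

    def __init__(self, values: np.ndarray, provenance: str,
                 bias_corrected: bool = False,
                 bias_coefficients: tuple[float, float] | None = None):
        if provenance not in self.PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        self.values = np.asarray(values, dtype=float)
        self.provenance = provenance
        self.bias_corrected = bias_corrected
        self.bias_coefficients = bias_coefficients

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_training_table(
    sample_idx: np.ndarray,
    features: dict[str, np.ndarray],
    reference_agb: np.ndarray,
    feature_names: tuple[str, ...],
    min_rows: int = 100,
) -> pd.DataFrame:
    """Join optical features with reference AGB at the sampled pixels.

    ``sample_idx`` holds flat raster indices (the output of the stratified
    histogram sampler).  Rows with any nodata value are dropped and logged;
    fewer than ``min_rows`` complete rows raises.
    """
    cols = {name: np.asarray(features[name], dtype=float).ravel()[sample_idx]
            for name in feature_names}
    cols["agb"] = np.asarray(reference_agb, dtype=float).ravel()[sample_idx]
    table = pd.DataFrame(cols, index=sample_idx)
    complete = table.dropna()
    dropped = len(table) - len(complete)
    if dropped:
        log.info("build_training_table: dropped %d nodata rows of %d",
                 dropped, len(table))
    if len(complete) < min_rows:
        raise ValueError(f"only {len(complete)} complete training rows "
                         f"(need >= {min_rows})")
    return complete


def predict_agb_map(
    model: LSSVRModel,
    features: dict[str, np.ndarray],
    provenance: str,
) -> AGBMap:
    """Per-pixel model prediction over a feature stack.

    Negative predictions are clipped to zero (with a logged count); nodata
    pixels propagate as NaN.
    """
    missing = [f for f in model.feature_names if f not in features]
    if missing:
        raise KeyError(f"feature stack lacks model features: {missing}")
    bands = [np.asarray(features[f], dtype=float) for f in model.feature_names]
    shape = bands[0].shape
    X = np.stack([b.ravel() for b in bands], axis=1)
    ok = np.all(np.isfinite(X), axis=1)
    pred = np.full(X.shape[0], np.nan)
    if ok.any():
        pred[ok] = model.predict(X[ok])
    negatives = int(np.sum(pred[ok] < 0))
    if negatives:
        log.info("predict_agb_map(%s): clipped %d negative pixels",
                 provenance, negatives)
    pred[ok] = np.maximum(pred[ok], 0.0)
    return AGBMap(pred.reshape(shape), provenance=provenance)
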