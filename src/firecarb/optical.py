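"""Optical predictor stack: band indices, tasseled cap, textures, terrain.

Derives the multispectral features used to extrapolate LiDAR-based biomass
estimates in space and time: the six reflectance bands (B2-B7), four
vegetation indices (NDVI, NDII, EVI, VARI), the tasseled cap brightness /
greenness / wetness components with the angle and distance summaries, gray
level co-occurrence matrix (GLCM) textures, and terrain layers (elevation
block-averaged to 30 m, slope and aspect by Horn's method).

Texture bands are computed on demand but excluded from the default model
feature set: window statistics imprint their own spatial pattern on the
prediction maps, an artifact that outweighs their predictive value here.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import graycomatrix

__all__ = [
    "BAND_NAMES",
    "TASSELED_CAP_OLI",
    "vegetation_indices",
    "tasseled_cap",
    "glcm_textures",
    "terrain_features",
    "build_feature_stack",
]

BAND_NAMES = ("B2", "B3", "B4", "B5", "B6", "B7")

#: Tasseled cap coefficients for Landsat 8 OLI surface reflectance bands 2-7
#: (brightness, greenness, wetness rows; Baig et al. 2014).
TASSELED_CAP_OLI = np.array([
    [0.3029, 0.2786, 0.4733, 0.5599, 0.5080, 0.1872],
    [-0.2941, -0.2430, -0.5424, 0.7276, 0.0713, -0.1608],
    [0.1511, 0.1973, 0.3283, 0.3407, -0.7117, -0.4559],
])


def _require(stack: dict[str, np.ndarray], *names: str) -> list[np.ndarray]:
    out = []
    for n in names:
        if n not in stack:
            raise KeyError(f"missing band {n!r}")
        out.append(np.asarray(stack[n], dtype=float))
    return out


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    return out


def vegetation_indices(stack: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """NDVI, NDII, EVI and VARI from a named band dictionary.

    Band semantics: B2 blue, B3 green, B4 red, B5 NIR, B6 SWIR1.  Zero
    denominators propagate as NaN (nodata).
    """
    blue, green, red, nir, swir1 = _require(stack, "B2", "B3", "B4", "B5", "B6")
    return {
        "NDVI": _safe_ratio(nir - red, nir + red),
        "NDII": _safe_ratio(nir - swir1, nir + swir1),
        "EVI": _safe_ratio(2.5 * (nir - red), nir + 6.0 * red - 7.5 * blue + 1.0),
        "VARI": _safe_ratio(green - red, green + red - blue),
    }


def tasseled_cap(stack: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Brightness/greenness/wetness plus the angle and distance summaries."""
    bands = np.stack(_require(stack, *BAND_NAMES))
    flat = bands.reshape(6, -1)
    bgw = TASSELED_CAP_OLI @ flat
    brightness, greenness, wetness = (x.reshape(bands.shape[1:]) for x in bgw)
    return {
        "TC_brightness": brightness,
        "TC_greenness": greenness,
        "TC_wetness": wetness,
        "TC_angle": np.arctan2(greenness, brightness),
        "TC_distance": np.hypot(brightness, greenness),
    }


def _glcm_stats(P: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """homogeneity, contrast, SD, entropy, ASM, correlation of one matrix."""
    levels = P.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())
    contrast = float((P * (i - j) ** 2).sum())
    asm = float((P ** 2).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    mu_i = float((P * i).sum())
    mu_j = float((P * j).sum())
    var_i = float((P * (i - mu_i) ** 2).sum())
    var_j = float((P * (j - mu_j) ** 2).sum())
    sd = float(np.sqrt(var_i))
    if var_i > 0 and var_j > 0:
        corr = float((P * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j))
    else:
        corr = 0.0
    return homogeneity, contrast, sd, entropy, asm, corr


TEXTURE_NAMES = ("homogeneity", "contrast", "sd", "entropy", "asm", "correlation")


def quantize(band: np.ndarray, levels: int = 64) -> np.ndarray:
    """Min-max quantization of a raster to ``levels`` gray levels."""
    band = np.asarray(band, dtype=float)
    lo, hi = float(np.nanmin(band)), float(np.nanmax(band))
    if hi <= lo:
        return np.zeros(band.shape, dtype=np.uint8)
    q = np.floor((band - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm_textures(
    band: np.ndarray,
    window: int = 7,
    levels: int = 64,
) -> dict[str, np.ndarray]:
    """Six isotropic GLCM textures in a sliding window.

    The co-occurrence matrix of each window is symmetric, averaged over the
    four one-pixel offsets (0, 45, 90, 135 degrees) and normalized; edges
    are mirror-padded.  A constant window yields contrast 0, ASM 1, entropy
    0, homogeneity 1 and correlation defined as 0.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    q = quantize(band, levels)
    pad = window // 2
    qp = np.pad(q, pad, mode="reflect")
    rows, cols = q.shape
    out = {name: np.empty((rows, cols)) for name in TEXTURE_NAMES}
    angles = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
    for r in range(rows):
        for c in range(cols):
            win = qp[r:r + window, c:c + window]
            glcm = graycomatrix(win, distances=[1], angles=angles,
                                levels=levels, symmetric=True, normed=False)
            P = glcm[:, :, 0, :].sum(axis=2).astype(float)
            total = P.sum()
            P = P / total if total > 0 else P
            for name, val in zip(TEXTURE_NAMES, _glcm_stats(P)):
                out[name][r, c] = val
    return out


def block_mean(raster: np.ndarray, factor: int) -> np.ndarray:
    """Average ``factor x factor`` blocks (fine DEM -> 30 m elevation)."""
    rows, cols = raster.shape
    if rows % factor or cols % factor:
        raise ValueError("raster shape must be a multiple of the block factor")
    return raster.reshape(rows // factor, factor, cols // factor, factor).mean(axis=(1, 3))


def terrain_features(
    dem: np.ndarray,
    cell_size_m: float = 30.0,
    resample_factor: int = 1,
) -> dict[str, np.ndarray]:
    """Elevation (block-averaged), slope and aspect.

    Slope (degrees) and aspect (degrees clockwise from north; NaN where
    flat) use Horn's 3x3 finite differences on the 30 m elevation grid,
    with edge rows/columns mirrored.
    """
    if resample_factor > 1:
        dem = block_mean(dem, resample_factor)
    z = np.pad(np.asarray(dem, dtype=float), 1, mode="edge")
    # Horn kernel weights
    dzdx = ((z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
            - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])) / (8 * cell_size_m)
    dzdy = ((z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
            - (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])) / (8 * cell_size_m)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    aspect = np.degrees(np.arctan2(-dzdx, dzdy))  # 0 = north, clockwise
    aspect = np.mod(aspect, 360.0)
    aspect[(dzdx == 0) & (dzdy == 0)] = np.nan
    return {"elevation": dem, "slope": slope, "aspect": aspect}


def build_feature_stack(
    reflectance: np.ndarray,
    dem: np.ndarray,
    include_textures: bool = False,
    texture_window: int = 7,
) -> dict[str, np.ndarray]:
    """Full named feature dictionary from a (6, rows, cols) stack + DEM."""
    stack = {name: reflectance[k] for k, name in enumerate(BAND_NAMES)}
    stack.update(vegetation_indices(stack))
    stack.update(tasseled_cap({n: stack[n] for n in BAND_NAMES}))
    stack.update(terrain_features(dem))
    if include_textures:
        for name in BAND_NAMES:
            tex = glcm_textures(stack[name], window=texture_window)
            stack.update({f"{name}_{t}": v for t, v in tex.items()})
    return stack
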