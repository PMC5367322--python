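"""Per-cell LiDAR metrics on a 30 m grid.

Computes the 41 structural, intensity and pseudowaveform metrics used to
model aboveground biomass (AGB) from discrete-return airborne LiDAR:

* 16 canopy-height metrics (percentiles, moments, inter-percentile ranges,
  canopy depth, fractional cover from return counts),
* 19 intensity metrics after range normalization (percentiles, moments,
  accumulated-intensity fractions at the height percentiles, energy-based
  fractional cover, canopy reflection sum and its density-weighted variant),
* 6 pseudowaveform metrics (height of median energy, height/median ratio,
  mean and quadratic-mean canopy height, canopy-height-profile variation
  and the area under the canopy waveform, AUCW).

Returns are assumed height-normalized (height above ground). "Canopy"
means height above a threshold, 2 m by default, the standard convention
for separating vegetation hits from ground and understory clutter.

Percentiles use linear interpolation between order statistics throughout;
kurtosis is reported as non-excess (Pearson) kurtosis and skewness as the
standardized third moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PointCloudTile",
    "Pseudowaveform",
    "METRIC_NAMES",
    "normalize_intensity",
    "height_metrics",
    "intensity_metrics",
    "build_pseudowaveform",
    "waveform_metrics",
    "all_metrics",
    "rasterize_metrics",
]

#: Canonical metric order: 16 height + 19 intensity + 6 pseudowaveform = 41.
METRIC_NAMES = (
    # height
    "H25", "H50", "H75", "H90", "H99",
    "mean_h", "sd_h", "kurt_h", "skew_h", "cv_h",
    "H99_H50", "H99_H25", "H90_H50", "H90_H25", "canopy_depth",
    "cover_ratio",
    # intensity
    "I25", "I50", "I75", "I90", "I99",
    "mean_i", "kurt_i", "range_i", "skew_i", "cv_i", "sd_i",
    "AI_H25", "AI_H50", "AI_H75", "AI_H90", "AI_H99",
    "FC_energy", "CRS", "dwCRS",
    # pseudowaveform
    "HOME", "height_median_ratio", "mean_canopy_height", "QMCH",
    "CHP_cv", "AUCW",
)

_HEIGHT_TOL = -0.5  # small negative heights tolerated after normalization


class EmptyTileError(ValueError):
    """Raised when a metric is requested for a tile with no returns."""


class MissingRangeError(ValueError):
    """Raised when intensity normalization is requested without range data."""


@dataclass
class PointCloudTile:
    """Height-normalized returns of one 30 m grid cell.

    ``intensity`` is raw (range-dependent) until :func:`normalize_intensity`
    has been applied, tracked by ``intensity_normalized``.
    """

    height_m: np.ndarray
    intensity: np.ndarray
    range_m: np.ndarray | None = None
    return_number: np.ndarray | None = None
    cell_id: tuple[int, int] | None = None
    cell_area_m2: float = 900.0
    intensity_normalized: bool = False
    empty_flag: bool = False

    def __post_init__(self) -> None:
        self.height_m = np.asarray(self.height_m, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.range_m is not None:
            self.range_m = np.asarray(self.range_m, dtype=float)
        if self.return_number is not None:
            self.return_number = np.asarray(self.return_number, dtype=int)
        if self.height_m.size and self.height_m.min() < _HEIGHT_TOL:
            raise ValueError(
                f"heights below {_HEIGHT_TOL} m: normalize to height above ground first"
            )
        if self.intensity.size and self.intensity.min() < 0:
            raise ValueError("negative intensities")

    @property
    def n_returns(self) -> int:
        return int(self.height_m.size)

    @property
    def n_pulses(self) -> int:
        """Pulse count: first returns if return numbers exist, else all returns."""
        if self.return_number is not None and self.return_number.size:
            return int(np.sum(self.return_number == 1))
        return self.n_returns


@dataclass
class Pseudowaveform:
    """Height-binned return energy emulating a full-waveform signal."""

    bin_edges: np.ndarray
    amplitude: np.ndarray
    total_energy: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.bin_edges.size != self.amplitude.size + 1:
            raise ValueError("need len(bin_edges) == len(amplitude) + 1")
        widths = np.diff(self.bin_edges)
        if widths.size and widths.min() <= 0:
            raise ValueError("bin width must be > 0")
        self.total_energy = float(self.amplitude.sum())

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def normalize_intensity(
    tile: PointCloudTile, reference_range_m: float | None = None
) -> PointCloudTile:
    """Correct raw intensities for range via the inverse-square law.

    ``I_norm = I_raw * (range / reference_range)**2`` so that a return at the
    reference range is unchanged.  ``reference_range_m`` defaults to the tile
    mean range (scene-level callers should pass the scene mean).
    """
    if tile.range_m is None:
        raise MissingRangeError("tile has no range field; cannot normalize intensity")
    if tile.range_m.size and tile.range_m.min() <= 0:
        raise MissingRangeError("ranges must be positive")
    if reference_range_m is None:
        reference_range_m = float(tile.range_m.mean()) if tile.range_m.size else 1.0
    scaled = tile.intensity * (tile.range_m / reference_range_m) ** 2
    return PointCloudTile(
        height_m=tile.height_m,
        intensity=scaled,
        range_m=tile.range_m,
        return_number=tile.return_number,
        cell_id=tile.cell_id,
        cell_area_m2=tile.cell_area_m2,
        intensity_normalized=True,
        empty_flag=tile.empty_flag,
    )


def _moments(x: np.ndarray) -> tuple[float, float, float, float, float]:
    """mean, sample sd, Pearson kurtosis, skewness, CV (degenerate -> 0)."""
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    if sd > 0:
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
        skew = float(stats.skew(x, bias=True))
        cv = sd / mean if mean != 0 else 0.0
    else:
        kurt = skew = cv = 0.0
    return mean, sd, kurt, skew, cv


def height_metrics(
    tile: PointCloudTile, canopy_threshold_m: float = 2.0
) -> dict[str, float]:
    """The 16 canopy-height metrics of one tile.

    Percentiles and moments are computed over canopy returns (height above
    the threshold); ``cover_ratio`` is the share of canopy returns among all
    returns.  A tile without canopy returns yields zeros for the canopy
    statistics while ``cover_ratio`` is still defined.
    """
    if tile.n_returns == 0:
        raise EmptyTileError("no returns in tile")
    h = tile.height_m
    canopy = h[h > canopy_threshold_m]
    out: dict[str, float] = {}
    if canopy.size:
        q = np.percentile(canopy, [25, 50, 75, 90, 99])
        out.update(zip(("H25", "H50", "H75", "H90", "H99"), map(float, q)))
        mean, sd, kurt, skew, cv = _moments(canopy)
        out.update(mean_h=mean, sd_h=sd, kurt_h=kurt, skew_h=skew, cv_h=cv)
        out["canopy_depth"] = float(canopy.max() - canopy.min())
    else:
        for k in ("H25", "H50", "H75", "H90", "H99",
                  "mean_h", "sd_h", "kurt_h", "skew_h", "cv_h", "canopy_depth"):
            out[k] = 0.0
    out["H99_H50"] = out["H99"] - out["H50"]
    out["H99_H25"] = out["H99"] - out["H25"]
    out["H90_H50"] = out["H90"] - out["H50"]
    out["H90_H25"] = out["H90"] - out["H25"]
    out["cover_ratio"] = float(canopy.size / tile.n_returns)
    return out


def intensity_metrics(
    tile: PointCloudTile, canopy_threshold_m: float = 2.0
) -> dict[str, float]:
    """The 19 intensity metrics of one tile (expects normalized intensities).

    ``AI_Hp`` is the accumulated canopy intensity below the height percentile
    Hp, as a fraction of the total canopy intensity (density-invariant by
    construction).  ``FC_energy`` is canopy energy over total energy; ``CRS``
    the canopy reflection sum; ``dwCRS`` the CRS per unit return density.
    Zero total intensity makes every energy ratio 0.
    """
    if tile.n_returns == 0:
        raise EmptyTileError("no returns in tile")
    h = tile.height_m
    i = tile.intensity
    mask = h > canopy_threshold_m
    ci, ch = i[mask], h[mask]
    out: dict[str, float] = {}
    if ci.size:
        q = np.percentile(ci, [25, 50, 75, 90, 99])
        out.update(zip(("I25", "I50", "I75", "I90", "I99"), map(float, q)))
        mean, sd, kurt, skew, cv = _moments(ci)
        out.update(mean_i=mean, kurt_i=kurt, range_i=float(ci.max() - ci.min()),
                   skew_i=skew, cv_i=cv, sd_i=sd)
        hp = np.percentile(ch, [25, 50, 75, 90, 99])
        total_canopy = float(ci.sum())
        for name, p in zip(("AI_H25", "AI_H50", "AI_H75", "AI_H90", "AI_H99"), hp):
            out[name] = float(ci[ch <= p].sum() / total_canopy) if total_canopy > 0 else 0.0
    else:
        for k in ("I25", "I50", "I75", "I90", "I99", "mean_i", "kurt_i",
                  "range_i", "skew_i", "cv_i", "sd_i",
                  "AI_H25", "AI_H50", "AI_H75", "AI_H90", "AI_H99"):
            out[k] = 0.0
    total = float(i.sum())
    crs = float(ci.sum())
    out["FC_energy"] = crs / total if total > 0 else 0.0
    out["CRS"] = crs
    density = tile.n_returns / tile.cell_area_m2
    out["dwCRS"] = crs / density if density > 0 else 0.0
    return out


def build_pseudowaveform(
    tile: PointCloudTile, bin_width_m: float = 0.5
) -> Pseudowaveform:
    """Height-bin the return intensity into a pseudowaveform.

    Bins span [min(0, lowest return), highest return] with uniform width;
    each bin amplitude is the summed intensity of the returns it contains.
    Total energy is conserved exactly (the top edge is inclusive).
    """
    if bin_width_m <= 0:
        raise ValueError("bin_width_m must be > 0")
    if tile.n_returns == 0:
        raise EmptyTileError("no returns in tile")
    h = tile.height_m
    lo = min(0.0, float(h.min()))
    hi = float(h.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width_m - 1e-12)))
    edges = lo + bin_width_m * np.arange(n_bins + 1)
    amp, _ = np.histogram(h, bins=edges, weights=tile.intensity)
    return Pseudowaveform(bin_edges=edges, amplitude=amp)


def _home(wf: Pseudowaveform, amp: np.ndarray) -> float:
    """Height where cumulative energy reaches half the total.

    The cumulative profile is anchored at mid-bin (cumulative fraction at a
    bin center = energy below the center assuming uniform in-bin density)
    and linearly interpolated, so a symmetric profile yields its midpoint.
    """
    e = float(amp.sum())
    if e <= 0:
        return 0.0
    nz = amp > 0
    centers = wf.centers[nz]
    cummid = (np.cumsum(amp[nz]) - amp[nz] / 2.0) / e
    if centers.size == 1:
        return float(centers[0])
    return float(np.interp(0.5, cummid, centers))


def waveform_metrics(
    wf: Pseudowaveform, canopy_threshold_m: float = 2.0, eps: float = 1e-6
) -> dict[str, float]:
    """The 6 pseudowaveform metrics.

    HOME is the height of the median energy; the height/median ratio divides
    the maximum canopy height by HOME.  Mean and quadratic-mean canopy
    heights are energy-weighted over canopy bins (bin center above the
    threshold).  The canopy height profile (CHP) applies the MacArthur-Horn
    occlusion correction top-down, ``ln(P_in / P_out)`` per bin, and its
    coefficient of variation summarizes vertical heterogeneity.  AUCW is the
    integral of the canopy part of the waveform.

    ``n_pulses`` normalization of AUCW is the caller's concern; see
    :func:`all_metrics`, which divides by the pulse count of the tile.
    """
    if wf.total_energy <= 0:
        raise ValueError("zero-energy waveform")
    amp = wf.amplitude
    centers = wf.centers
    canopy = centers > canopy_threshold_m
    camp = amp[canopy]
    ccent = centers[canopy]
    ce = float(camp.sum())
    out: dict[str, float] = {}
    out["HOME"] = _home(wf, amp if ce <= 0 else amp)
    if ce > 0:
        max_ch = float(ccent[camp > 0].max()) if np.any(camp > 0) else 0.0
        out["height_median_ratio"] = max_ch / out["HOME"] if out["HOME"] > 0 else 0.0
        out["mean_canopy_height"] = float((camp * ccent).sum() / ce)
        out["QMCH"] = float(np.sqrt((camp * ccent**2).sum() / ce))
        # MacArthur-Horn transform, top of canopy downward
        total = wf.total_energy
        above = np.concatenate(([0.0], np.cumsum(camp[::-1])))[:-1][::-1]
        p_in = total - above
        p_out = p_in - camp
        chp = np.log(np.maximum(p_in, eps * total) / np.maximum(p_out, eps * total))
        chp = chp / wf.bin_width
        pos = chp[chp > 0]
        if pos.size > 1 and pos.mean() > 0:
            out["CHP_cv"] = float(pos.std(ddof=1) / pos.mean())
        else:
            out["CHP_cv"] = 0.0
        out["AUCW"] = float((camp * wf.bin_width).sum())
    else:
        out.update(height_median_ratio=0.0, mean_canopy_height=0.0,
                   QMCH=0.0, CHP_cv=0.0, AUCW=0.0)
    return out


def all_metrics(
    tile: PointCloudTile,
    canopy_threshold_m: float = 2.0,
    bin_width_m: float = 0.5,
) -> dict[str, float]:
    """All 41 metrics of one tile, in :data:`METRIC_NAMES` order.

    AUCW here is normalized by the pulse count of the cell so that it is
    comparable across cells with different point densities.
    """
    out = height_metrics(tile, canopy_threshold_m)
    out.update(intensity_metrics(tile, canopy_threshold_m))
    if float(tile.intensity.sum()) > 0:
        wf = build_pseudowaveform(tile, bin_width_m)
        wfm = waveform_metrics(wf, canopy_threshold_m)
    else:
        wfm = dict(HOME=0.0, height_median_ratio=0.0, mean_canopy_height=0.0,
                   QMCH=0.0, CHP_cv=0.0, AUCW=0.0)
    n_pulses = max(tile.n_pulses, 1)
    wfm["AUCW"] = wfm["AUCW"] / n_pulses
    out.update(wfm)
    return {k: out[k] for k in METRIC_NAMES}


def rasterize_metrics(
    tiles,
    grid_shape: tuple[int, int],
    canopy_threshold_m: float = 2.0,
    bin_width_m: float = 0.5,
) -> dict[str, np.ndarray]:
    """Metric rasters (one band per metric) from an iterable of tiles.

    Every tile must carry a ``cell_id = (row, col)`` inside ``grid_shape``;
    cells never visited, or visited with an empty tile, are NaN (nodata).
    Tile order is irrelevant.
    """
    rows, cols = grid_shape
    stack = {name: np.full((rows, cols), np.nan) for name in METRIC_NAMES}
    for tile in tiles:
        if tile.cell_id is None:
            raise ValueError("tile without cell_id cannot be rasterized")
        r, c = tile.cell_id
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"tile cell_id {tile.cell_id} outside grid {grid_shape}")
        if tile.n_returns == 0:
            continue
        m = all_metrics(tile, canopy_threshold_m, bin_width_m)
        for name, val in m.items():
            stack[name][r, c] = val
    return stack
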