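"""Synthetic pre/post-fire landscapes with known ground truth.

Generates complete virtual fire scenes on a 30 m grid so that every stage of
the biomass-consumption pipeline can be exercised and validated against a
known truth: a digital elevation model, vegetation-type and burn-severity
maps, per-cell tree lists and true aboveground biomass (AGB) before and
after the fire, per-cell point clouds at ~20 pts/m2, six-band reflectance
stacks for a pre-fire and a post-fire date, and a set of circular 0.09 ha
field plots in the unburned buffer around the fire perimeter.

The generator emulates the observational setting of a large Sierra Nevada
megafire: a burn perimeter in which 7.9% of the area remained unburned and
30.9 / 25.4 / 35.8% burned at low / moderate / high severity, surrounded by
an unburned buffer strip where calibration plots are located.  Fire effects
on the point cloud follow the field phenomenology: canopy returns are
removed in proportion to the biomass consumed, and in high-severity cells
the surviving returns are concentrated near the tops of standing dead trees
(snags), so that height percentiles stay high while the canopy energy
collapses — the situation the H50 correction exists to fix.

Stand structure: per-cell tree lists are drawn against a target AGB with a
diameter distribution whose scale grows with stand biomass, heights from a
saturating height-diameter curve, and a single power-form allometry
``agb_kg = alpha * DBH**beta * H**delta`` per species group.  Canopy cover
rises essentially linearly with AGB (saturating only above ~430 Mg/ha),
which keeps the canopy energy metrics informative across the whole biomass
range of the landscape (open oak savanna through dense mixed conifer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .lidar import PointCloudTile

__all__ = [
    "SceneConfig",
    "TreeRecord",
    "FieldPlot",
    "Scene",
    "InfeasibleTargetError",
    "EmptyCalibrationError",
    "generate_trees",
    "simulate_point_cloud",
    "simulate_reflectance",
    "filter_plots",
    "generate_scene",
]

SEVERITY_CODES = {"unburned": 0, "low": 1, "moderate": 2, "high": 3}
SEVERITY_NAMES = {v: k for k, v in SEVERITY_CODES.items()}
VEG_CODES = {"conifer": 1, "deciduous": 2, "mixed": 3}

# height-diameter curve H = 1.3 + a*(1 - exp(-b*DBH))**c per species group
HEIGHT_CURVE = {
    "conifer": (52.0, 0.012, 1.3),
    "deciduous": (42.0, 0.013, 1.3),
}
# allometry agb_kg = alpha * DBH**beta * H**delta
ALLOMETRY = {
    "conifer": (0.036, 2.0, 1.0),
    "deciduous": (0.045, 2.0, 1.0),
}

# endmember spectra for bands B2..B7 (blue, green, red, NIR, SWIR1, SWIR2)
SPEC_VEG = np.array([0.03, 0.06, 0.04, 0.42, 0.18, 0.09])
SPEC_SOIL = np.array([0.08, 0.10, 0.13, 0.20, 0.28, 0.24])
SPEC_CHAR = np.array([0.04, 0.05, 0.06, 0.07, 0.22, 0.26])
# per-band linear elevation response (reflectance units over the full range)
SPEC_ELEV = np.array([-0.002, -0.002, -0.003, 0.009, -0.006, -0.005])
# char fraction of the exposed background per severity code (post-fire)
CHAR_FRACTION = {0: 0.0, 1: 0.35, 2: 0.65, 3: 0.90}
# exponent of the height bias of surviving canopy returns per severity code;
# 0 = unbiased thinning, large = survivors concentrated at the snag tops
SNAG_EXPONENT = {0: 0.0, 1: 0.0, 2: 1.0, 3: 6.0}


class InfeasibleTargetError(ValueError):
    """Target plot biomass cannot be reached within the tree-count cap."""


class EmptyCalibrationError(ValueError):
    """Plot filtering removed every calibration plot."""


@dataclass
class SceneConfig:
    """Scene-level knobs.  Defaults encode the study conditions.

    ``grid_rows``/``grid_cols`` count 30 m cells including the unburned
    buffer strip of width ``buffer_width`` cells around the fire perimeter.
    ``severity_fractions`` are proportions of the perimeter interior;
    ``consumption_fractions`` are the true per-severity fractions of AGB
    removed by the fire.
    """

    grid_rows: int = 60
    grid_cols: int = 60
    buffer_width: int = 12
    cell_size_m: float = 30.0
    point_density: float = 20.0
    severity_fractions: dict[str, float] = field(default_factory=lambda: {
        "unburned": 0.079, "low": 0.309, "moderate": 0.254, "high": 0.358,
    })
    veg_fractions: dict[str, float] = field(default_factory=lambda: {
        "conifer": 0.60, "deciduous": 0.10, "mixed": 0.30,
    })
    consumption_fractions: dict[str, float] = field(default_factory=lambda: {
        "unburned": 0.0, "low": 0.30, "moderate": 0.50, "high": 0.85,
    })
    elevation_range_m: tuple[float, float] = (60.0, 2400.0)
    # landscape AGB distribution (lognormal body, open-meadow low tail)
    agb_mean: float = 195.8
    agb_sd: float = 143.1
    agb_max: float = 645.4
    open_fraction: float = 0.08
    # canopy cover response: cover = cover_slope * AGB, capped at cover_max
    cover_slope: float = 0.0022
    cover_max: float = 0.95
    cover_noise: float = 0.08
    # sensor model
    reflectance_noise: float = 0.010
    intensity_noise: float = 0.20
    # cell-to-cell variability of canopy reflectance at the laser wavelength
    # (species and moisture effects): makes canopy-energy metrics a noisy
    # biomass proxy, as in real forests, so height percentiles carry most of
    # the biomass signal
    canopy_reflectance_noise: float = 0.15
    canopy_intensity_mean: float = 60.0
    ground_intensity_mean: float = 28.0
    flight_altitude_m: float = 3000.0
    n_plots: int = 71
    n_bad_gps_plots: int = 2
    n_sparse_plots: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in (("severity_fractions", self.severity_fractions),
                           ("veg_fractions", self.veg_fractions)):
            total = sum(frac.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
        cf = self.consumption_fractions
        order = [cf.get("unburned", 0.0), cf["low"], cf["moderate"], cf["high"]]
        if any(not (0.0 <= f <= 1.0) for f in order):
            raise ValueError("consumption_fractions must lie in [0, 1]")
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValueError("consumption_fractions must be non-decreasing "
                             "from unburned to high severity")
        if min(self.grid_rows, self.grid_cols) <= 2 * self.buffer_width:
            raise ValueError("grid too small for the requested buffer width")

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size_m ** 2

    @property
    def cell_area_ha(self) -> float:
        return self.cell_area_m2 / 1e4


@dataclass
class TreeRecord:
    """One tallied tree (DBH >= 10 cm)."""

    dbh_cm: float
    height_m: float
    species_group: str
    agb_kg: float

    def __post_init__(self) -> None:
        if self.dbh_cm < 10.0 - 1e-9:
            raise ValueError("tally threshold is DBH >= 10 cm")
        if self.agb_kg <= 0:
            raise ValueError("agb_kg must be positive")


@dataclass
class FieldPlot:
    """A circular 0.09 ha calibration plot co-located with one grid cell."""

    plot_id: int
    cell: tuple[int, int]
    trees: list[TreeRecord]
    plot_agb_Mg_ha: float
    fractional_cover: float
    gps_error_m: float

    PLOT_AREA_HA = 0.09


def tree_height(dbh_cm: float | np.ndarray, species_group: str) -> np.ndarray:
    a, b, c = HEIGHT_CURVE[species_group]
    return 1.3 + a * (1.0 - np.exp(-b * np.asarray(dbh_cm, dtype=float))) ** c


def tree_agb_kg(dbh_cm, height_m, species_group: str) -> np.ndarray:
    alpha, beta, delta = ALLOMETRY[species_group]
    return alpha * np.asarray(dbh_cm, dtype=float) ** beta \
        * np.asarray(height_m, dtype=float) ** delta


def _species_for(veg_code: int, n: int, rng: np.random.Generator) -> np.ndarray:
    if veg_code == VEG_CODES["conifer"]:
        return np.zeros(n, dtype=int)
    if veg_code == VEG_CODES["deciduous"]:
        return np.ones(n, dtype=int)
    return (rng.random(n) < 0.5).astype(int)  # mixed: 50/50 per tree


def _solve_dbh_for_agb(target_kg: float, species: str) -> float:
    """Invert the allometry (with the height curve substituted) by bisection."""
    lo, hi = 10.0, 160.0
    f = lambda d: float(tree_agb_kg(d, tree_height(d, species), species))
    if target_kg <= f(lo):
        return lo
    if target_kg >= f(hi):
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f(mid) < target_kg:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_trees(
    target_agb: float,
    veg_code: int,
    rng: np.random.Generator,
    plot_area_ha: float = 0.09,
    tolerance: float = 0.05,
    max_trees: int = 5000,
    height_noise: float = 0.06,
) -> list[TreeRecord]:
    """Draw a tree list whose summed AGB is within ``tolerance`` of target.

    Diameters follow a shifted gamma whose scale grows with the target
    biomass (small stands are made of small stems); heights come from the
    species height-diameter curve with lognormal scatter; trees are
    accumulated until the plot mass is reached, and the final stem is
    re-sized through the allometry so that the realized total lands inside
    the tolerance band whenever geometrically possible.
    """
    if target_agb <= 0:
        raise ValueError("target_agb must be > 0; treeless cells are handled upstream")
    target_kg = target_agb * plot_area_ha * 1000.0
    # stand maturity: diameter scale rises steeply with stand biomass, so
    # low-biomass stands are short/young rather than thinned-out tall forest
    mean_dbh = 10.0 + 135.0 * (min(target_agb, 645.0) / 645.0) ** 1.54
    shape = 6.0
    scale = max((mean_dbh - 10.0) / shape, 0.25)

    species_names = ("conifer", "deciduous")
    dbh_acc: list[float] = []
    h_acc: list[float] = []
    agb_acc: list[float] = []
    sp_acc: list[int] = []
    total = 0.0
    while total < target_kg:
        if len(dbh_acc) >= max_trees:
            raise InfeasibleTargetError(
                f"target {target_agb} Mg/ha not reachable within {max_trees} stems")
        n = 64
        d = np.minimum(10.0 + rng.gamma(shape, scale, size=n), 145.0)
        sp = _species_for(veg_code, n, rng)
        h = np.empty(n)
        for code, name in enumerate(species_names):
            m = sp == code
            if m.any():
                h[m] = tree_height(d[m], name) * np.exp(
                    rng.normal(0.0, height_noise, size=int(m.sum())))
        agb = np.where(sp == 0,
                       tree_agb_kg(d, h, "conifer"),
                       tree_agb_kg(d, h, "deciduous"))
        cum = total + np.cumsum(agb)
        stop = int(np.searchsorted(cum, target_kg)) + 1
        stop = min(stop, n)
        dbh_acc.extend(d[:stop]); h_acc.extend(h[:stop])
        agb_acc.extend(agb[:stop]); sp_acc.extend(sp[:stop])
        total = float(cum[stop - 1])

    # close the gap by re-sizing the last stem through the allometry
    rest = total - agb_acc[-1]
    want_last = target_kg - rest
    name = species_names[sp_acc[-1]]
    min_tree = float(tree_agb_kg(10.0, tree_height(10.0, name), name))
    if want_last >= min_tree:
        d_new = _solve_dbh_for_agb(want_last, name)
        h_new = float(tree_height(d_new, name))
        dbh_acc[-1], h_acc[-1] = d_new, h_new
        agb_acc[-1] = float(tree_agb_kg(d_new, h_new, name))
    elif len(dbh_acc) > 1:
        # gap smaller than the smallest tally tree: drop the last stem and
        # accept the (sub-minimal-tree) shortfall instead of a full overshoot
        for acc in (dbh_acc, h_acc, agb_acc, sp_acc):
            acc.pop()
    # else: a single minimum-size tree overshoots tiny targets; accept it

    return [TreeRecord(d, h, species_names[s], a)
            for d, h, s, a in zip(dbh_acc, h_acc, sp_acc, agb_acc)]


def plot_agb(trees: list[TreeRecord], plot_area_ha: float = 0.09) -> float:
    """Plot-level AGB density in Mg/ha (sum of stems / 1000 / area)."""
    return sum(t.agb_kg for t in trees) / 1000.0 / plot_area_ha


def _weighted_subset(weights: np.ndarray, k: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Indices of a weighted sample without replacement (exponential-key trick)."""
    if k <= 0:
        return np.empty(0, dtype=int)
    if k >= weights.size:
        return np.arange(weights.size)
    w = np.maximum(weights, 1e-12)
    keys = rng.exponential(size=w.size) / w
    return np.argpartition(keys, k)[:k]


def simulate_point_cloud(
    trees: list[TreeRecord],
    config: SceneConfig,
    severity: str = "unburned",
    date: str = "pre",
    rng: np.random.Generator | None = None,
    elevation_m: float = 1000.0,
    cell_id: tuple[int, int] | None = None,
    cover: float | None = None,
) -> PointCloudTile:
    """Simulate the discrete-return cloud of one 30 m cell.

    Pre-fire (or unburned) cells split ``Poisson(density * area)`` returns
    into canopy and ground hits according to the cell canopy cover; canopy
    return heights are uniform within ``[0.5 H, H]`` of the tree they hit
    (crown envelope), trees weighted by their biomass share.  Post-fire
    cells in burned severity classes convert a fraction of canopy returns —
    equal to the consumed biomass fraction — into ground returns; the
    survivors are chosen with a height bias that grows with severity, and in
    high severity the topmost return always survives (standing snags), so
    the maximum height is preserved while the canopy return count collapses.

    Raw intensities carry the inverse-square range dependence of the sensor
    (flight altitude minus terrain minus return height) and are meant to be
    undone by :func:`firecarb.lidar.normalize_intensity`.
    """
    if rng is None:
        rng = np.random.default_rng()
    if severity not in SEVERITY_CODES:
        raise ValueError(f"unknown severity {severity!r}")
    area = config.cell_area_m2
    n_total = int(rng.poisson(config.point_density * area))
    if config.point_density <= 0 or n_total == 0:
        return PointCloudTile(np.empty(0), np.empty(0), np.empty(0),
                              cell_id=cell_id, cell_area_m2=area,
                              empty_flag=True)
    if trees:
        agb = np.array([t.agb_kg for t in trees])
        if cover is None:
            cover = config.cover_slope * (agb.sum() / 1000.0 / config.cell_area_ha)
            cover *= math.exp(rng.normal(0.0, config.cover_noise))
        cover = float(np.clip(cover, 0.0, config.cover_max))
    else:
        cover = 0.0
    n_canopy = int(round(cover * n_total))
    n_ground = n_total - n_canopy

    if n_canopy:
        heights = np.array([t.height_m for t in trees])
        p = agb / agb.sum()
        idx = rng.choice(len(trees), size=n_canopy, p=p)
        th = heights[idx]
        ch = th * rng.uniform(0.5, 1.0, size=n_canopy)
        cell_gain = math.exp(rng.normal(0.0, config.canopy_reflectance_noise))
        ci = rng.normal(config.canopy_intensity_mean * cell_gain,
                        config.canopy_intensity_mean * config.intensity_noise,
                        size=n_canopy)
    else:
        ch = np.empty(0)
        ci = np.empty(0)

    sev_code = SEVERITY_CODES[severity]
    burned = date == "post" and sev_code > 0
    char = CHAR_FRACTION[sev_code] if burned else 0.0
    if burned and n_canopy:
        cf = config.consumption_fractions[severity]
        n_keep = int(round((1.0 - cf) * n_canopy))
        rel = np.clip((ch - 2.0) / max(ch.max() - 2.0, 1e-9), 1e-6, None)
        w = rel ** SNAG_EXPONENT[sev_code]
        keep = _weighted_subset(w, n_keep, rng)
        if SNAG_EXPONENT[sev_code] > 0 and n_keep > 0:
            top = int(np.argmax(ch))
            if top not in keep:
                keep = np.concatenate((keep[:-1], [top]))
        n_ground += n_canopy - keep.size
        ch, ci = ch[keep], ci[keep]
        n_canopy = keep.size

    gh = np.abs(rng.normal(0.0, 0.05, size=n_ground))
    g_mean = config.ground_intensity_mean * (1.0 - 0.5 * char)
    gi = rng.normal(g_mean, g_mean * config.intensity_noise, size=n_ground)

    h = np.concatenate((ch, gh))
    i_true = np.clip(np.concatenate((ci, gi)), 1.0, None)
    rng_m = config.flight_altitude_m - elevation_m - h
    ref = config.flight_altitude_m - 0.5 * sum(config.elevation_range_m)
    i_raw = i_true * (ref / rng_m) ** 2
    order = rng.permutation(h.size)
    return PointCloudTile(
        height_m=h[order],
        intensity=i_raw[order],
        range_m=rng_m[order],
        return_number=np.ones(h.size, dtype=int),
        cell_id=cell_id,
        cell_area_m2=area,
    )


def filter_plots(
    plots: list[FieldPlot],
    max_gps_error_m: float = 2.0,
    min_fc: float = 0.10,
) -> list[FieldPlot]:
    """Drop plots with GPS error above threshold or fractional cover below it.

    Boundaries follow the field protocol: error strictly greater than the
    limit is rejected; cover exactly at the minimum is retained.
    """
    kept = [p for p in plots
            if p.gps_error_m <= max_gps_error_m and p.fractional_cover >= min_fc]
    if plots and not kept:
        raise EmptyCalibrationError("all plots removed by filtering")
    return kept


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

def _smooth_field(shape, rng: np.random.Generator, sigma: float = 6.0) -> np.ndarray:
    """Standardized Gaussian random field (unit variance, mean 0)."""
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma, mode="reflect")
    return (f - f.mean()) / max(f.std(), 1e-12)


def _classify_by_quantiles(field2d: np.ndarray, mask: np.ndarray,
                           fractions: list[float]) -> np.ndarray:
    """Assign classes 0..k-1 inside ``mask`` with exact class counts."""
    out = np.zeros(field2d.shape, dtype=int)
    vals = field2d[mask]
    order = np.argsort(vals, kind="stable")
    n = vals.size
    counts = [int(round(f * n)) for f in fractions]
    counts[-1] = n - sum(counts[:-1])
    labels = np.empty(n, dtype=int)
    start = 0
    for k, c in enumerate(counts):
        labels[order[start:start + c]] = k
        start += c
    out[mask] = labels
    return out


def _cell_rng(seed: int, stage: int, r: int = 0, c: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage, r, c]))


_STAGE_FIELDS, _STAGE_TREES, _STAGE_CLOUD_PRE, _STAGE_CLOUD_POST, \
    _STAGE_REFL_PRE, _STAGE_REFL_POST, _STAGE_PLOTS = range(7)


@dataclass
class Scene:
    """A generated landscape with ground truth and sensor simulations.

    Point clouds are not stored (at 20 pts/m2 a full scene holds tens of
    millions of returns); :meth:`point_cloud` regenerates any tile
    bit-identically from the scene seed.
    """

    config: SceneConfig
    dem: np.ndarray
    vegtype: np.ndarray
    severity: np.ndarray
    perimeter: np.ndarray          # bool: True inside the fire perimeter
    agb_true_pre: np.ndarray
    agb_true_post: np.ndarray
    cover_true: np.ndarray         # realized pre-fire canopy cover per cell
    reflectance_pre: np.ndarray    # (6, rows, cols) in [0, 1]
    reflectance_post: np.ndarray
    plots: list[FieldPlot]

    @property
    def shape(self) -> tuple[int, int]:
        return self.dem.shape

    @property
    def reference_range_m(self) -> float:
        cfg = self.config
        return cfg.flight_altitude_m - 0.5 * sum(cfg.elevation_range_m)

    def cell_trees(self, r: int, c: int) -> list[TreeRecord]:
        """Deterministically regenerate the tree list of a cell."""
        target = float(self.agb_true_pre[r, c])
        if target <= 1.0:
            return []
        rng = _cell_rng(self.config.seed, _STAGE_TREES, r, c)
        return generate_trees(target, int(self.vegtype[r, c]), rng)

    def point_cloud(self, r: int, c: int, date: str = "post") -> PointCloudTile:
        if date not in ("pre", "post"):
            raise ValueError("date must be 'pre' or 'post'")
        stage = _STAGE_CLOUD_PRE if date == "pre" else _STAGE_CLOUD_POST
        rng = _cell_rng(self.config.seed, stage, r, c)
        sev = SEVERITY_NAMES[int(self.severity[r, c])]
        # unburned cells: same structural draw on both dates (identical up to
        # sensor noise); burned cells get an independent post-fire realization
        if date == "post" and sev == "unburned":
            rng = _cell_rng(self.config.seed, _STAGE_CLOUD_PRE, r, c)
        return simulate_point_cloud(
            self.cell_trees(r, c), self.config, severity=sev, date=date,
            rng=rng, elevation_m=float(self.dem[r, c]), cell_id=(r, c),
            cover=float(self.cover_true[r, c]),
        )

    def iter_tiles(self, date: str = "post"):
        rows, cols = self.shape
        for r in range(rows):
            for c in range(cols):
                yield self.point_cloud(r, c, date)

    def true_consumed_Mg_ha(self) -> np.ndarray:
        return self.agb_true_pre - self.agb_true_post


def simulate_reflectance(
    agb: np.ndarray,
    dem: np.ndarray,
    severity: np.ndarray,
    config: SceneConfig,
    date: str,
    rng: np.random.Generator,
    cover: np.ndarray | None = None,
) -> np.ndarray:
    """Six-band reflectance stack from the biomass/terrain truth.

    A linear-mixture response: each cell mixes a green-vegetation spectrum
    (weight = canopy cover, which rises with AGB) with an exposed-background
    spectrum; post-fire, the background of burned cells is partly char, in a
    proportion that grows with severity.  A per-band linear elevation term
    and Gaussian sensor noise are added, and values are clipped to [0, 1].
    NIR therefore increases and SWIR decreases with AGB, and burned cells
    show the NIR drop / SWIR rise characteristic of fire scars.

    Pass ``cover`` to use the realized canopy-cover field of the scene (the
    same canopy the LiDAR sees); otherwise cover is derived from ``agb``
    with fresh lognormal noise.
    """
    lo, hi = config.elevation_range_m
    elev_norm = (dem - lo) / max(hi - lo, 1e-9) - 0.5
    if cover is None:
        v = np.clip(
            config.cover_slope * agb * np.exp(
                rng.normal(0.0, config.cover_noise, size=agb.shape)),
            0.0, config.cover_max)
    else:
        v = np.clip(np.asarray(cover, dtype=float), 0.0, config.cover_max)
    char = np.zeros_like(agb)
    if date == "post":
        for code, frac in CHAR_FRACTION.items():
            char[severity == code] = frac
    bands = np.empty((6,) + agb.shape)
    for b in range(6):
        background = (1.0 - char) * SPEC_SOIL[b] + char * SPEC_CHAR[b]
        bands[b] = (v * SPEC_VEG[b] + (1.0 - v) * background
                    + SPEC_ELEV[b] * elev_norm
                    + rng.normal(0.0, config.reflectance_noise, size=agb.shape))
    return np.clip(bands, 0.0, 1.0)


def _draw_agb_field(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Pre-fire AGB targets: lognormal forest body plus open-meadow patches."""
    shape = (config.grid_rows, config.grid_cols)
    sigma2 = math.log(1.0 + (config.agb_sd / config.agb_mean) ** 2)
    sigma = math.sqrt(sigma2)
    mu = math.log(config.agb_mean) - 0.5 * sigma2
    lo, hi = config.elevation_range_m

    z_struct = _smooth_field(shape, rng, sigma=5.0)
    z_local = _smooth_field(shape, rng, sigma=1.5)
    return z_struct, z_local, mu, sigma


def generate_scene(config: SceneConfig | None = None) -> Scene:
    """Build a full scene deterministically from ``config.seed``."""
    if config is None:
        config = SceneConfig()
    shape = (config.grid_rows, config.grid_cols)
    rng = _cell_rng(config.seed, _STAGE_FIELDS)

    # terrain
    lo, hi = config.elevation_range_m
    dem_field = _smooth_field(shape, rng, sigma=5.0)
    dem = lo + (hi - lo) * (dem_field - dem_field.min()) / max(
        dem_field.max() - dem_field.min(), 1e-12)

    # vegetation type blobs over the whole grid
    veg_field = _smooth_field(shape, rng, sigma=5.0)
    veg_names = list(config.veg_fractions)
    veg_cls = _classify_by_quantiles(
        veg_field, np.ones(shape, dtype=bool),
        [config.veg_fractions[k] for k in veg_names])
    vegtype = np.zeros(shape, dtype=int)
    for k, name in enumerate(veg_names):
        vegtype[veg_cls == k] = VEG_CODES[name]

    # severity blobs inside the perimeter; buffer stays unburned
    b = config.buffer_width
    perimeter = np.zeros(shape, dtype=bool)
    perimeter[b:config.grid_rows - b, b:config.grid_cols - b] = True
    sev_field = _smooth_field(shape, rng, sigma=4.0)
    sev_names = ["unburned", "low", "moderate", "high"]
    sev_cls = _classify_by_quantiles(
        sev_field, perimeter, [config.severity_fractions[k] for k in sev_names])
    severity = np.zeros(shape, dtype=int)
    severity[perimeter] = sev_cls[perimeter]

    # pre-fire AGB targets: elevation-correlated lognormal + meadow patches
    z_struct, z_local, mu, sigma = _draw_agb_field(config, rng)
    elev_z = (dem - dem.mean()) / max(dem.std(), 1e-12)
    z = 0.20 * elev_z + 0.55 * z_struct + 0.35 * z_local
    z = z / max(z.std(), 1e-12)
    agb_target = np.exp(mu + sigma * z)
    meadow_field = _smooth_field(shape, rng, sigma=3.0)
    meadow = meadow_field > np.quantile(meadow_field, 1.0 - config.open_fraction)
    agb_target[meadow] = rng.uniform(3.0, 40.0, size=int(meadow.sum()))
    agb_target = np.clip(agb_target, 0.0, config.agb_max)

    # realize tree lists cell by cell; truth is the realized stand mass
    agb_pre = np.zeros(shape)
    for r in range(shape[0]):
        for c in range(shape[1]):
            target = float(agb_target[r, c])
            if target <= 1.0:
                continue
            t_rng = _cell_rng(config.seed, _STAGE_TREES, r, c)
            trees = generate_trees(target, int(vegtype[r, c]), t_rng)
            agb_pre[r, c] = plot_agb(trees)

    cf = np.zeros(shape)
    for name, code in SEVERITY_CODES.items():
        cf[severity == code] = config.consumption_fractions.get(name, 0.0)
    agb_post = agb_pre * (1.0 - cf)

    # realized canopy cover (shared by the point clouds of both dates)
    cover_rng = _cell_rng(config.seed, _STAGE_FIELDS, 1, 1)
    cover = np.clip(
        config.cover_slope * agb_pre * np.exp(
            cover_rng.normal(0.0, config.cover_noise, size=shape)),
        0.0, config.cover_max)

    # both sensors observe the same realized canopy: reflectance mixes with
    # the cover field the point clouds use, scaled by the surviving biomass
    # fraction after the fire
    with np.errstate(invalid="ignore", divide="ignore"):
        survival = np.where(agb_pre > 0, agb_post / np.maximum(agb_pre, 1e-9), 0.0)
    refl_pre = simulate_reflectance(
        agb_pre, dem, severity, config, "pre",
        _cell_rng(config.seed, _STAGE_REFL_PRE), cover=cover)
    refl_post = simulate_reflectance(
        agb_post, dem, severity, config, "post",
        _cell_rng(config.seed, _STAGE_REFL_POST), cover=cover * survival)

    scene = Scene(config=config, dem=dem, vegtype=vegtype, severity=severity,
                  perimeter=perimeter, agb_true_pre=agb_pre,
                  agb_true_post=agb_post, cover_true=cover,
                  reflectance_pre=refl_pre, reflectance_post=refl_post,
                  plots=[])
    scene.plots = _place_plots(scene)
    return scene


def _place_plots(scene: Scene) -> list[FieldPlot]:
    """Stratified field campaign in the unburned buffer.

    Plots sample the buffer across the biomass range; a configured number of
    plots fall on sparse (low canopy cover) cells and a configured number
    carry a GPS error above the 2 m acceptance threshold, reproducing the
    attrition of the real campaign.
    """
    cfg = scene.config
    rng = _cell_rng(cfg.seed, _STAGE_PLOTS)
    buffer_cells = np.argwhere(~scene.perimeter)
    agb = scene.agb_true_pre[tuple(buffer_cells.T)]

    def realized_fc(cell) -> float:
        tile = scene.point_cloud(int(cell[0]), int(cell[1]), "post")
        return float(np.mean(tile.height_m > 2.0)) if tile.n_returns else 0.0

    sparse_pool = buffer_cells[agb <= 20.0]
    dense_pool = buffer_cells[agb > 24.0]
    dense_agb = scene.agb_true_pre[tuple(dense_pool.T)]
    n_dense = cfg.n_plots - cfg.n_sparse_plots
    if (sparse_pool.shape[0] < cfg.n_sparse_plots
            or dense_pool.shape[0] < n_dense):  # pragma: no cover
        raise ValueError("buffer too small for the configured plot design")
    # stratify plots uniformly over the biomass RANGE (not its frequency
    # distribution): for evenly spaced target values pick the closest
    # unused buffer cell, so sparse tails of the landscape distribution are
    # still anchored by calibration data
    targets = np.linspace(dense_agb.min(), dense_agb.max(), n_dense)
    order_all = np.argsort(dense_agb)
    sorted_agb = dense_agb[order_all]
    used = np.zeros(order_all.size, dtype=bool)
    picks_l = []
    for tgt in targets:
        j = int(np.searchsorted(sorted_agb, tgt))
        cand = [k for k in (j - 1, j, j + 1) if 0 <= k < order_all.size]
        cand = sorted(cand, key=lambda k: abs(sorted_agb[k] - tgt))
        k = next((k for k in cand if not used[k]), None)
        if k is None:
            k = int(np.argmin(np.where(used, np.inf, np.abs(sorted_agb - tgt))))
        used[k] = True
        picks_l.append(order_all[k])
    picks = np.array(picks_l)
    order = order_all
    fallback = [i for i in order[::-1] if i not in set(picks.tolist())]
    cells: list[tuple[int, int]] = []
    fcs: list[float] = []
    for i in picks:
        cell = tuple(dense_pool[i])
        fc = realized_fc(cell)
        while fc < 0.105 and fallback:  # keep measured cover clear of the cut
            cell = tuple(dense_pool[fallback.pop(0)])
            fc = realized_fc(cell)
        cells.append(cell)
        fcs.append(fc)
    sparse_left = list(rng.permutation(sparse_pool.shape[0]))
    while len(cells) < cfg.n_plots:
        if not sparse_left:  # pragma: no cover
            raise ValueError("no sparse buffer cell below the cover threshold")
        cell = tuple(sparse_pool[sparse_left.pop(0)])
        fc = realized_fc(cell)
        if fc < 0.095:
            cells.append(cell)
            fcs.append(fc)

    plots: list[FieldPlot] = []
    bad_gps = set(rng.choice(n_dense, size=cfg.n_bad_gps_plots,
                             replace=False).tolist())
    for pid, ((r, c), fc) in enumerate(zip(cells, fcs)):
        trees = scene.cell_trees(r, c)
        if pid in bad_gps:
            err = float(rng.uniform(2.2, 4.0))
        else:
            err = float(min(abs(rng.normal(0.0, 0.5)), 1.8))
        plots.append(FieldPlot(
            plot_id=pid, cell=(int(r), int(c)), trees=trees,
            plot_agb_Mg_ha=plot_agb(trees) if trees else 0.0,
            fractional_cover=fc, gps_error_m=err))
    return plots
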