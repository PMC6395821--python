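"""Synthetic alpine-valley landscape generator.

Builds a covariate stack with the structure a montane resource-selection
analysis expects: a glacial-valley DEM, terrain derivatives (slope,
cosine aspect, ruggedness), NDVI declining with elevation and generated at
a coarser satellite-like grid, a four-class land cover, hiking trails with
a log-distance raster, steep scree/rock "safe areas" with a distance
raster, and hydro-geographic sectors.

Aspect convention (used package-wide): compass degrees clockwise from
north of the steepest-*descent* direction, so ``cos_aspect`` is +1 on
north-facing slopes and -1 on south-facing slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import LANDCOVER_CODES, NODATA, CovariateStack, GridGeoref


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic valley.

    Defaults mirror a steep ~1700-ha glacial valley spanning
    1700-3300 m a.s.l. on a 10-m grid, with the valley floor in the west
    and ridges to the east and north-east.
    """

    nrows: int = 410
    ncols: int = 415
    cell_size: float = 10.0
    elev_min: float = 1700.0
    elev_max: float = 3300.0
    # trail polylines in grid (row, col) vertices; default follows the valley floor
    trails: list = field(default_factory=list)
    scree_fraction: float = 0.35
    ndvi_at_floor: float = 0.75
    ndvi_elev_slope: float = -4.0e-4  # NDVI units per metre of elevation
    ndvi_coarse_factor: int = 25  # coarse NDVI pixel = 25 DEM cells (250 m at 10 m)
    dem_noise: float = 120.0  # m, SD of the smooth relief component
    dem_noise_sigma: float = 6.0  # cells, smoothing length of the relief
    ndvi_noise: float = 0.06
    safe_slope_threshold: float = 45.0  # degrees; 30.0 is the tested alternative
    n_sectors: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.nrows < 3 or self.ncols < 3:
            raise ValueError("grid must be at least 3x3: terrain derivatives undefined")
        if self.nrows * self.ncols <= 0:
            raise ValueError("grid must be non-empty")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if not self.elev_min < self.elev_max:
            raise ValueError("elevation range must satisfy min < max")
        for name in ("dem_noise", "ndvi_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def default_trails(self) -> list:
        """One trail along the valley floor plus a switchback spur."""
        r, c = self.nrows, self.ncols
        main = [(0.05 * r, 0.06 * c), (0.5 * r, 0.1 * c), (0.95 * r, 0.06 * c)]
        spur = [(0.5 * r, 0.1 * c), (0.55 * r, 0.45 * c), (0.45 * r, 0.7 * c)]
        return [main, spur]


def terrain_derivatives(dem: np.ndarray, cell_size: float):
    """Slope (degrees), cosine aspect and Riley ruggedness from a DEM.

    Gradients use centred finite differences (one-sided on the border).
    Flat cells get ``cos_aspect`` 0 (aspect undefined).  Ruggedness is the
    square root of the summed squared elevation differences to the eight
    neighbours, in metres.
    """
    dem = np.asarray(dem, float)
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3 for finite differences")
    # row axis points south: northward derivative is the negated row gradient
    dz_drow, dz_dcol = np.gradient(dem, cell_size)
    dz_dx = dz_dcol  # eastward
    dz_dy = -dz_drow  # northward
    grad = np.hypot(dz_dx, dz_dy)
    slope = np.degrees(np.arctan(grad))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_aspect = np.where(grad > 0, -dz_dy / grad, 0.0)
    # Riley terrain ruggedness index
    sq = np.zeros_like(dem)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.roll(np.roll(dem, dr, axis=0), dc, axis=1)
            sq += (dem - shifted) ** 2
    # border rolls wrap; recompute border conservatively by edge-padding
    padded = np.pad(dem, 1, mode="edge")
    sq_edge = np.zeros_like(dem)
    for dr in (0, 1, 2):
        for dc in (0, 1, 2):
            if dr == 1 and dc == 1:
                continue
            sq_edge += (dem - padded[dr : dr + dem.shape[0], dc : dc + dem.shape[1]]) ** 2
    sq[0, :], sq[-1, :], sq[:, 0], sq[:, -1] = (
        sq_edge[0, :],
        sq_edge[-1, :],
        sq_edge[:, 0],
        sq_edge[:, -1],
    )
    ruggedness = np.sqrt(sq)
    return slope, cos_aspect, ruggedness


def _smooth_field(rng, shape, sigma, sd):
    """Gaussian-smoothed white noise rescaled to the requested SD."""
    if sd == 0:
        return np.zeros(shape)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    s = f.std()
    return f * (sd / s) if s > 0 else f


def _rasterize_polylines(polylines, nrows, ncols):
    mask = np.zeros((nrows, ncols), dtype=bool)
    for line in polylines:
        pts = np.asarray(line, float)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            n = int(max(abs(r1 - r0), abs(c1 - c0)) * 2) + 2
            rr = np.linspace(r0, r1, n)
            cc = np.linspace(c0, c1, n)
            rr = np.clip(np.round(rr).astype(int), 0, nrows - 1)
            cc = np.clip(np.round(cc).astype(int), 0, ncols - 1)
            mask[rr, cc] = True
    return mask


def _block_average_resample(fine: np.ndarray, factor: int) -> np.ndarray:
    """Block-average to a coarse grid, then repeat back to the fine grid.

    Emulates a satellite product whose native pixel is ``factor`` DEM cells
    wide (e.g. 250 m NDVI on a 10 m DEM).
    """
    nr, nc = fine.shape
    nrc = -(-nr // factor)
    ncc = -(-nc // factor)
    padded = np.pad(fine, ((0, nrc * factor - nr), (0, ncc * factor - nc)), mode="edge")
    coarse = padded.reshape(nrc, factor, ncc, factor).mean(axis=(1, 3))
    back = np.repeat(np.repeat(coarse, factor, axis=0), factor, axis=1)
    return back[:nr, :nc]


def generate_landscape(config: LandscapeConfig) -> CovariateStack:
    """Generate the covariate stack for one synthetic valley.

    Deterministic given ``config.seed``.  The DEM is a west-floor/east-ridge
    trend plus smooth relief, rescaled exactly to the configured elevation
    range; derivatives come from :func:`terrain_derivatives`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nr, nc = config.nrows, config.ncols
    georef = GridGeoref(x0=0.0, y0=0.0, cell_size=config.cell_size, nrows=nr, ncols=nc)

    rows = np.arange(nr)[:, None] / max(nr - 1, 1)
    cols = np.arange(nc)[None, :] / max(nc - 1, 1)
    trend = 0.75 * cols**1.3 + 0.25 * (1.0 - rows) ** 1.5  # floor in SW, ridge in NE
    relief = _smooth_field(rng, (nr, nc), config.dem_noise_sigma, 1.0)
    dem = trend * (config.elev_max - config.elev_min) + relief * config.dem_noise
    lo, hi = dem.min(), dem.max()
    dem = config.elev_min + (dem - lo) * (config.elev_max - config.elev_min) / (hi - lo)

    slope, cos_aspect, ruggedness = terrain_derivatives(dem, config.cell_size)

    # NDVI: linear decline with elevation plus smooth noise, generated at the
    # coarse satellite grid and resampled back to the DEM grid
    ndvi_fine = (
        config.ndvi_at_floor
        + config.ndvi_elev_slope * (dem - config.elev_min)
        + _smooth_field(rng, (nr, nc), 3 * config.dem_noise_sigma, config.ndvi_noise)
    )
    ndvi = _block_average_resample(ndvi_fine, config.ndvi_coarse_factor)
    ndvi = np.clip(ndvi, -0.1, 0.95)

    # land cover: scree/rock on the high fraction, wood low, meadow between
    elev_q = np.quantile(dem, 1.0 - config.scree_fraction)
    tree_line = np.quantile(dem, 0.22)
    cover_noise = _smooth_field(rng, (nr, nc), 8.0, 1.0)
    landcover = np.full((nr, nc), LANDCOVER_CODES["meadow"], dtype=float)
    landcover[(dem < tree_line) & (cover_noise > -0.8)] = LANDCOVER_CODES["wood"]
    landcover[(dem >= elev_q) | ((slope > 50) & (cover_noise > 0.5))] = LANDCOVER_CODES[
        "scree_rock"
    ]
    landcover[(dem < tree_line) & (cover_noise < -1.6)] = LANDCOVER_CODES["other"]

    safe_mask = (landcover == LANDCOVER_CODES["scree_rock"]) & (
        slope > config.safe_slope_threshold
    )

    trails = config.trails or config.default_trails()
    trail_mask = _rasterize_polylines(trails, nr, nc)
    dist_trail = ndimage.distance_transform_edt(~trail_mask) * config.cell_size
    log_dist_trail = np.log(dist_trail + 1.0)

    if safe_mask.any():
        dist_safe = ndimage.distance_transform_edt(~safe_mask) * config.cell_size
    else:
        dist_safe = np.full((nr, nc), np.hypot(nr, nc) * config.cell_size)

    # hydro-geographic sectors: longitudinal bands across the valley
    sector = np.floor(cols * config.n_sectors).clip(0, config.n_sectors - 1)
    sector = np.broadcast_to(sector, (nr, nc)).copy()

    return CovariateStack(
        layers={
            "dem": dem,
            "slope": slope,
            "cos_aspect": cos_aspect,
            "ruggedness": ruggedness,
            "ndvi": ndvi,
            "log_dist_trail": log_dist_trail,
            "dist_safe": dist_safe,
            "landcover": landcover,
            "safe_mask": safe_mask.astype(float),
            "sector": sector,
        },
        georef=georef,
        nodata=NODATA,
    )
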