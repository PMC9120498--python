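"""Pixel filtering and normalization ahead of spectral-diversity metrics.

The processing chain drops unusable bands (sensor edges and atmospheric
water-absorption windows), screens pixels with a greenness (NDVI) mask and
a near-infrared shade mask, keeps a plot only if at least half of its
pixels pass both screens, and finally brightness-normalizes each retained
spectrum to unit Euclidean norm so that downstream variance measures
respond to spectral shape rather than illumination.

Masks are computed on the original (pre-band-drop) reflectance; the NDVI
and shade windows lie outside the dropped ranges so the order does not
change their values. Thresholds are applied inclusively (>=).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

from .io import SpectralCube

__all__ = [
    "MaskConfig",
    "PlotPixelMatrix",
    "drop_bad_bands",
    "compute_ndvi",
    "compute_nir_shade_index",
    "extract_plot_pixels",
    "brightness_normalize",
    "preprocess_site",
]

#: default shade-mask thresholds by dominant vegetation type
SHADE_THRESHOLDS = {"forest": 0.18, "shrubland": 0.20, "grassland": 0.22}


@dataclass
class MaskConfig:
    """Band-exclusion windows and pixel-screening thresholds.

    Wavelengths are nm. Water windows and the sensor-edge cuts are treated
    as closed intervals (a band at exactly 400 or 1340 nm is removed). The
    NDVI threshold is site-specific (sparse sites use lower greenness
    cut-offs than closed forests); the shade threshold depends on the
    dominant vegetation type.
    """

    water_windows: tuple[tuple[float, float], ...] = ((1340.0, 1445.0), (1790.0, 1955.0))
    lower_cut: float = 400.0
    upper_cut: float = 2400.0
    ndvi_threshold: float = 0.5
    shade_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(SHADE_THRESHOLDS)
    )
    min_valid_fraction: float = 0.5
    red_window: tuple[float, float] = (650.0, 680.0)
    nir_window: tuple[float, float] = (780.0, 800.0)
    shade_window: tuple[float, float] = (752.0, 1048.0)

    def __post_init__(self) -> None:
        if not -1.0 <= self.ndvi_threshold <= 1.0:
            raise ValueError("ndvi_threshold must lie in [-1, 1]")
        for k, v in self.shade_thresholds.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"shade threshold for {k} must lie in [0, 1]")
        if not 0.0 <= self.min_valid_fraction <= 1.0:
            raise ValueError("min_valid_fraction must lie in [0, 1]")


@dataclass
class PlotPixelMatrix:
    """Retained pixels of one plot: rows are pixels, columns retained bands."""

    plot_id: str
    pixels: np.ndarray  # (n_pixels, n_bands)
    wavelengths: np.ndarray
    coords: np.ndarray  # (n_pixels, 2) raster (row, col)
    normalized: bool = False

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]


def band_keep_mask(wavelengths: np.ndarray, config: MaskConfig) -> np.ndarray:
    """Boolean mask of bands surviving the edge cuts and water windows."""
    w = np.asarray(wavelengths, dtype=float)
    keep = (w > config.lower_cut) & (w < config.upper_cut)
    for lo, hi in config.water_windows:
        keep &= ~((w >= lo) & (w <= hi))
    return keep


def drop_bad_bands(cube: SpectralCube, config: MaskConfig) -> SpectralCube:
    """Remove sensor-edge bands (<=400, >=2400 nm) and water-absorption
    windows from the cube."""
    keep = band_keep_mask(cube.wavelengths, config)
    if not keep.any():
        raise ValueError("band exclusion removed every band")
    return cube.select_bands(keep)


def _window_mean(cube: SpectralCube, window: tuple[float, float], name: str) -> np.ndarray:
    lo, hi = window
    sel = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
    if not sel.any():
        raise ValueError(f"no band inside the {name} window [{lo}, {hi}] nm")
    return cube.data[:, :, sel].mean(axis=2)


def compute_ndvi(
    cube: SpectralCube,
    red_window: tuple[float, float] = (650.0, 680.0),
    nir_window: tuple[float, float] = (780.0, 800.0),
) -> np.ndarray:
    """NDVI = (NIR - red) / (NIR + red) on band-window means; 0/0 -> NaN."""
    red = _window_mean(cube, red_window, "red")
    nir = _window_mean(cube, nir_window, "NIR")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / denom, np.nan)
    return ndvi


def compute_nir_shade_index(
    cube: SpectralCube, window: tuple[float, float] = (752.0, 1048.0)
) -> np.ndarray:
    """Mean reflectance over the 752–1048 nm window; low values flag shade."""
    return _window_mean(cube, window, "shade")


def extract_plot_pixels(
    cube: SpectralCube,
    plot_id: str,
    polygon: Polygon,
    config: MaskConfig,
    vegetation_type: str = "forest",
    masked_cube: SpectralCube | None = None,
) -> PlotPixelMatrix | None:
    """Extract one plot's pixels, apply the NDVI and shade screens, and
    enforce the minimum-valid-fraction rule.

    A pixel belongs to the plot if its center lies inside the polygon
    (half-open cells, so a shared edge assigns each pixel exactly once).
    NDVI and shade indices are evaluated on ``cube`` (full-band reflectance);
    spectra are taken from ``masked_cube`` (the band-dropped cube) when
    given, else from ``cube``. Returns None when fewer than
    ``min_valid_fraction`` of the plot's pixels pass — a reported rejection,
    not an error.
    """
    px, py = cube.pixel_centers()
    inside = shapely.contains_xy(polygon, px.ravel(), py.ravel()).reshape(px.shape)
    if not inside.any():
        raise ValueError(f"plot {plot_id!r} polygon lies outside the raster")

    ndvi = compute_ndvi(cube, config.red_window, config.nir_window)
    shade = compute_nir_shade_index(cube, config.shade_window)
    try:
        shade_thr = config.shade_thresholds[vegetation_type]
    except KeyError:
        raise ValueError(f"unknown vegetation type {vegetation_type!r}") from None

    good = inside & (ndvi >= config.ndvi_threshold) & (shade >= shade_thr)
    n_total = int(inside.sum())
    n_good = int(good.sum())
    if n_good / n_total < config.min_valid_fraction:
        return None

    rows, cols = np.nonzero(good)
    src = masked_cube if masked_cube is not None else cube
    return PlotPixelMatrix(
        plot_id=plot_id,
        pixels=src.data[rows, cols, :].copy(),
        wavelengths=src.wavelengths.copy(),
        coords=np.column_stack([rows, cols]),
        normalized=False,
    )


def brightness_normalize(matrix: PlotPixelMatrix) -> PlotPixelMatrix:
    """Scale every pixel spectrum to unit Euclidean norm.

    Removes overall brightness so that a spectrum and the same spectrum
    dimmed by shade become identical. Zero-norm rows cannot be normalized
    and are dropped with a warning. Idempotent.
    """
    norms = np.linalg.norm(matrix.pixels, axis=1)
    ok = norms > 0
    if not ok.all():
        warnings.warn(
            f"plot {matrix.plot_id}: dropped {int((~ok).sum())} zero-norm spectra",
            stacklevel=2,
        )
    return PlotPixelMatrix(
        plot_id=matrix.plot_id,
        pixels=matrix.pixels[ok] / norms[ok, None],
        wavelengths=matrix.wavelengths,
        coords=matrix.coords[ok],
        normalized=True,
    )


def preprocess_site(
    cube: SpectralCube,
    config: MaskConfig | None = None,
    vegetation_type: str = "forest",
) -> tuple[dict[str, PlotPixelMatrix], list[str]]:
    """Run the full chain for every plot polygon on a cube.

    Returns the brightness-normalized pixel matrices of retained plots and
    the ids of plots rejected by the minimum-valid-fraction rule.
    """
    config = config or MaskConfig()
    masked = drop_bad_bands(cube, config)
    kept: dict[str, PlotPixelMatrix] = {}
    rejected: list[str] = []
    for pid, poly in cube.plot_polygons.items():
        m = extract_plot_pixels(
            cube, pid, poly, config, vegetation_type, masked_cube=masked
        )
        if m is None:
            rejected.append(pid)
        else:
            kept[pid] = brightness_normalize(m)
    return kept, rejected
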