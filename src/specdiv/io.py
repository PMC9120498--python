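"""Raster container and on-disk interchange formats.

A :class:`SpectralCube` is a band-indexed reflectance raster with its
wavelength grid and georeferencing (axis-aligned, north-up, square pixels).
Cubes are stored as multi-band TIFF with the wavelength grid and geotransform
in a JSON ``ImageDescription`` tag; plot polygons travel in a GeoJSON
sidecar. Tables (tree inventories, percent cover, LAI) are plain CSV and
phylogenies are Newick.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, box, mapping, shape

from .scene import Scene

__all__ = [
    "SpectralCube",
    "scene_to_cube",
    "write_cube",
    "read_cube",
    "write_plot_polygons",
    "read_plot_polygons",
    "write_tree_table",
    "read_tree_table",
    "write_cover_matrix",
    "read_cover_matrix",
    "write_lai",
    "read_lai",
    "write_phylogeny",
    "read_phylogeny",
]


@dataclass
class SpectralCube:
    """Reflectance raster: ``data[row, col, band]`` with world coordinates
    ``x = origin_x + (col + 0.5) * pixel_size`` (pixel centers), y likewise
    increasing with row index (plot-local convention, not map north-up).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    pixel_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    plot_polygons: dict[str, Polygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be (rows, cols, bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError("band count does not match wavelength grid")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World x/y coordinates of every pixel center (2-D arrays)."""
        ny, nx = self.data.shape[:2]
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def select_bands(self, keep: np.ndarray) -> "SpectralCube":
        keep = np.asarray(keep)
        return SpectralCube(
            data=self.data[:, :, keep],
            wavelengths=self.wavelengths[keep],
            pixel_size=self.pixel_size,
            origin=self.origin,
            plot_polygons=dict(self.plot_polygons),
        )


def scene_to_cube(scene: Scene) -> SpectralCube:
    """Mosaic a rendered scene's plots into one raster with plot polygons.

    Plots are laid out row-major on a near-square grid, separated by a
    1-plot-wide apron of bare soil so polygons never touch.
    """
    from .scene import soil_spectrum

    n_plots, npx, _, nb = scene.cube.shape
    ncol = int(np.ceil(np.sqrt(n_plots)))
    nrow = int(np.ceil(n_plots / ncol))
    gap = max(2, npx // 10)
    side = npx + gap
    H, W = nrow * side + gap, ncol * side + gap
    soil = soil_spectrum(scene.wavelengths)
    data = np.broadcast_to(soil, (H, W, nb)).copy()

    polys: dict[str, Polygon] = {}
    ps = scene.config.pixel_size
    for p in range(n_plots):
        r, c = divmod(p, ncol)
        r0, c0 = gap + r * side, gap + c * side
        data[r0 : r0 + npx, c0 : c0 + npx, :] = scene.cube[p]
        polys[scene.plot_ids[p]] = box(
            c0 * ps, r0 * ps, (c0 + npx) * ps, (r0 + npx) * ps
        )
    return SpectralCube(
        data=data,
        wavelengths=scene.wavelengths,
        pixel_size=ps,
        origin=(0.0, 0.0),
        plot_polygons=polys,
    )


# ---------------------------------------------------------------------------
# raster + vector I/O


def write_cube(cube: SpectralCube, path: str | Path) -> None:
    """Write as band-sequential TIFF; grid and georeferencing go into the
    ImageDescription tag as JSON."""
    meta = {
        "wavelengths_nm": cube.wavelengths.tolist(),
        "pixel_size_m": cube.pixel_size,
        "origin": list(cube.origin),
    }
    tifffile.imwrite(
        str(path),
        np.moveaxis(cube.data, 2, 0).astype(np.float32),
        description=json.dumps(meta),
    )


def read_cube(path: str | Path, polygons: str | Path | None = None) -> SpectralCube:
    with tifffile.TiffFile(str(path)) as tif:
        meta = json.loads(tif.pages[0].description)
        data = tif.asarray()
    cube = SpectralCube(
        data=np.moveaxis(data, 0, 2).astype(np.float64),
        wavelengths=np.asarray(meta["wavelengths_nm"], dtype=float),
        pixel_size=float(meta["pixel_size_m"]),
        origin=tuple(meta["origin"]),
    )
    if polygons is not None:
        cube.plot_polygons = read_plot_polygons(polygons)
    return cube


def write_plot_polygons(polys: dict[str, Polygon], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"plot_id": pid},
            "geometry": mapping(poly),
        }
        for pid, poly in polys.items()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_plot_polygons(path: str | Path) -> dict[str, Polygon]:
    fc = json.loads(Path(path).read_text())
    return {
        f["properties"]["plot_id"]: shape(f["geometry"]) for f in fc["features"]
    }


# ---------------------------------------------------------------------------
# tables


def write_tree_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["plot_id", "species", "x_m", "y_m", "crown_diameter_m", "height_m"]
    table[cols].to_csv(path, index=False)


def read_tree_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cover_matrix(cover: pd.DataFrame, path: str | Path) -> None:
    """Cover matrix: rows = plots (index name plot_id), columns = species."""
    cover.rename_axis("plot_id").to_csv(path)


def read_cover_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="plot_id")


def write_lai(lai: pd.Series, path: str | Path) -> None:
    lai.rename("lai").rename_axis("plot_id").to_csv(path)


def read_lai(path: str | Path) -> pd.Series:
    return pd.read_csv(path, index_col="plot_id")["lai"]


def write_phylogeny(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_phylogeny(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
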