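"""Synthetic hyperspectral scenes with known ground truth.

This module emulates the four inputs of an airborne-imaging vegetation
diversity study: a surface-reflectance cube on a fine wavelength grid,
per-plot percent-cover inventories, stem-mapped tree tables, and per-plot
leaf area index (LAI) — all generated from a simulated phylogeny and
species endmember library, with compositional turnover along a 1-D
environmental gradient whose strength is controlled. Because the gradient
strength, community draws, crown placement and pixel labels are all known,
every downstream stage (masking, PCA, diversity metrics, two-table
statistics) can be verified against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "SpeciesLibrary",
    "SceneConfig",
    "SceneTruth",
    "Scene",
    "default_wavelengths",
    "soil_spectrum",
    "simulate_phylogeny",
    "simulate_endmembers",
    "simulate_communities",
    "render_scene",
    "simulate_study",
]


def default_wavelengths() -> np.ndarray:
    """The working band grid: 426 bands, 380–2510 nm at 5 nm spacing."""
    return np.arange(380.0, 2510.0 + 2.5, 5.0)[:426]


# ---------------------------------------------------------------------------
# phylogeny


def simulate_phylogeny(n_species: int, seed: int) -> dendropy.Tree:
    """Simulate a rooted ultrametric tree by coalescent-style pairwise joining.

    Lineages are merged two at a time; waiting times between merges are
    exponential with rate proportional to the number of active lineage
    pairs, so the process mimics a Kingman coalescent. Total depth is
    rescaled to 1, which makes the phylogenetic covariance matrix have a
    unit diagonal.

    Parameters
    ----------
    n_species : int
        Number of tips (>= 2). Tips are labeled ``sp01 .. spNN``.
    seed : int
        Seed for the local random generator; same seed gives an identical
        Newick string.
    """
    if n_species < 2:
        raise ValueError(f"n_species must be >= 2, got {n_species}")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace(
        [f"sp{i + 1:02d}" for i in range(n_species)]
    )
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes = []
    for tax in taxa:
        node = dendropy.Node(taxon=tax)
        node.age = 0.0
        nodes.append(node)

    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.age = t
        a, b = nodes[i], nodes[j]
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = t - a.age
        b.edge.length = t - b.age
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)

    root = nodes[0]
    depth = root.age
    tree.seed_node = root
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= depth
        node.age /= depth
    tree.seed_node.edge.length = None
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# endmember library


@dataclass
class SpeciesLibrary:
    """Per-species endmember spectra and structural attributes.

    Attributes
    ----------
    species : list of str
        Species ids, matching the phylogeny tips one-to-one.
    wavelengths : ndarray, nm
    spectra : ndarray, (n_species, n_bands), unitless reflectance in [0, 1]
    growth_form : list of {"tree", "herb"}
    crown_diameter_range : ndarray, (n_species, 2), m — for trees
    height_range : ndarray, (n_species, 2), m
    """

    species: list[str]
    wavelengths: np.ndarray
    spectra: np.ndarray
    growth_form: list[str]
    crown_diameter_range: np.ndarray
    height_range: np.ndarray

    def __post_init__(self) -> None:
        if self.spectra.shape != (len(self.species), len(self.wavelengths)):
            raise ValueError("spectra shape inconsistent with species/wavelengths")
        if self.spectra.min() < 0 or self.spectra.max() > 1:
            raise ValueError("reflectance must lie in [0, 1]")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        return self.species.index(name)


def soil_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Bundled bare-soil endmember: smooth, monotonically brightening into
    the SWIR, with low NDVI so greenness masking can reject it."""
    w = np.asarray(wavelengths, dtype=float)
    refl = 0.12 + 0.30 * (w - 400.0) / 2000.0
    return np.clip(refl, 0.0, 1.0)


def _vegetation_template(
    w: np.ndarray,
    green_peak: float,
    red_depth: float,
    nir_plateau: float,
    water_depth: float,
    swir_level: float,
) -> np.ndarray:
    """Smooth vegetation-like reflectance: green-peak bump, chlorophyll red
    trough, logistic red edge to an NIR plateau, water-absorption dips,
    declining SWIR. Parameters are the knobs Brownian motion acts on."""
    vis = 0.04 + green_peak * np.exp(-((w - 550.0) ** 2) / (2 * 40.0**2))
    vis -= red_depth * np.exp(-((w - 670.0) ** 2) / (2 * 30.0**2))
    red_edge = 1.0 / (1.0 + np.exp(-(w - 715.0) / 12.0))
    nir = nir_plateau * red_edge
    swir_decay = 1.0 / (1.0 + np.exp((w - 1350.0) / 250.0))
    dips = (
        water_depth * np.exp(-((w - 1450.0) ** 2) / (2 * 45.0**2))
        + water_depth * 1.3 * np.exp(-((w - 1940.0) ** 2) / (2 * 55.0**2))
        + 0.4 * water_depth * np.exp(-((w - 1200.0) ** 2) / (2 * 35.0**2))
    )
    spectrum = vis * (1.0 - red_edge) + nir * (swir_decay + swir_level * (1 - swir_decay))
    spectrum = spectrum * (1.0 - np.clip(dips, 0.0, 0.95))
    return np.clip(spectrum, 0.0, 1.0)


# template parameter means and Brownian step scales (per unit branch length)
_TRAIT_MEANS = np.array([0.08, 0.02, 0.45, 0.55, 0.45])
_TRAIT_SCALES = np.array([0.03, 0.008, 0.10, 0.15, 0.12])
_TRAIT_LO = np.array([0.01, 0.0, 0.25, 0.10, 0.10])
_TRAIT_HI = np.array([0.20, 0.04, 0.75, 0.90, 0.90])


def simulate_endmembers(
    tree: dendropy.Tree,
    wavelengths: np.ndarray,
    seed: int,
    brownian_scale: float = 1.0,
) -> SpeciesLibrary:
    """Evolve endmember spectra along a phylogeny by Brownian motion.

    Five shape parameters of a smooth vegetation template (green-peak
    height, red-trough depth, NIR plateau, water-dip depth, SWIR level)
    diffuse along the tree, so closely related species have similar
    spectra in expectation. ``brownian_scale = 0`` makes all species
    identical. Parameters are reflected into biophysically sane bounds;
    reflectance is clamped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    w = np.asarray(wavelengths, dtype=float)

    traits: dict[int, np.ndarray] = {id(tree.seed_node): _TRAIT_MEANS.copy()}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = traits[id(node.parent_node)]
        step = rng.normal(
            0.0,
            _TRAIT_SCALES * brownian_scale * np.sqrt(max(node.edge.length, 0.0)),
        )
        val = parent + step
        # reflect into bounds (triangle wave) to keep templates vegetation-like
        span = _TRAIT_HI - _TRAIT_LO
        val = _TRAIT_LO + (span - np.abs(np.mod(val - _TRAIT_LO, 2 * span) - span))
        traits[id(node)] = val

    species = []
    spectra = []
    forms = []
    crown_rng = []
    height_rng = []
    leaves = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)
    for k, leaf in enumerate(leaves):
        p = traits[id(leaf)]
        species.append(leaf.taxon.label)
        spectra.append(_vegetation_template(w, *p))
        # alternate growth forms so every scene has canopy and understory
        if k % 2 == 0:
            forms.append("tree")
            crown_rng.append((2.0, 6.0))
            height_rng.append((5.0, 25.0))
        else:
            forms.append("herb")
            crown_rng.append((0.0, 0.0))
            height_rng.append((0.1, 1.5))

    return SpeciesLibrary(
        species=species,
        wavelengths=w,
        spectra=np.asarray(spectra),
        growth_form=forms,
        crown_diameter_range=np.asarray(crown_rng, dtype=float),
        height_range=np.asarray(height_rng, dtype=float),
    )


# ---------------------------------------------------------------------------
# communities


def simulate_communities(
    n_plots: int,
    library: SpeciesLibrary,
    gradient_strength: float,
    seed: int,
    total_cover: float | tuple[float, float] = (35.0, 95.0),
    noise_sd: float = 0.35,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-plot percent covers along a 1-D environmental gradient.

    Plots sit at evenly spaced gradient positions in [0, 1]. Each species
    has a Gaussian niche (random optimum and width); its expected abundance
    at position g is ``exp(-strength * (g - opt)^2 / (2 w^2))`` times a
    random base abundance, perturbed by lognormal noise. Abundances are
    rescaled so each plot's total cover equals ``total_cover`` percent
    (<= 100) — a scalar, or a (lo, hi) range sampled per plot so that
    canopy density (hence LAI) varies across plots. With
    ``gradient_strength = 0`` the niche factor is identically 1 and plots
    are exchangeable.

    Returns
    -------
    cover : ndarray (n_plots, n_species), percent
    positions : ndarray (n_plots,), gradient positions in [0, 1]
    """
    if n_plots < 2:
        raise ValueError("n_plots must be >= 2")
    if library.n_species < 1:
        raise ValueError("species library is empty")
    if gradient_strength < 0:
        raise ValueError("gradient_strength must be >= 0")
    rng = np.random.default_rng(seed)
    s = library.n_species

    positions = np.linspace(0.0, 1.0, n_plots)
    optima = rng.uniform(0.0, 1.0, size=s)
    widths = rng.uniform(0.15, 0.4, size=s)
    base = rng.lognormal(0.0, 0.5, size=s)

    niche = np.exp(
        -gradient_strength
        * (positions[:, None] - optima[None, :]) ** 2
        / (2.0 * widths[None, :] ** 2)
    )
    abundance = base[None, :] * niche * rng.lognormal(0.0, noise_sd, size=(n_plots, s))
    row_sums = abundance.sum(axis=1, keepdims=True)
    if np.isscalar(total_cover):
        totals = np.full(n_plots, float(total_cover))
    else:
        lo, hi = total_cover
        totals = rng.uniform(lo, hi, size=n_plots)
    if totals.max() > 100.0:
        raise ValueError("total_cover must not exceed 100 percent")
    cover = totals[:, None] * abundance / row_sums
    return cover, positions


# ---------------------------------------------------------------------------
# scene rendering


@dataclass
class SceneConfig:
    """Geometry, spectral grid and noise settings for rendered scenes.

    Defaults follow the study design this generator emulates: 20 m x 20 m
    plots at 1 m pixels on a 426-band 380–2510 nm grid.
    """

    n_plots: int = 12
    plot_side: float = 20.0
    pixel_size: float = 1.0
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    gradient_strength: float = 12.0
    noise_sd: float = 0.005
    shade_fraction: float = 0.08
    bare_soil_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.plot_side / self.pixel_size
        if abs(n - round(n)) > 1e-9:
            raise ValueError("plot_side must be divisible by pixel_size")
        for name in ("shade_fraction", "bare_soil_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.gradient_strength < 0:
            raise ValueError("gradient_strength must be >= 0")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")

    @property
    def pixels_per_side(self) -> int:
        return int(round(self.plot_side / self.pixel_size))


@dataclass
class SceneTruth:
    """Ground truth for a rendered scene.

    ``pixel_species`` holds, per plot, the index of the species rendered at
    each pixel (-1 for bare soil). ``shade`` and ``soil`` are boolean masks
    of the same shape. ``cover`` is the intended combined (top-of-canopy)
    percent cover per plot; ``lai`` the per-plot leaf area index.
    """

    cover: np.ndarray
    positions: np.ndarray
    lai: np.ndarray
    pixel_species: np.ndarray
    shade: np.ndarray
    soil: np.ndarray


@dataclass
class Scene:
    """A rendered multi-plot scene plus its tabular side-products."""

    cube: np.ndarray  # (n_plots, ny, nx, n_bands)
    wavelengths: np.ndarray
    plot_ids: list[str]
    tree_table: "pd.DataFrame"  # noqa: F821 - imported lazily below
    understory: np.ndarray  # (n_plots, n_species) percent cover
    lai: np.ndarray
    truth: SceneTruth
    config: SceneConfig
    library: SpeciesLibrary


SHADE_FACTOR = 0.1  # multiplicative reflectance factor for shaded pixels


def render_scene(
    communities: np.ndarray,
    library: SpeciesLibrary,
    config: SceneConfig,
    seed: int,
    positions: np.ndarray | None = None,
) -> Scene:
    """Render plot reflectance cubes from community cover vectors.

    Tree-species cover is realized as circular crowns (stems uniform in the
    plot, crowns clipped to the plot for cover accounting); each pixel is
    assigned the tallest crown covering its center, otherwise an understory
    species or bare soil drawn from the plot's remaining cover. The pixel
    spectrum is that class's endmember, times ``SHADE_FACTOR`` for pixels
    flagged shaded, plus additive Gaussian noise truncated to [0, 1].
    Per-plot LAI increases linearly with total cover.
    """
    import pandas as pd

    communities = np.asarray(communities, dtype=float)
    n_plots, n_species = communities.shape
    if n_species != library.n_species:
        raise ValueError("communities inconsistent with library")
    rng = np.random.default_rng(seed)
    npx = config.pixels_per_side
    w = config.wavelengths
    if not np.array_equal(w, library.wavelengths):
        raise ValueError("config wavelengths differ from library grid")
    nb = len(w)
    soil = soil_spectrum(w)
    if positions is None:
        positions = np.linspace(0.0, 1.0, n_plots)

    is_tree = np.array([f == "tree" for f in library.growth_form])
    cube = np.empty((n_plots, npx, npx, nb), dtype=np.float64)
    pixel_species = np.full((n_plots, npx, npx), -1, dtype=np.int32)
    shade_mask = np.zeros((n_plots, npx, npx), dtype=bool)
    soil_mask = np.zeros((n_plots, npx, npx), dtype=bool)
    understory = np.zeros_like(communities)
    lai = np.empty(n_plots)
    tree_rows = []

    # pixel-center coordinates in plot-local metres
    centers = (np.arange(npx) + 0.5) * config.pixel_size
    cx, cy = np.meshgrid(centers, centers)  # cy = row -> y, cx = col -> x
    plot_area = config.plot_side**2

    for p in range(n_plots):
        cover = communities[p]
        # --- place crowns for tree species until intended cover is reached
        height_grid = np.full((npx, npx), -np.inf)
        owner = np.full((npx, npx), -1, dtype=np.int32)
        for s in np.flatnonzero(is_tree & (cover > 0)):
            target_area = cover[s] / 100.0 * plot_area
            placed = 0.0
            attempts = 0
            dlo, dhi = library.crown_diameter_range[s]
            hlo, hhi = library.height_range[s]
            while placed < target_area and attempts < 200:
                attempts += 1
                d = rng.uniform(max(dlo, 0.5), max(dhi, 0.6))
                h = rng.uniform(hlo, hhi)
                x = rng.uniform(0.0, config.plot_side)
                y = rng.uniform(0.0, config.plot_side)
                tree_rows.append(
                    dict(
                        plot_id=f"plot{p + 1:03d}",
                        species=library.species[s],
                        x_m=x,
                        y_m=y,
                        crown_diameter_m=d,
                        height_m=h,
                    )
                )
                inside = (cx - x) ** 2 + (cy - y) ** 2 <= (d / 2.0) ** 2
                taller = inside & (h > height_grid)
                owner[taller] = s
                height_grid[taller] = h
                # expected within-plot crown area (clip ignored; bounded loop)
                placed += np.pi * (d / 2.0) ** 2

        crowned = owner >= 0

        # --- understory / soil assignment on open pixels
        herb_cover = np.where(is_tree, 0.0, cover)
        understory[p] = herb_cover
        open_idx = np.flatnonzero(~crowned.ravel())
        labels = owner.ravel().copy()
        if open_idx.size:
            # soil probability on open pixels chosen so the soil share of ALL
            # pixels matches the configured bare-soil fraction in expectation
            open_frac = open_idx.size / crowned.size
            p_soil = min(config.bare_soil_fraction / open_frac, 1.0)
            herb_total = herb_cover.sum()
            probs = np.zeros(n_species + 1)
            if herb_total > 0:
                probs[:n_species] = (1.0 - p_soil) * herb_cover / herb_total
                probs[n_species] = p_soil
            else:
                probs[n_species] = 1.0
            probs /= probs.sum()
            draw = rng.choice(n_species + 1, size=open_idx.size, p=probs)
            labels[open_idx] = np.where(draw == n_species, -1, draw)
        labels = labels.reshape(npx, npx)

        # --- shading
        shade = rng.random((npx, npx)) < config.shade_fraction

        # --- spectra
        palette = np.vstack([library.spectra, soil[None, :]])
        refl = palette[np.where(labels < 0, n_species, labels)]
        refl = refl * np.where(shade[..., None], SHADE_FACTOR, 1.0)
        if config.noise_sd > 0:
            refl = refl + rng.normal(0.0, config.noise_sd, size=refl.shape)
        cube[p] = np.clip(refl, 0.0, 1.0)

        pixel_species[p] = labels
        shade_mask[p] = shade
        soil_mask[p] = labels < 0

        total_frac = min(cover.sum() / 100.0, 1.0)
        lai[p] = np.clip(
            0.13 + 3.67 * total_frac * (1.0 - config.bare_soil_fraction)
            + rng.normal(0.0, 0.05),
            0.13,
            3.80,
        )

    truth = SceneTruth(
        cover=communities.copy(),
        positions=np.asarray(positions, dtype=float),
        lai=lai.copy(),
        pixel_species=pixel_species,
        shade=shade_mask,
        soil=soil_mask,
    )
    tree_table = pd.DataFrame(
        tree_rows,
        columns=["plot_id", "species", "x_m", "y_m", "crown_diameter_m", "height_m"],
    )
    return Scene(
        cube=cube,
        wavelengths=w,
        plot_ids=[f"plot{p + 1:03d}" for p in range(n_plots)],
        tree_table=tree_table,
        understory=understory,
        lai=lai,
        truth=truth,
        config=config,
        library=library,
    )


def simulate_study(
    config: SceneConfig,
    n_species: int = 12,
    seed: int = 0,
    decouple_inventory: bool = False,
) -> tuple[Scene, np.ndarray, dendropy.Tree]:
    """Simulate a full single-site study: phylogeny, endmembers, communities
    and rendered scene.

    Returns ``(scene, inventory_cover, tree)`` where ``inventory_cover`` is
    the percent-cover table the plant-diversity side consumes. With
    ``decouple_inventory=True`` the inventory is drawn independently of the
    communities that were rendered, severing any spectral–taxonomic link —
    the null configuration used for statistical calibration.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)
    tree = simulate_phylogeny(n_species, seed=int(sub[0]))
    library = simulate_endmembers(tree, config.wavelengths, seed=int(sub[1]))
    cover, positions = simulate_communities(
        config.n_plots, library, config.gradient_strength, seed=int(sub[2])
    )
    scene = render_scene(cover, library, config, seed=int(sub[3]), positions=positions)
    if decouple_inventory:
        alt, _ = simulate_communities(
            config.n_plots,
            library,
            config.gradient_strength,
            seed=int(sub[2]) + 10_007,
        )
        inventory = alt
    else:
        inventory = cover
    return scene, inventory, tree
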