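"""Plant diversity from stem maps and percent-cover inventories.

Field inventories report understory cover directly but only stem positions,
crown diameters and heights for trees, so top-of-canopy ("as seen from
above") cover is reconstructed geometrically: crowns are flat discs, taller
crowns occlude shorter ones, and the plot is rasterized on a fine sub-grid
to measure each species' visible fraction. Understory cover is then scaled
to the area left open by crowns and the two layers are combined.

Diversity metrics on the combined cover:

* richness — number of species with positive cover;
* Shannon index H = -sum p_i ln p_i (nats);
* phylogenetic species evenness (PSE) — abundance-weighted phylogenetic
  variability computed from the covariance matrix C of a depth-1
  ultrametric tree: with abundances m and M = sum m_i,
  PSE = (M * sum_i m_i C_ii - m'Cm) / (M^2 - sum_i m_i^2),
  which equals PSV under equal abundances and 1 on a star phylogeny;
* beta-diversity — Euclidean distances among Hellinger-transformed rows
  (square roots of relative covers), bounded by sqrt(2).
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "visible_crown_cover",
    "combine_cover",
    "combine_site_cover",
    "richness",
    "shannon",
    "phylo_covariance",
    "pse",
    "diversity_table",
    "hellinger_transform",
    "taxonomic_beta_distances",
]


def visible_crown_cover(
    trees: pd.DataFrame,
    plot_side: float,
    resolution: float = 0.1,
) -> tuple[pd.Series, float]:
    """Visible (top-of-canopy) cover fraction per tree species in one plot.

    The plot is rasterized at ``resolution`` metres; every cell belongs to
    the crown disc of the tallest tree covering its center, or to "open".
    Height ties break by record order (later rows win), crowns extending
    past the plot edge are clipped by construction. Returns per-species
    visible fractions (of plot area) and the total crowned fraction.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if resolution > 0.5:
        raise ValueError("resolution must be <= 0.5 m for sub-pixel accuracy")
    n = int(round(plot_side / resolution))
    centers = (np.arange(n) + 0.5) * resolution
    cx, cy = np.meshgrid(centers, centers)

    height = np.full((n, n), -np.inf)
    owner = np.full((n, n), -1, dtype=np.int64)
    species = list(dict.fromkeys(trees["species"])) if len(trees) else []
    sp_index = {s: i for i, s in enumerate(species)}

    for _, row in trees.iterrows():
        r = row["crown_diameter_m"] / 2.0
        h = row["height_m"]
        if r <= 0 or h <= 0:
            raise ValueError("crown diameter and height must be positive")
        inside = (cx - row["x_m"]) ** 2 + (cy - row["y_m"]) ** 2 <= r**2
        win = inside & (h >= height)
        owner[win] = sp_index[row["species"]]
        height[win] = h

    total_cells = n * n
    counts = np.bincount(owner[owner >= 0].ravel(), minlength=len(species))
    fractions = pd.Series(counts / total_cells, index=species, dtype=float)
    return fractions, float((owner >= 0).sum() / total_cells)


def combine_cover(
    tree_visible: pd.Series,
    understory: pd.Series,
    crown_fraction: float,
) -> pd.Series:
    """Combine tree-visible cover with understory cover rescaled to the
    open (non-crowned) plot fraction.

    Both inputs and the result are percent of plot area. A species present
    in both layers accumulates. Understory rows summing above 100% are
    rescaled to 100 with a warning.
    """
    if not 0.0 <= crown_fraction <= 1.0:
        raise ValueError("crown_fraction must lie in [0, 1]")
    understory = understory[understory > 0].astype(float)
    total = understory.sum()
    if total > 100.0 + 1e-9:
        warnings.warn(
            f"understory covers sum to {total:.1f}% > 100%; rescaling to 100%",
            stacklevel=2,
        )
        understory = understory * (100.0 / total)
    tree_pct = 100.0 * tree_visible[tree_visible > 0].astype(float)
    combined = tree_pct.add(understory * (1.0 - crown_fraction), fill_value=0.0)
    return combined.sort_index()


def combine_site_cover(
    tree_table: pd.DataFrame,
    understory: pd.DataFrame,
    plot_side: float,
    resolution: float = 0.1,
) -> pd.DataFrame:
    """Top-of-canopy combined cover for every plot of a site.

    ``understory`` is a plots-by-species percent-cover table; trees absent
    from a plot simply contribute nothing.
    """
    rows = {}
    for pid in understory.index:
        sub = tree_table[tree_table["plot_id"] == pid]
        visible, frac = visible_crown_cover(sub, plot_side, resolution)
        rows[pid] = combine_cover(visible, understory.loc[pid], frac)
    out = pd.DataFrame(rows).T.fillna(0.0)
    out.index.name = "plot_id"
    return out.sort_index(axis=1)


# ---------------------------------------------------------------------------
# alpha-diversity metrics


def richness(cover: np.ndarray | pd.Series) -> int:
    """Number of species with positive cover."""
    return int((np.asarray(cover, dtype=float) > 0).sum())


def shannon(cover: np.ndarray | pd.Series) -> float:
    """Shannon index H (nats) of relative covers; NaN for an empty row."""
    m = np.asarray(cover, dtype=float)
    total = m.sum()
    if total <= 0:
        return float("nan")
    p = m[m > 0] / total
    return float(-(p * np.log(p)).sum())


def phylo_covariance(tree: dendropy.Tree, species: list[str] | None = None) -> pd.DataFrame:
    """Phylogenetic covariance C of an ultrametric tree.

    ``C[i, j]`` is the root-to-MRCA path length shared by tips i and j; the
    diagonal holds total tip depths (1 for a depth-normalized tree). The
    matrix is symmetric positive semidefinite by construction.
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)
    labels = [lf.taxon.label for lf in leaves]
    depths = np.array([lf.root_distance for lf in leaves])
    if np.max(np.abs(depths - depths[0])) > 1e-9 * max(depths[0], 1.0):
        raise ValueError("tree is not ultrametric")

    n = len(labels)
    C = np.zeros((n, n))
    # accumulate shared branch lengths: each internal node contributes its
    # root distance to every tip pair whose MRCA it is
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [lf.taxon for lf in leaves]
    for i in range(n):
        C[i, i] = depths[i]
        for j in range(i + 1, n):
            mrca = pdm.mrca(taxa[i], taxa[j])
            C[i, j] = C[j, i] = mrca.root_distance
    out = pd.DataFrame(C, index=labels, columns=labels)
    if species is not None:
        missing = sorted(set(species) - set(labels))
        if missing:
            raise ValueError(f"species missing from the phylogeny: {missing}")
        out = out.loc[species, species]
    return out


def pse(cover: pd.Series | np.ndarray, C: pd.DataFrame | np.ndarray) -> float:
    """Phylogenetic species evenness of one community.

    Requires the phylogenetic covariance of a depth-1 ultrametric tree
    (unit diagonal). Communities with fewer than two species present have
    undefined evenness and return NaN.
    """
    if isinstance(cover, pd.Series) and isinstance(C, pd.DataFrame):
        sp = [s for s in cover.index if cover[s] > 0]
        m = cover[sp].to_numpy(dtype=float)
        Cm = C.loc[sp, sp].to_numpy(dtype=float)
    else:
        m = np.asarray(cover, dtype=float)
        Cm = np.asarray(C, dtype=float)
        keep = m > 0
        m, Cm = m[keep], Cm[np.ix_(keep, keep)]
    if len(m) < 2:
        return float("nan")
    if np.max(np.abs(np.diag(Cm) - 1.0)) > 1e-8:
        raise ValueError("C must have unit diagonal (depth-normalized tree)")
    M = m.sum()
    num = M * (m * np.diag(Cm)).sum() - m @ Cm @ m
    den = M**2 - (m**2).sum()
    return float(num / den)


def diversity_table(
    cover: pd.DataFrame,
    C: pd.DataFrame | None = None,
    trees: list[dendropy.Tree] | None = None,
) -> pd.DataFrame:
    """Richness, Shannon and PSE for every plot of a cover table.

    PSE needs phylogenetic information: either a precomputed covariance
    ``C`` or a list of phylogenies whose per-tree PSE values are averaged
    (emulating replicate phylogeny construction).
    """
    covs: list[pd.DataFrame] = []
    if C is not None:
        covs.append(C)
    if trees is not None:
        covs.extend(phylo_covariance(t) for t in trees)
    rows = []
    for pid in cover.index:
        row = cover.loc[pid]
        vals = [pse(row, c) for c in covs]
        rows.append(
            dict(
                plot_id=pid,
                richness=richness(row),
                shannon=shannon(row),
                pse=float(np.mean(vals)) if vals else float("nan"),
            )
        )
    return pd.DataFrame(rows).set_index("plot_id")


# ---------------------------------------------------------------------------
# beta-diversity


def hellinger_transform(cover: pd.DataFrame) -> pd.DataFrame:
    """Square roots of relative covers; each transformed row has unit norm.

    Zero-sum rows cannot be transformed and are excluded with a warning.
    """
    X = cover.to_numpy(dtype=float)
    sums = X.sum(axis=1)
    ok = sums > 0
    if not ok.all():
        warnings.warn(
            f"excluded {int((~ok).sum())} zero-sum cover rows", stacklevel=2
        )
    Y = np.sqrt(X[ok] / sums[ok, None])
    return pd.DataFrame(Y, index=cover.index[ok], columns=cover.columns)


def taxonomic_beta_distances(transformed: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distances among Hellinger-transformed rows (<= sqrt(2))."""
    if len(transformed) < 2:
        raise ValueError("beta distances need at least 2 plots")
    d = squareform(pdist(transformed.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=transformed.index, columns=transformed.index)
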