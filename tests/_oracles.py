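"""Independent brute-force reference implementations used only by tests.

Every function here recomputes a quantity by the most literal route
available (explicit loops, direct formulas, exact geometry), sharing no
code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Point, box
from shapely.ops import unary_union


def sd_alpha_loops(scores: np.ndarray) -> float:
    """Naive double loop over pixels and components."""
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    mean = [sum(scores[i, j] for i in range(n)) / n for j in range(k)]
    total = 0.0
    for i in range(n):
        for j in range(k):
            total += (scores[i, j] - mean[j]) ** 2
    return total / n


def hellinger_distances_loops(cover: np.ndarray) -> np.ndarray:
    """Per-pair sum of squared sqrt relative-abundance differences."""
    cover = np.asarray(cover, dtype=float)
    n = cover.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            p = cover[i] / cover[i].sum()
            q = cover[j] / cover[j].sum()
            out[i, j] = np.sqrt(((np.sqrt(p) - np.sqrt(q)) ** 2).sum())
    return out


def euclidean_distances_loops(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(((X[i] - X[j]) ** 2).sum())
    return out


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> dict:
    """OLS via the explicit 2x2 normal equations and textbook formulas."""
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    A = np.array([[n, x.sum()], [x.sum(), (x**2).sum()]])
    b = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(A, b)
    resid = y - intercept - slope * x
    ss_res = (resid**2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    se = np.sqrt(ss_res / (n - 2) / ((x - x.mean()) ** 2).sum())
    tval = slope / se
    return dict(
        slope=slope,
        intercept=intercept,
        r_squared=1 - ss_res / ss_tot,
        t_value=tval,
        p_value=2 * tdist.sf(abs(tval), n - 2),
    )


def pca_eigenvalues_svd(X: np.ndarray) -> np.ndarray:
    """Biased covariance eigenvalues via SVD of the centered data matrix."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    vals = s**2 / X.shape[0]
    out = np.zeros(min(X.shape))
    out[: len(vals)] = vals
    return out


def coinertia_eigenvalues_eigh(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Eigenvalues of (Y'X/n)(X'Y/n) via a dense symmetric eigensolver."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    S = Yc.T @ Xc / n
    vals = np.linalg.eigvalsh(S @ S.T)[::-1]
    return np.clip(vals, 0.0, None)


def phylo_covariance_ancestor_sets(tree) -> tuple[list[str], np.ndarray]:
    """C by intersecting root-to-tip ancestor edge sets: the shared branch
    length of two tips is the summed length of edges on both paths."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append((id(node), node.edge.length))
            node = node.parent_node
        paths[leaf.taxon.label] = dict(edges)
    labels = sorted(paths)
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = set(paths[a]) & set(paths[b])
            C[i, j] = sum(paths[a][k] for k in shared)
    return labels, C


def pse_direct(m: np.ndarray, C: np.ndarray) -> float:
    """Literal scalar-loop evaluation of the evenness formula."""
    m = np.asarray(m, dtype=float)
    C = np.asarray(C, dtype=float)
    n = len(m)
    M = sum(m)
    num = M * sum(m[i] * C[i, i] for i in range(n))
    num -= sum(m[i] * C[i, j] * m[j] for i in range(n) for j in range(n))
    den = M**2 - sum(m[i] ** 2 for i in range(n))
    return num / den


def psv_direct(C: np.ndarray) -> float:
    """Phylogenetic species variability: (n^2 - sum C) / (n (n - 1)) for
    unit-diagonal C."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    return (n * np.trace(C) - C.sum()) / (n * (n - 1))


def visible_cover_exact(trees, plot_side: float) -> dict[str, float]:
    """Exact visible crown cover by polygon clipping: process trees from
    tallest to shortest, each claiming its disc minus everything taller,
    clipped to the plot."""
    plot = box(0.0, 0.0, plot_side, plot_side)
    order = trees.sort_values("height_m", ascending=False, kind="stable")
    claimed = None
    areas: dict[str, float] = {}
    for _, row in order.iterrows():
        disc = Point(row["x_m"], row["y_m"]).buffer(
            row["crown_diameter_m"] / 2.0, quad_segs=256
        )
        visible = disc.intersection(plot)
        if claimed is not None:
            visible = visible.difference(claimed)
        areas[row["species"]] = areas.get(row["species"], 0.0) + visible.area
        claimed = disc if claimed is None else unary_union([claimed, disc])
    total = plot.area
    return {s: a / total for s, a in areas.items()}
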