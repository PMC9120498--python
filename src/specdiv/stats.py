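"""Two-table statistics linking spectral and plant diversity.

Three families of analysis:

* simple OLS regressions of spectral on taxonomic pairwise distances
  (pooled over pairs, per plot, per site, or across sites). Inference on
  pooled pairs uses naive OLS standard errors — distance pairs sharing a
  plot are not independent, so these p-values are descriptive; an optional
  Mantel permutation test (permuting plot labels of one matrix) provides
  calibrated inference;
* co-inertia analysis of two plot-matched tables, exposed statsmodels-style
  as ``CoInertia(X, Y).fit()`` returning a results object with the
  eigenvalue spectrum, RV coefficient and a Monte-Carlo permutation
  p-value on total co-inertia;
* per-LAI-class OLS of plant alpha-diversity metrics on spectral
  alpha-diversity.

Total co-inertia is the sum of squared singular values of the
cross-covariance Y'X/n, i.e. its squared Frobenius norm — the identity used
to keep the 999-permutation loop cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OlsFit",
    "DistanceRegressionResult",
    "distance_regression",
    "multisite_distance_regression",
    "mantel_test",
    "CoInertia",
    "CoInertiaResults",
    "variance_explained",
    "PAPER_LAI_CLASSES",
    "lai_class_regressions",
]


# ---------------------------------------------------------------------------
# ordinary least squares (closed form)


@dataclass
class OlsFit:
    """Simple-regression fit: y = intercept + slope * x."""

    n: int
    slope: float
    intercept: float
    r_squared: float
    t_value: float
    p_value: float

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


def ols_fit(x: np.ndarray, y: np.ndarray) -> OlsFit:
    """Closed-form OLS with the standard two-sided t test on the slope.

    A zero-variance regressor leaves the slope undefined; the fit is
    reported as missing (NaN statistics) rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("OLS needs at least 3 observations")
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx <= 0:
        return OlsFit(n, np.nan, np.nan, np.nan, np.nan, np.nan)
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    ss_res = (resid**2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    sigma2 = ss_res / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    if se == 0:
        t = np.inf if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return OlsFit(n, float(slope), float(intercept), float(r2), float(t), float(p))


# ---------------------------------------------------------------------------
# distance regressions


@dataclass
class DistanceRegressionResult:
    scope: str
    fit: OlsFit
    mantel_p: float | None = None
    site: str | None = None


def _upper(mat: pd.DataFrame) -> np.ndarray:
    a = mat.to_numpy(dtype=float)
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def _check_aligned(spectral: pd.DataFrame, taxonomic: pd.DataFrame) -> pd.DataFrame:
    if list(spectral.index) != list(spectral.columns) or list(
        taxonomic.index
    ) != list(taxonomic.columns):
        raise ValueError("distance matrices must be square with matching labels")
    common = [p for p in spectral.index if p in set(taxonomic.index)]
    if len(common) != len(spectral.index) or len(common) != len(taxonomic.index):
        raise ValueError("spectral and taxonomic matrices cover different plots")
    return taxonomic.loc[spectral.index, spectral.index]


def distance_regression(
    spectral: pd.DataFrame,
    taxonomic: pd.DataFrame,
    scope: str = "pairwise-pooled",
    mantel: bool = False,
    n_perm: int = 999,
    seed: int | None = None,
) -> DistanceRegressionResult:
    """OLS of spectral on taxonomic distance within one site.

    ``scope='pairwise-pooled'`` regresses over each unordered plot pair
    once; ``scope='per-plot'`` first averages each plot's distances to all
    other plots and regresses over plots. With ``mantel=True`` a label-
    permutation p-value (two-sided, on the Pearson correlation of pooled
    pairs) is attached.
    """
    taxonomic = _check_aligned(spectral, taxonomic)
    if scope == "pairwise-pooled":
        x, y = _upper(taxonomic), _upper(spectral)
    elif scope == "per-plot":
        n = len(spectral)
        x = (taxonomic.to_numpy().sum(axis=1)) / (n - 1)
        y = (spectral.to_numpy().sum(axis=1)) / (n - 1)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    res = DistanceRegressionResult(scope=scope, fit=ols_fit(x, y))
    if mantel:
        res.mantel_p = mantel_test(spectral, taxonomic, n_perm=n_perm, seed=seed)
    return res


def mantel_test(
    spectral: pd.DataFrame,
    taxonomic: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """Two-sided Mantel permutation p-value for the correlation between two
    distance matrices, permuting plot labels of the second matrix."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    taxonomic = _check_aligned(spectral, taxonomic)
    A = spectral.to_numpy(dtype=float)
    B = taxonomic.to_numpy(dtype=float)
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(b: np.ndarray) -> float:
        x, y = b[iu], A[iu]
        xc, yc = x - x.mean(), y - y.mean()
        denom = np.sqrt((xc**2).sum() * (yc**2).sum())
        return float(xc @ yc / denom) if denom > 0 else 0.0

    obs = abs(corr(B))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(corr(B[np.ix_(perm, perm)])) >= obs - 1e-15:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def multisite_distance_regression(
    sites: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    scope: str = "across-sites",
) -> DistanceRegressionResult | list[DistanceRegressionResult]:
    """Pooled ('across-sites') or per-site distance regressions.

    ``sites`` maps site id to a (spectral, taxonomic) distance-matrix pair.
    Across-sites pools every site's unordered pairs into one OLS.
    """
    if scope == "per-site":
        out = []
        for sid, (sp, tx) in sites.items():
            r = distance_regression(sp, tx, scope="pairwise-pooled")
            r.scope, r.site = "per-site", sid
            out.append(r)
        return out
    if scope == "across-sites":
        xs, ys = [], []
        for sp, tx in sites.values():
            tx = _check_aligned(sp, tx)
            xs.append(_upper(tx))
            ys.append(_upper(sp))
        return DistanceRegressionResult(
            scope="across-sites", fit=ols_fit(np.concatenate(xs), np.concatenate(ys))
        )
    raise ValueError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# co-inertia analysis


@dataclass
class CoInertiaResults:
    """Fitted co-inertia decomposition of two plot-matched tables."""

    eigenvalues: np.ndarray
    total_coinertia: float
    rv: float
    x_axes: np.ndarray  # (p, k) right singular vectors (X side)
    y_axes: np.ndarray  # (q, k) left singular vectors (Y side)
    n: int
    p_value: float | None = None
    n_permutations: int | None = None

    def summary(self) -> str:
        lines = [
            "Co-inertia analysis",
            f"  rows (plots):        {self.n}",
            f"  total co-inertia:    {self.total_coinertia:.6g}",
            f"  RV coefficient:      {self.rv:.4f}",
            "  eigenvalues:         "
            + ", ".join(f"{v:.4g}" for v in self.eigenvalues[:5])
            + (" ..." if len(self.eigenvalues) > 5 else ""),
        ]
        if self.p_value is not None:
            lines.append(
                f"  permutation p-value: {self.p_value:.4g}"
                f"  ({self.n_permutations} permutations)"
            )
        return "\n".join(lines)


class CoInertia:
    """Co-inertia analysis of two tables sharing rows (plots).

    Columns of both tables are centered with uniform row weights; the
    decomposition is the SVD of the cross-covariance Y'X/n. Eigenvalues are
    squared singular values; the RV coefficient normalizes their sum by the
    Frobenius norms of the two self-covariances.
    """

    def __init__(self, X: pd.DataFrame | np.ndarray, Y: pd.DataFrame | np.ndarray):
        if isinstance(X, pd.DataFrame) and isinstance(Y, pd.DataFrame):
            if list(X.index) != list(Y.index):
                raise ValueError("X and Y must share plots in the same row order")
        Xa = np.asarray(X, dtype=float)
        Ya = np.asarray(Y, dtype=float)
        if Xa.shape[0] != Ya.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        if Xa.shape[0] < 3:
            raise ValueError("co-inertia needs at least 3 rows")
        self.n = Xa.shape[0]
        self.Xc = Xa - Xa.mean(axis=0)
        self.Yc = Ya - Ya.mean(axis=0)

    @staticmethod
    def _total(Xc: np.ndarray, Yc: np.ndarray) -> float:
        # sum of squared singular values of Y'X/n == squared Frobenius norm
        n = Xc.shape[0]
        return float(((Yc.T @ Xc) ** 2).sum() / n**2)

    def fit(
        self, n_permutations: int | None = 999, seed: int | None = None
    ) -> CoInertiaResults:
        """Decompose and, unless ``n_permutations`` is None, attach the
        Monte-Carlo p-value for total co-inertia under row permutation of Y."""
        n = self.n
        cross = self.Yc.T @ self.Xc / n
        u, s, vt = np.linalg.svd(cross, full_matrices=False)
        eig = s**2
        total = float(eig.sum())
        sxx = self.Xc.T @ self.Xc / n
        syy = self.Yc.T @ self.Yc / n
        denom = np.sqrt((sxx**2).sum() * (syy**2).sum())
        rv = total / denom if denom > 0 else 0.0

        res = CoInertiaResults(
            eigenvalues=eig,
            total_coinertia=total,
            rv=float(rv),
            x_axes=vt.T,
            y_axes=u,
            n=n,
        )
        if n_permutations is not None:
            res.p_value = self.permutation_test(n_permutations, seed, observed=total)
            res.n_permutations = n_permutations
        return res

    def permutation_test(
        self, n_permutations: int = 999, seed: int | None = None, observed: float | None = None
    ) -> float:
        """p = (1 + #{permuted total >= observed}) / (n_permutations + 1),
        permuting rows of Y uniformly at random; deterministic under seed."""
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if observed is None:
            observed = self._total(self.Xc, self.Yc)
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(self.n)
            if self._total(self.Xc, self.Yc[perm]) >= observed - 1e-15:
                hits += 1
        return (1 + hits) / (n_permutations + 1)


def variance_explained(results: CoInertiaResults, model: CoInertia, n_axes: int | None = None) -> float:
    """Fraction of Y's total variance captured by projecting Y onto the
    co-inertia scores of X (a redundancy-style statistic; one plausible
    operationalization of "variation explained", not a canonical one).

    Non-decreasing in the number of axes used; 1 when Y = X and all axes
    are kept; 0 when the tables' column spaces are orthogonal.
    """
    k = len(results.eigenvalues) if n_axes is None else n_axes
    S = model.Xc @ results.x_axes[:, :k]
    ss_tot = (model.Yc**2).sum()
    if ss_tot == 0:
        return 0.0
    coef, *_ = np.linalg.lstsq(S, model.Yc, rcond=None)
    yhat = S @ coef
    return float((yhat**2).sum() / ss_tot)


# ---------------------------------------------------------------------------
# alpha-scale regressions by LAI class

#: LAI class bounds: first interval closed, the rest left-open/right-closed
PAPER_LAI_CLASSES: tuple[tuple[float, float], ...] = (
    (0.13, 0.634),
    (0.634, 1.183),
    (1.183, 1.84),
    (1.84, 3.80),
)


def lai_class_regressions(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = ("richness", "shannon", "pse"),
    classes: tuple[tuple[float, float], ...] = PAPER_LAI_CLASSES,
    min_plots: int = 3,
) -> pd.DataFrame:
    """Per-LAI-class OLS of each plant diversity metric on spectral
    alpha-diversity.

    ``table`` must carry columns ``sd_alpha``, ``lai`` and the metric
    columns. Classes partition LAI left-open/right-closed, except the first
    class which includes its left endpoint. Classes with fewer than
    ``min_plots`` plots are skipped with a warning. Returns a tidy frame
    with one row per (class, metric).
    """
    rows = []
    lai = table["lai"].to_numpy(dtype=float)
    for ci, (lo, hi) in enumerate(classes, start=1):
        if ci == 1:
            in_class = (lai >= lo) & (lai <= hi)
        else:
            in_class = (lai > lo) & (lai <= hi)
        sub = table[in_class]
        for metric in metrics:
            ok = sub[[metric, "sd_alpha"]].dropna()
            if len(ok) < min_plots:
                warnings.warn(
                    f"LAI class {ci} [{lo}, {hi}]: only {len(ok)} plots for "
                    f"{metric}; skipped",
                    stacklevel=2,
                )
                continue
            fit = ols_fit(ok["sd_alpha"].to_numpy(), ok[metric].to_numpy())
            rows.append(
                dict(
                    lai_class=ci,
                    lai_lo=lo,
                    lai_hi=hi,
                    metric=metric,
                    n=fit.n,
                    slope=fit.slope,
                    intercept=fit.intercept,
                    r_squared=fit.r_squared,
                    t_value=fit.t_value,
                    p_value=fit.p_value,
                )
            )
    return pd.DataFrame(rows)
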