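"""Spectral alpha- and beta-diversity in principal-component space.

All retained plots of a site are pooled into one pixels-by-bands matrix and
reduced by a single PCA with type-I (distance-preserving) scaling: columns
are centered on the pooled mean, never standardized, and pixel scores are
projections onto unit-norm eigenvectors, so Euclidean distances among
scores equal distances among centered spectra when all components are kept.
Components are retained until more than a target fraction (default 0.95)
of total spectral variance is explained.

Spectral alpha-diversity (SD_alpha) of a plot is the mean squared deviation
of its pixel scores from the plot centroid, summed over retained
components — i.e. the total biased variance of the plot in the retained
space. Spectral beta-diversity is the matrix of pairwise Euclidean
distances among plot mean spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .preprocess import PlotPixelMatrix

__all__ = [
    "PcaModel",
    "SpectralAlphaResult",
    "fit_pooled_pca",
    "spectral_alpha",
    "site_spectral_alpha",
    "plot_mean_spectrum",
    "plot_mean_spectra",
    "spectral_beta_distances",
]


@dataclass
class PcaModel:
    """Pooled principal components with type-I scaling.

    ``eigenvectors`` columns are unit-norm band-space axes ordered by
    non-increasing ``eigenvalues`` (biased covariance eigenvalues);
    ``n_retained`` is the smallest k whose cumulative variance fraction
    exceeds the target.
    """

    mean: np.ndarray
    eigenvectors: np.ndarray  # (n_bands, n_components)
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    n_retained: int

    def transform(self, spectra: np.ndarray, retained_only: bool = True) -> np.ndarray:
        vec = self.eigenvectors[:, : self.n_retained] if retained_only else self.eigenvectors
        return (np.asarray(spectra) - self.mean) @ vec


@dataclass
class SpectralAlphaResult:
    plot_id: str
    sd_alpha: float
    n_pixels: int


def fit_pooled_pca(
    matrices: dict[str, PlotPixelMatrix] | list[PlotPixelMatrix],
    variance_target: float = 0.95,
) -> tuple[PcaModel, dict[str, np.ndarray]]:
    """Fit one PCA on all plots' pixels pooled; return per-plot scores.

    The eigendecomposition runs on the band-space covariance when there are
    at least as many pixels as bands, otherwise on the pixel-space Gram
    matrix; both routes give identical retained scores up to sign.
    """
    if isinstance(matrices, dict):
        items = list(matrices.items())
    else:
        items = [(m.plot_id, m) for m in matrices]
    if not items:
        raise ValueError("no plot pixel matrices supplied")
    X = np.vstack([m.pixels for _, m in items])
    n, p = X.shape
    if n < 2:
        raise ValueError("pooled PCA needs at least 2 pixels")

    mean = X.mean(axis=0)
    Xc = X - mean
    if n >= p:
        cov = (Xc.T @ Xc) / n
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
    else:
        gram = (Xc @ Xc.T) / n
        gvals, gvecs = np.linalg.eigh(gram)
        order = np.argsort(gvals)[::-1]
        gvals = np.clip(gvals[order], 0.0, None)
        gvecs = gvecs[:, order]
        nz = gvals > 1e-14 * max(gvals[0], 1.0)
        gvals, gvecs = gvals[nz], gvecs[:, nz]
        evals = gvals
        evecs = Xc.T @ gvecs / np.sqrt(n * gvals)  # unit band-space axes

    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    cum = np.cumsum(frac)
    k = int(np.searchsorted(cum, variance_target, side="right")) + 1
    k = min(k, len(evals))

    model = PcaModel(
        mean=mean,
        eigenvectors=evecs,
        eigenvalues=evals,
        variance_fraction=frac,
        n_retained=k,
    )
    scores = {pid: model.transform(m.pixels) for pid, m in items}
    return model, scores


def spectral_alpha(plot_id: str, scores: np.ndarray) -> SpectralAlphaResult:
    """SD_alpha: mean over pixels of the squared deviation from the plot's
    centroid, summed across retained components (biased total variance)."""
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n < 1:
        raise ValueError("spectral alpha needs at least one pixel")
    dev = scores - scores.mean(axis=0)
    return SpectralAlphaResult(plot_id, float((dev**2).sum() / n), n)


def site_spectral_alpha(scores: dict[str, np.ndarray]) -> pd.DataFrame:
    """SD_alpha for every plot; index = plot_id."""
    rows = [spectral_alpha(pid, s) for pid, s in scores.items()]
    return pd.DataFrame(
        {"sd_alpha": [r.sd_alpha for r in rows], "n_pixels": [r.n_pixels for r in rows]},
        index=pd.Index([r.plot_id for r in rows], name="plot_id"),
    )


def plot_mean_spectrum(matrix: PlotPixelMatrix) -> np.ndarray:
    """Per-band arithmetic mean of a plot's retained (normalized) pixels."""
    if matrix.n_pixels < 1:
        raise ValueError(f"plot {matrix.plot_id}: no retained pixels")
    return matrix.pixels.mean(axis=0)


def plot_mean_spectra(matrices: dict[str, PlotPixelMatrix]) -> pd.DataFrame:
    """Stack plot mean spectra into a plots-by-bands table."""
    ids = list(matrices)
    means = np.vstack([plot_mean_spectrum(matrices[p]) for p in ids])
    return pd.DataFrame(means, index=pd.Index(ids, name="plot_id"))


def spectral_beta_distances(mean_spectra: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Euclidean distance matrix among plot mean spectra."""
    if len(mean_spectra) < 2:
        raise ValueError("beta distances need at least 2 plots")
    d = squareform(pdist(mean_spectra.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=mean_spectra.index, columns=mean_spectra.index)
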