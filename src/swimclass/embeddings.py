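"""PCA of classifier embeddings and the speed/concentration gradient.

The penultimate-layer activations summarize the visual features the
classifier extracted from a track image.  PCA of those vectors shows how
the conditions organize in feature space; rank-correlating each principal
component with the independently computed per-segment average speed (and
with concentration) tests whether the learned representation is a mere
speed readout or captures additional track structure.  Rank correlation is
used because the speed relation is a gradient, not a line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA

from .classifier import EmbeddingMatrix
from .trajectory import ValidationError

__all__ = ["PCAResult", "GradientReport", "pca", "variance_explained", "speed_gradient"]


@dataclass
class PCAResult:
    components: np.ndarray  # (n_components, dim), orthonormal rows
    explained_variance_ratio: np.ndarray  # non-increasing, sums to <= 1
    projections: np.ndarray  # (n_segments, n_components)
    mean: np.ndarray
    segment_refs: list


@dataclass
class GradientReport:
    spearman_with_speed: np.ndarray  # per component
    spearman_with_concentration: np.ndarray  # per component, controls excluded

    @property
    def n_components(self) -> int:
        return len(self.spearman_with_speed)


def pca(embeddings: EmbeddingMatrix, n_components: int) -> PCAResult:
    """Principal components of the (mean-centered) embedding rows.

    Deterministic sign convention: within each component the loading of
    largest magnitude is made positive, so repeated runs and different SVD
    backends agree.
    """
    if n_components <= 0:
        raise ValidationError("n_components must be > 0")
    x = np.asarray(embeddings.rows, dtype=np.float64)
    if n_components > min(x.shape):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_samples, dim)={min(x.shape)}")
    model = _SkPCA(n_components=n_components, svd_solver="full")
    projections = model.fit_transform(x)
    components = model.components_.copy()
    for i in range(components.shape[0]):
        j = int(np.abs(components[i]).argmax())
        if components[i, j] < 0:
            components[i] = -components[i]
            projections[:, i] = -projections[:, i]
    return PCAResult(
        components=components,
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
        projections=projections,
        mean=model.mean_.copy(),
        segment_refs=list(embeddings.segment_refs),
    )


def variance_explained(result: PCAResult, k: int) -> float:
    """Cumulative variance fraction captured by the first k components."""
    if k > len(result.explained_variance_ratio):
        raise ValidationError("k exceeds the number of computed components")
    return float(result.explained_variance_ratio[:k].sum())


def speed_gradient(result: PCAResult, speeds, concentrations=None) -> GradientReport:
    """Rank correlation of each component with speed and concentration.

    ``speeds`` and ``concentrations`` align with ``result.segment_refs``.
    Control segments must carry NaN concentration; they are excluded from
    the concentration correlation (but kept for speed).
    """
    speeds = np.asarray(speeds, dtype=np.float64)
    if speeds.shape[0] != result.projections.shape[0]:
        raise ValidationError("speeds misaligned with projections")
    k = result.projections.shape[1]
    rho_speed = np.empty(k)
    for i in range(k):
        rho_speed[i] = stats.spearmanr(result.projections[:, i], speeds).statistic
    if concentrations is None:
        rho_conc = np.full(k, np.nan)
    else:
        conc = np.asarray(concentrations, dtype=np.float64)
        if conc.shape[0] != result.projections.shape[0]:
            raise ValidationError("concentrations misaligned with projections")
        mask = ~np.isnan(conc)
        rho_conc = np.empty(k)
        degenerate = mask.sum() < 2 or np.unique(conc[mask]).size < 2
        for i in range(k):
            if degenerate:
                rho_conc[i] = np.nan
                continue
            rho_conc[i] = stats.spearmanr(
                result.projections[mask, i], conc[mask]).statistic
    return GradientReport(spearman_with_speed=rho_speed,
                          spearman_with_concentration=rho_conc)
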