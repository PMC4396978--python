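"""PCA score-plane outlier screening with a Hotelling T-squared ellipse.

Samples are projected onto the first two principal components of the
autoscaled matrix; a sample whose T-squared statistic
``t1^2/lambda1 + t2^2/lambda2`` exceeds the F-based 95% ellipse boundary is
flagged and removed once (no iterative re-screening), and the remaining rows
are re-autoscaled before discriminant modeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import DataValidationError
from .preprocess import ScaledMatrix, autoscale


class DegenerateRankError(ValueError):
    """The matrix has fewer than two non-degenerate principal directions."""


class InsufficientSamplesError(ValueError):
    """Too few samples for the requested screen."""


class AllOutliersError(RuntimeError):
    """Every sample was flagged; the pipeline cannot continue."""


@dataclass
class OutlierReport:
    """Scores, eigenvalues, per-sample T-squared and the ellipse decision."""

    scores: np.ndarray        # n x 2
    eigenvalues: np.ndarray   # (lambda1, lambda2), sample variances of the scores
    t2_stat: np.ndarray
    threshold: float
    outlier_mask: np.ndarray
    alpha: float = 0.95

    @property
    def n_flagged(self) -> int:
        return int(self.outlier_mask.sum())

    def to_frame(self, sample_ids=None) -> pd.DataFrame:
        ids = sample_ids if sample_ids is not None else np.arange(len(self.t2_stat))
        return pd.DataFrame({
            "sample": ids,
            "pc1": self.scores[:, 0],
            "pc2": self.scores[:, 1],
            "t2": self.t2_stat,
            "threshold": self.threshold,
            "flagged": self.outlier_mask,
        })


def pca_scores(X: np.ndarray | ScaledMatrix, k: int = 2
               ) -> tuple[np.ndarray, np.ndarray]:
    """Scores and eigenvalues of the top-k principal components.

    Eigenvalues are the sample variances of the scores (n-1 denominator).
    Sign convention: the largest-magnitude loading entry of each component
    is made positive, so scores are reproducible across LAPACK builds.
    Raises :class:`DegenerateRankError` when fewer than ``k`` directions
    carry variance (lambda_k below 1e-10, absolutely or relative to
    lambda_1).
    """
    if isinstance(X, ScaledMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise InsufficientSamplesError("PCA screening needs at least 3 samples")
    if p < k:
        raise DegenerateRankError(f"need at least {k} columns, got {p}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s ** 2 / (n - 1)
    if eigenvalues[k - 1] < 1e-10 or eigenvalues[k - 1] < 1e-12 * eigenvalues[0]:
        raise DegenerateRankError(
            f"rank below {k}: eigenvalue {k} = {eigenvalues[k - 1]:.3e}")
    scores = U[:, :k] * s[:k]
    for a in range(k):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            scores[:, a] = -scores[:, a]
    return scores, eigenvalues[:k]


def hotelling_outliers(scores: np.ndarray, eigenvalues: np.ndarray,
                       alpha: float = 0.95, n: int | None = None) -> OutlierReport:
    """Flag samples outside the (alpha x 100)% Hotelling ellipse in the score plane.

    The boundary uses the exact small-sample F form for two components:
    ``threshold = 2 (n-1) / (n-2) * F_alpha(2, n-2)``.
    """
    scores = np.asarray(scores, dtype=float)
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if n is None:
        n = scores.shape[0]
    if n <= 3:
        raise InsufficientSamplesError("Hotelling screen needs more than 3 samples")
    if np.any(eigenvalues <= 0):
        raise DegenerateRankError("non-positive eigenvalue in Hotelling screen")
    t2 = (scores[:, 0] ** 2) / eigenvalues[0] + (scores[:, 1] ** 2) / eigenvalues[1]
    threshold = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(alpha, 2, n - 2)
    mask = t2 > threshold
    return OutlierReport(scores=scores, eigenvalues=eigenvalues, t2_stat=t2,
                         threshold=float(threshold), outlier_mask=mask, alpha=alpha)


@dataclass
class ScreenResult:
    clean: ScaledMatrix
    report: OutlierReport
    kept_rows: np.ndarray


def screen(X: np.ndarray, alpha: float = 0.95, names=None,
           rescale_after_removal: bool = True) -> ScreenResult:
    """Autoscale, screen once on the first two PCs, drop outliers, re-autoscale.

    ``X`` is the unscaled analysis matrix.  Because autoscaling is a
    per-column affine map, re-autoscaling the retained raw rows equals
    re-autoscaling the retained rows of the scaled matrix.  With
    ``rescale_after_removal=False`` the original scaling is kept and only
    the flagged rows are dropped.
    """
    X = np.asarray(X, dtype=float)
    scaled = autoscale(X, names=names)
    scores, eigenvalues = pca_scores(scaled.values)
    report = hotelling_outliers(scores, eigenvalues, alpha=alpha)
    keep = ~report.outlier_mask
    if not keep.any():
        raise AllOutliersError("every sample fell outside the Hotelling ellipse")
    kept_rows = np.flatnonzero(keep)
    if report.n_flagged == 0:
        return ScreenResult(clean=scaled, report=report, kept_rows=kept_rows)
    if rescale_after_removal:
        clean = autoscale(X[kept_rows], names=names)
    else:
        clean = ScaledMatrix(values=scaled.values[keep], means=scaled.means,
                             sds=scaled.sds, kept=scaled.kept,
                             dropped=scaled.dropped, names=scaled.names)
    return ScreenResult(clean=clean, report=report, kept_rows=kept_rows)
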