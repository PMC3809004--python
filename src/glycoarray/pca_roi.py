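"""PCA of ROI spectrum matrices: variance accounting, PC1 orientation,
loading-threshold ion selection, and region-separation testing.

The spectrum matrix (one row per ROI-averaged, total-ion-normalized and
mean-centered spectrum) is decomposed by SVD. PC1 of a field containing a
printed glycan spot separates spot ROIs from substrate/background ROIs; its
sign is arbitrary, so :func:`orient_pc1` fixes the convention that background
ROIs score positive — substrate/background ions then carry positive PC1
loadings and glycan-related ions negative ones. Ions whose |PC1 loading|
reaches a threshold (0.03 by default) are selected for imaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sims_cube import PeakTable, SpectrumMatrix

__all__ = [
    "PcaResult",
    "IonSelection",
    "fit_pca",
    "orient_pc1",
    "select_ions",
    "group_separation",
]

DEFAULT_LOADING_THRESHOLD = 0.03


@dataclass
class PcaResult:
    """Scores, unit-norm loadings and variance fractions, descending variance."""

    scores: np.ndarray  # n_spectra x n_components
    loadings: np.ndarray  # n_peaks x n_components, orthonormal columns
    variance_fraction: np.ndarray
    singular_values: np.ndarray
    labels: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def to_csv(self, directory: str | Path, prefix: str = "pca") -> None:
        directory = Path(directory)
        pd.DataFrame(
            self.scores,
            index=self.labels,
            columns=[f"PC{i+1}" for i in range(self.n_components)],
        ).to_csv(directory / f"{prefix}_scores.csv")
        pd.DataFrame(
            self.loadings, columns=[f"PC{i+1}" for i in range(self.n_components)]
        ).to_csv(directory / f"{prefix}_loadings.csv", index=False)
        pd.DataFrame(
            {"component": np.arange(1, self.n_components + 1),
             "variance_fraction": self.variance_fraction}
        ).to_csv(directory / f"{prefix}_variance.csv", index=False)


def fit_pca(
    matrix: SpectrumMatrix | np.ndarray, n_components: int | None = None
) -> PcaResult:
    """PCA by singular value decomposition of a column-centered matrix.

    scores = U * S (projections onto the loadings), loadings = right singular
    vectors, variance_fraction_j = s_j^2 / sum(s^2) over all singular values.
    The matrix must already be column-centered (see
    :func:`glycoarray.sims_cube.normalize_spectra`); each component's sign is
    fixed by making its largest-magnitude loading positive, a deterministic
    convention later overridden for PC1 by :func:`orient_pc1`.
    """
    labels = None
    if isinstance(matrix, SpectrumMatrix):
        labels = list(matrix.labels)
        x = matrix.values
    else:
        x = np.asarray(matrix, dtype=float)
    n, p = x.shape
    scale = max(1.0, float(np.abs(x).max()))
    if np.any(np.abs(x.mean(axis=0)) > 1e-8 * scale):
        raise ValueError("matrix is not column mean-centered")
    max_k = min(n - 1, p)
    if n_components is None:
        n_components = max_k
    if not 1 <= n_components <= max_k:
        raise ValueError(f"n_components must be in [1, {max_k}]")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if not np.any(s > 0):
        raise ValueError("rank-zero matrix")
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(len(s)):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    total = float(np.sum(s**2))
    k = n_components
    return PcaResult(
        scores=u[:, :k] * s[:k],
        loadings=vt[:k].T.copy(),
        variance_fraction=s[:k] ** 2 / total,
        singular_values=s[:k].copy(),
        labels=labels,
    )


def orient_pc1(pca: PcaResult, background_rows: Sequence[int]) -> PcaResult:
    """Flip PC1 so background-ROI rows have positive mean score.

    Resolves the sign indeterminacy of the first component to the convention
    that substrate/background spectra score (and load) positive. Scores and
    loadings flip jointly; other components are untouched.
    """
    background_rows = list(background_rows)
    if not background_rows:
        raise ValueError("background row indices must be non-empty")
    mean = float(pca.scores[background_rows, 0].mean())
    if mean == 0.0:
        raise ValueError("orientation undefined: background mean PC1 score is zero")
    scores = pca.scores.copy()
    loadings = pca.loadings.copy()
    if mean < 0:
        scores[:, 0] = -scores[:, 0]
        loadings[:, 0] = -loadings[:, 0]
    return PcaResult(
        scores=scores,
        loadings=loadings,
        variance_fraction=pca.variance_fraction.copy(),
        singular_values=pca.singular_values.copy(),
        labels=list(pca.labels) if pca.labels is not None else None,
    )


@dataclass
class IonSelection:
    """Ions passing the |PC1 loading| threshold, split by loading sign.

    With PC1 oriented, the positive list collects substrate/background ions
    and the negative list glycan-related ions. `table` holds one row per peak
    with its loading and side ("positive", "negative" or "none").
    """

    positive_ions: PeakTable
    negative_ions: PeakTable
    threshold: float
    table: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def selected_peaks(self) -> PeakTable:
        df = pd.concat([self.positive_ions.df, self.negative_ions.df])
        return PeakTable(df.sort_values("mz"))


def select_ions(
    pca: PcaResult,
    peaks: PeakTable,
    threshold: float = DEFAULT_LOADING_THRESHOLD,
) -> IonSelection:
    """Threshold PC1 loadings to select ions for imaging (boundary inclusive).

    `peaks` must list the peaks in the column order of the fitted matrix.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    loading = pca.loadings[:, 0]
    if len(loading) != len(peaks):
        raise ValueError("peak table length must match loading count")
    side = np.where(
        loading >= threshold, "positive", np.where(loading <= -threshold, "negative", "none")
    )
    table = peaks.df.copy()
    table["loading"] = loading
    table["side"] = side
    table = table[["mz", "loading", "side", "formula", "category"]]
    return IonSelection(
        positive_ions=PeakTable(peaks.df[side == "positive"], mz_tol=peaks.mz_tol),
        negative_ions=PeakTable(peaks.df[side == "negative"], mz_tol=peaks.mz_tol),
        threshold=threshold,
        table=table,
    )


def group_separation(
    scores_pc1: np.ndarray, labels: Sequence[str]
) -> float:
    """Two-sided Welch two-sample t-test p-value on PC1 scores.

    Exactly two groups with >= 2 rows each are required. Welch's unequal-
    variance form is used because spot and background ROI classes have no
    reason to share a variance. Degenerate case: both groups constant —
    p = 1 for equal means, p = 0 otherwise.
    """
    scores_pc1 = np.asarray(scores_pc1, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a = scores_pc1[labels == groups[0]]
    b = scores_pc1[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two rows")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
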