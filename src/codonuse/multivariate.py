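"""Cross-strain analysis: PCA on strain x RSCU matrices and correlations.

Each strain is a 59-dimensional point (one RSCU value per synonymous sense
codon).  PCA of the column-centered matrix extracts the major axes of codon
usage variation; the first two scores are the strain coordinates usually
plotted and tabulated.  Composition variables (overall vs third-position
base percentages, GC12 vs GC3, ENC vs GC3) are compared by Pearson
product-moment correlation, with a Spearman option for sensitivity checks.
"""

from __future__ import annotations

import dataclasses
import math
import warnings as _warnings
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .codon_stats import CompositionProfile, RSCUVector
from .genetic_code import BASES, SYNONYMOUS_CODONS

__all__ = [
    "RSCUMatrix",
    "PCAResult",
    "CorrelationReport",
    "build_rscu_matrix",
    "pca_rscu",
    "pearson",
    "correlation_suite",
]

#: neutral RSCU used to fill cells of families absent from a strain
NEUTRAL_RSCU = 1.0


@dataclasses.dataclass
class RSCUMatrix:
    """Strains x 59 RSCU value matrix with fixed codon column order."""

    strain_ids: list[str]
    matrix: np.ndarray
    column_labels: tuple[str, ...] = SYNONYMOUS_CODONS

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 59:
            raise ValueError("RSCU matrix must have exactly 59 columns")
        if self.matrix.shape[0] != len(self.strain_ids):
            raise ValueError("row count must match number of strain ids")
        if np.isnan(self.matrix).any():
            raise ValueError("RSCU matrix may not contain missing cells")


@dataclasses.dataclass(frozen=True)
class PCAResult:
    """Scores, variance fractions and loadings of an RSCU decomposition.

    ``coordinates[:, 0]`` and ``coordinates[:, 1]`` are the first and
    second principal-component scores per strain.  ``variance_fraction``
    is ``None`` for a zero-variance input (all strains identical).
    """

    coordinates: np.ndarray
    variance_fraction: np.ndarray | None
    loadings: np.ndarray
    scaling: str


@dataclasses.dataclass(frozen=True)
class CorrelationReport:
    """Pairwise correlations: list of (x_name, y_name, r, p, n) tuples."""

    pairs: list[tuple[str, str, float, float, int]]


def build_rscu_matrix(vectors: Sequence[RSCUVector],
                      ids: Sequence[str]) -> RSCUMatrix:
    """Stack per-strain RSCU vectors into a strains x 59 matrix.

    Codon columns are in fixed alphabetical (DNA spelling) order.  Cells of
    families absent from a strain are imputed with the neutral value 1.0
    (equal usage) and a warning is emitted — imputing 0 would manufacture
    bias in families the strain simply never uses.
    """
    if len(vectors) != len(ids):
        raise ValueError("vectors and ids must have equal length")
    if len(vectors) < 2:
        raise ValueError("need at least 2 strains to build a matrix")

    rows = []
    for strain_id, vec in zip(ids, vectors):
        row = [vec.values[c] for c in SYNONYMOUS_CODONS]
        if vec.undefined:
            _warnings.warn(
                f"{strain_id}: imputing neutral RSCU 1.0 for absent "
                f"families ({len(vec.undefined)} codons)",
                stacklevel=2,
            )
            row = [NEUTRAL_RSCU if math.isnan(v) else v for v in row]
        rows.append(row)
    return RSCUMatrix(strain_ids=list(ids), matrix=np.array(rows))


def pca_rscu(m: RSCUMatrix,
             scaling: Literal["covariance", "correlation"] = "covariance",
             ) -> PCAResult:
    """PCA of the column-centered RSCU matrix.

    ``covariance`` (default) decomposes the centered values as-is — RSCU is
    already a common dimensionless scale; ``correlation`` additionally
    standardizes each codon column to unit variance.  Component signs are
    fixed so that each component's largest-magnitude loading is positive,
    making results deterministic across runs and platforms.  All
    ``min(n_strains, 59)`` components are retained so that
    ``scores @ loadings.T`` reconstructs the centered (scaled) matrix.
    """
    if scaling not in ("covariance", "correlation"):
        raise ValueError(f"bad scaling: {scaling!r}")
    x = m.matrix.astype(float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 strains for a PCA")

    centered = x - x.mean(axis=0)
    if scaling == "correlation":
        sd = centered.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0  # constant columns carry no variance either way
        centered = centered / sd

    total_var = float(np.sum(centered ** 2))
    if total_var <= 1e-12:
        k = min(n, 59)
        return PCAResult(coordinates=np.zeros((n, k)),
                         variance_fraction=None,
                         loadings=np.zeros((59, k)),
                         scaling=scaling)

    k = min(n, 59)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(centered)
    loadings = pca.components_.T  # 59 x k

    # sign convention: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    frac = pca.explained_variance_ratio_.copy()
    return PCAResult(coordinates=scores, variance_fraction=frac,
                     loadings=loadings, scaling=scaling)


def pearson(x: Sequence[float], y: Sequence[float],
            method: Literal["pearson", "spearman"] = "pearson",
            ) -> tuple[float, float, int]:
    """Correlation between two equal-length vectors.

    Returns (r, p, n) with a two-sided p from the t-distribution on n-2
    degrees of freedom.  Zero variance in either argument yields NaN r and
    p rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan, n
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def correlation_suite(profiles: Iterable[CompositionProfile],
                      enc_values: Sequence[float] | None = None,
                      method: Literal["pearson", "spearman"] = "pearson",
                      ) -> CorrelationReport:
    """All overall-vs-third-position correlations, plus GC12-GC3 (and
    ENC-GC3 when per-strain ENC values are supplied).

    Each overall base percentage (T%, C%, A%, G%) is correlated with each
    synonymous-third-position percentage (T3%, C3%, A3%, G3%), probing
    whether genome-wide composition drives third-position usage.
    """
    profiles = list(profiles)
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles")
    if any(p.third_syn is None for p in profiles):
        raise ValueError("all profiles must have third-position data")

    pairs: list[tuple[str, str, float, float, int]] = []
    for bx in BASES:
        for by in BASES:
            x = [p.overall[bx] for p in profiles]
            y = [p.third_syn[by] for p in profiles]  # type: ignore[index]
            r, p_val, n = pearson(x, y, method=method)
            pairs.append((f"{bx}%", f"{by}3%", r, p_val, n))

    gc12 = [p.gc12 for p in profiles]
    gc3 = [p.gc3 for p in profiles]
    r, p_val, n = pearson(gc12, gc3, method=method)
    pairs.append(("gc12", "gc3", r, p_val, n))

    if enc_values is not None:
        if len(enc_values) != len(profiles):
            raise ValueError("enc_values length must match profiles")
        r, p_val, n = pearson(list(enc_values), gc3, method=method)
        pairs.append(("enc", "gc3", r, p_val, n))

    return CorrelationReport(pairs=pairs)
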