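"""Spot-to-centroid similarity scores and pie proportions.

Each spot s is scored against every cluster centroid k at a resolution with
an exponentially decaying function of their root-mean-square deviation:

    score(s, k) = exp(-lambda * RMSD(x_s, mean{x_s'} for s' in C(k)))

where x_s is the spot's expression vector and C(k) the spots of cluster k.
Scores lie in (0, 1] and equal 1 exactly when the spot matches the centroid.
Normalizing a spot's scores to sum to one gives the slice proportions of its
pie glyph in the array plot; because the pies relativize membership rather
than hard-assigning it, gradual spatial transitions between regions remain
visible.

lambda controls the sharpness of the decay and is user-selectable.  The
"auto" mode picks lambda = ln 2 / median_s RMSD(x_s, nearest centroid), so a
spot at the median distance from its closest centroid scores 0.5 — a scale-
free default that behaves consistently across normalizations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreConfig:
    """Decay constant configuration: a fixed lambda or data-driven "auto"."""

    lambda_: float = 0.0
    mode: str = "auto"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "auto"):
            raise ValueError(f"mode must be 'fixed' or 'auto', got {self.mode!r}")
        if self.lambda_ < 0:
            raise ValueError(f"lambda must be nonnegative, got {self.lambda_}")


@dataclass(frozen=True)
class SimilarityResult:
    """Per-resolution spots × clusters scores and normalized pie proportions."""

    resolution_label: str
    spot_ids: tuple[str, ...]
    scores: np.ndarray
    proportions: np.ndarray
    lambda_used: float

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        props = np.asarray(self.proportions, dtype=float)
        if scores.shape != props.shape:
            raise ValueError("scores and proportions differ in shape")
        if scores.shape[0] != len(self.spot_ids):
            raise ValueError("row count does not match spot_ids")
        if (scores <= 0).any() or (scores > 1 + 1e-12).any():
            raise ValueError("scores must lie in (0, 1]")
        if not np.allclose(props.sum(axis=1), 1.0, rtol=0, atol=1e-9):
            raise ValueError("proportion rows must sum to 1")

    @property
    def n_clusters(self) -> int:
        return self.scores.shape[1]

    def to_dataframe(self):
        import pandas as pd

        data = {}
        for j in range(self.n_clusters):
            data[f"cluster_{j + 1}_score"] = self.scores[:, j]
        for j in range(self.n_clusters):
            data[f"cluster_{j + 1}_proportion"] = self.proportions[:, j]
        return pd.DataFrame(data, index=list(self.spot_ids)).rename_axis("spot")


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two gene vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError(f"need equal-length 1-D vectors, got {a.shape} and {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _rmsd_matrix(values: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # euclidean distance / sqrt(G) == RMSD
    return cdist(values, centroids, metric="euclidean") / np.sqrt(values.shape[1])


def resolve_lambda(
    matrix: ExpressionMatrix, centroids: np.ndarray, config: ScoreConfig
) -> float:
    """Concrete decay constant for scoring.

    Fixed mode passes the configured value through.  Auto mode returns
    ln 2 / median over spots of the RMSD to the nearest centroid (median of
    an even count = mean of the two central order statistics); when every
    spot coincides with a centroid the median is zero and lambda falls back
    to 0 with a warning.
    """
    if config.mode == "fixed":
        return float(config.lambda_)
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if centroids.shape[1] != matrix.n_genes:
        raise ValueError(
            f"centroid gene dimension {centroids.shape[1]} != {matrix.n_genes}"
        )
    nearest = _rmsd_matrix(matrix.values, centroids).min(axis=1)
    med = float(np.median(nearest))
    if med == 0.0:
        logger.warning("auto lambda: median nearest-centroid RMSD is 0; lambda = 0")
        return 0.0
    return float(np.log(2.0) / med)


def similarity_scores(
    matrix: ExpressionMatrix,
    centroids: np.ndarray,
    config: ScoreConfig = ScoreConfig(),
    resolution_label: str = "",
) -> SimilarityResult:
    """Score every spot against every centroid and derive pie proportions.

    ``proportions[s, :]`` is ``scores[s, :]`` normalized to sum to one; with
    lambda = 0 all scores are 1 and every pie is uniform.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if centroids.shape[1] != matrix.n_genes:
        raise ValueError(
            f"centroid gene dimension {centroids.shape[1]} != {matrix.n_genes}"
        )
    lam = resolve_lambda(matrix, centroids, config)
    scores = np.exp(-lam * _rmsd_matrix(matrix.values, centroids))
    proportions = scores / scores.sum(axis=1, keepdims=True)
    return SimilarityResult(
        resolution_label=resolution_label,
        spot_ids=matrix.spot_ids,
        scores=scores,
        proportions=proportions,
        lambda_used=lam,
    )


def pie_entropy(proportions: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) of each spot's pie; high = ambiguous membership."""
    p = np.asarray(proportions, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=-1)
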