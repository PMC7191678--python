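"""Multi-resolution clustering with a pluggable backend registry.

Rather than committing to a single cluster count, the expression matrix is
clustered independently at every requested *resolution* (a target k plus a
backend and seed).  Relationships between the resulting partitions are
recovered afterwards by the cluster graph; no hierarchy is imposed here.
Backends are plain callables ``(values, k, seed) -> labels`` registered by
name, so any clustering algorithm can slot in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

# backend signature: (values: (n_spots, n_genes) float array, k, seed) -> int labels
Backend = Callable[[np.ndarray, int, int], np.ndarray]

_BACKENDS: dict[str, Backend] = {}


class UnknownBackendError(KeyError):
    pass


def register_backend(name: str, fn: Backend, *, overwrite: bool = False) -> None:
    """Register a clustering backend under ``name``.

    The callable receives the (possibly normalized) expression values, the
    target cluster count and a seed, and must return one integer label per
    spot (any label values; they are compacted and canonicalized afterwards).
    """
    if name in _BACKENDS and not overwrite:
        raise ValueError(f"backend {name!r} already registered")
    _BACKENDS[name] = fn


def get_backend(name: str) -> Backend:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise UnknownBackendError(
            f"unknown backend {name!r}; registered: {sorted(_BACKENDS)}"
        ) from None


def list_backends() -> list[str]:
    return sorted(_BACKENDS)


def _kmeans_backend(values: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(values)


def _ward_backend(values: np.ndarray, k: int, seed: int) -> np.ndarray:
    # deterministic; seed unused
    return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(values)


register_backend("kmeans", _kmeans_backend)
register_backend("hierarchical-ward", _ward_backend)


@dataclass(frozen=True)
class ResolutionSpec:
    """One clustering resolution: a label, target k, backend and seed."""

    label: str
    k: int
    method: str = "kmeans"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"resolution {self.label!r}: k must be >= 1, got {self.k}")


def resolutions_from_ks(
    ks: Sequence[int], method: str = "kmeans", seed: int = 0
) -> list[ResolutionSpec]:
    """Convenience: one spec per k, labeled by the k value."""
    return [ResolutionSpec(label=str(k), k=k, method=method, seed=seed) for k in ks]


@dataclass(frozen=True)
class MultiResolutionClustering:
    """Per-resolution spot→cluster assignments.

    ``assignments[label]`` is an int vector aligned with ``spot_ids`` using
    labels 1..k_effective (consecutive, no empty clusters).
    """

    spot_ids: tuple[str, ...]
    resolutions: tuple[ResolutionSpec, ...]
    assignments: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "spot_ids", tuple(self.spot_ids))
        object.__setattr__(self, "resolutions", tuple(self.resolutions))
        labels = [r.label for r in self.resolutions]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate resolution labels in {labels}")
        if set(self.assignments) != set(labels):
            raise ValueError("assignments do not cover exactly the declared resolutions")
        for label in labels:
            vec = np.asarray(self.assignments[label], dtype=int)
            self.assignments[label] = vec
            if vec.shape != (len(self.spot_ids),):
                raise ValueError(
                    f"resolution {label!r}: {vec.shape[0]} labels for "
                    f"{len(self.spot_ids)} spots"
                )
            present = np.unique(vec)
            if not np.array_equal(present, np.arange(1, len(present) + 1)):
                raise ValueError(
                    f"resolution {label!r}: labels must be consecutive from 1, "
                    f"got {present.tolist()}"
                )

    @property
    def resolution_labels(self) -> list[str]:
        return [r.label for r in self.resolutions]

    def k_effective(self, label: str) -> int:
        return int(self.assignments[label].max())

    def spots_in_cluster(self, resolution_label: str, cluster: int) -> list[str]:
        vec = self.assignments[resolution_label]
        return [s for s, c in zip(self.spot_ids, vec) if c == cluster]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {label: self.assignments[label] for label in self.resolution_labels},
            index=list(self.spot_ids),
        ).rename_axis("spot")


def canonicalize_labels(raw: np.ndarray) -> np.ndarray:
    """Compact labels to 1..k and order clusters canonically.

    Clusters are numbered by descending size; ties broken by the smallest
    spot index they contain, so the numbering is stable under backend label
    permutations.
    """
    raw = np.asarray(raw)
    order: list = []
    for value in raw:
        if value not in order:
            order.append(value)
    stats = []
    for value in order:
        members = np.flatnonzero(raw == value)
        stats.append((-members.size, members[0], value))
    stats.sort(key=lambda t: (t[0], t[1]))
    mapping = {value: new + 1 for new, (_, _, value) in enumerate(stats)}
    return np.array([mapping[v] for v in raw], dtype=int)


def cluster_multi_resolution(
    matrix: ExpressionMatrix, specs: Sequence[ResolutionSpec]
) -> MultiResolutionClustering:
    """Cluster the matrix once per resolution spec.

    Each resolution is clustered independently and deterministically given
    its seed.  Empty clusters (possible with some backends) are removed and
    labels compacted; the effective k may therefore be below the target.
    """
    if not specs:
        raise ValueError("at least one resolution spec required")
    if not matrix.normalized:
        logger.warning("clustering a matrix whose normalized flag is False")
    assignments: dict[str, np.ndarray] = {}
    for spec in specs:
        if spec.k > matrix.n_spots:
            raise ValueError(
                f"resolution {spec.label!r}: k={spec.k} exceeds {matrix.n_spots} spots"
            )
        backend = get_backend(spec.method)
        raw = np.asarray(backend(matrix.values, spec.k, spec.seed))
        if raw.shape != (matrix.n_spots,):
            raise ValueError(
                f"backend {spec.method!r} returned shape {raw.shape}, "
                f"expected ({matrix.n_spots},)"
            )
        labels = canonicalize_labels(raw)
        k_eff = int(labels.max())
        if k_eff < spec.k:
            logger.info(
                "resolution %s: %d of %d clusters non-empty", spec.label, k_eff, spec.k
            )
        assignments[spec.label] = labels
    return MultiResolutionClustering(
        spot_ids=matrix.spot_ids, resolutions=tuple(specs), assignments=assignments
    )


def compute_centroids(matrix: ExpressionMatrix, assignment: np.ndarray) -> np.ndarray:
    """Mean expression vector per cluster; row k-1 is cluster k's centroid."""
    assignment = np.asarray(assignment, dtype=int)
    if assignment.shape != (matrix.n_spots,):
        raise ValueError(
            f"assignment length {assignment.shape[0]} != {matrix.n_spots} spots"
        )
    k = int(assignment.max())
    centroids = np.empty((k, matrix.n_genes))
    for c in range(1, k + 1):
        members = assignment == c
        if not members.any():
            raise ValueError(f"cluster {c} has no members")
        centroids[c - 1] = matrix.values[members].mean(axis=0)
    return centroids


def subcluster_select(
    matrix: ExpressionMatrix,
    mrc: MultiResolutionClustering,
    resolution_label: str,
    clusters: Iterable[int],
) -> ExpressionMatrix:
    """Restrict the matrix to spots of selected clusters for re-clustering.

    The returned sub-matrix keeps the original spot order; genes that become
    all-zero on the subset are dropped (logged) since they can no longer
    inform centroids or distances.  Feed the result to a fresh
    :func:`cluster_multi_resolution` run for iterative sub-clustering.
    """
    if resolution_label not in mrc.assignments:
        raise KeyError(
            f"unknown resolution {resolution_label!r}; have {mrc.resolution_labels}"
        )
    if tuple(mrc.spot_ids) != tuple(matrix.spot_ids):
        raise ValueError("matrix and clustering refer to different spot sets")
    clusters = set(int(c) for c in clusters)
    if not clusters:
        raise ValueError("empty cluster selection")
    available = set(range(1, mrc.k_effective(resolution_label) + 1))
    bad = clusters - available
    if bad:
        raise KeyError(
            f"resolution {resolution_label!r} has no clusters {sorted(bad)}; "
            f"available: {sorted(available)}"
        )
    vec = mrc.assignments[resolution_label]
    keep = [s for s, c in zip(matrix.spot_ids, vec) if c in clusters]
    if not keep:
        raise ValueError("selection matched no spots")
    sub = matrix.select_spots(keep)
    totals = sub.values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        dropped = [g for g, z in zip(sub.gene_names, zero) if z]
        logger.info("subcluster selection drops %d all-zero genes", len(dropped))
        from dataclasses import replace

        sub = replace(
            sub,
            values=sub.values[:, ~zero],
            gene_names=tuple(g for g, z in zip(sub.gene_names, zero) if not z),
        )
    return sub
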