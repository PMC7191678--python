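"""Reading, writing and normalizing spatial count matrices.

Spatial transcriptomics (ST) counts arrive as a spots × genes table, either
as a TSV with one header axis of gene names and one of spot identifiers, or
as a MatrixMarket triplet with ``.rows``/``.cols`` name sidecars.  Spot
identifiers in the classic ST dialect encode the array position directly,
``"<x>x<y>"`` (e.g. ``"7x15"`` is column 7, row 15, 1-based), so coordinates
can usually be recovered from the matrix alone.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

_SPOT_ID_RE = re.compile(r"^(\d+(?:\.\d+)?)x(\d+(?:\.\d+)?)$")


class SpotIdFormatError(ValueError):
    """Raised when a spot identifier does not match the ``<x>x<y>`` dialect."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A spots × genes expression matrix with row/column names.

    ``values`` holds raw counts or normalized expression depending on the
    ``normalized`` flag; rows follow ``spot_ids`` and columns ``gene_names``.
    """

    values: np.ndarray
    spot_ids: tuple[str, ...]
    gene_names: tuple[str, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spot_ids", tuple(str(s) for s in self.spot_ids))
        object.__setattr__(self, "gene_names", tuple(str(g) for g in self.gene_names))
        if values.ndim != 2:
            raise ValueError(f"expression matrix must be 2-D, got {values.ndim}-D")
        if len(self.spot_ids) != values.shape[0]:
            raise ValueError(
                f"{len(self.spot_ids)} spot IDs for {values.shape[0]} rows"
            )
        if len(self.gene_names) != values.shape[1]:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {values.shape[1]} columns"
            )
        if len(set(self.spot_ids)) != len(self.spot_ids):
            dupes = _duplicates(self.spot_ids)
            raise ValueError(f"duplicate spot IDs: {sorted(dupes)}")
        if len(set(self.gene_names)) != len(self.gene_names):
            dupes = _duplicates(self.gene_names)
            raise ValueError(f"duplicate gene names: {sorted(dupes)}")
        if np.isnan(values).any():
            raise ValueError("expression matrix contains NaN entries")
        if (values < 0).any():
            raise ValueError("expression matrix contains negative entries")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.spot_ids), columns=list(self.gene_names)
        )

    def select_spots(self, spot_ids: Iterable[str]) -> "ExpressionMatrix":
        """Row-subset by spot ID, preserving this matrix's spot order."""
        wanted = set(spot_ids)
        missing = wanted - set(self.spot_ids)
        if missing:
            raise KeyError(f"unknown spot IDs: {sorted(missing)}")
        mask = np.array([s in wanted for s in self.spot_ids])
        return replace(
            self,
            values=self.values[mask],
            spot_ids=tuple(s for s in self.spot_ids if s in wanted),
        )


@dataclass(frozen=True)
class SpotCoordinates:
    """Mapping of spot IDs to (x, y) array positions."""

    positions: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, tuple[float, float]] = {}
        for spot, (x, y) in dict(self.positions).items():
            x, y = float(x), float(y)
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite coordinate for spot {spot!r}")
            cleaned[str(spot)] = (x, y)
        object.__setattr__(self, "positions", cleaned)

    def __getitem__(self, spot: str) -> tuple[float, float]:
        return self.positions[spot]

    def __contains__(self, spot: str) -> bool:
        return spot in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    def require(self, spot_ids: Iterable[str]) -> None:
        missing = [s for s in spot_ids if s not in self.positions]
        if missing:
            raise KeyError(f"spots without coordinates: {missing[:10]}")


def parse_spot_id(spot_id: str) -> tuple[float, float]:
    """Parse an ``"<x>x<y>"`` spot identifier into (x, y) coordinates.

    >>> parse_spot_id("7x15")
    (7.0, 15.0)
    """
    m = _SPOT_ID_RE.match(str(spot_id))
    if m is None:
        raise SpotIdFormatError(
            f"spot ID {spot_id!r} does not match the '<x>x<y>' format"
        )
    return float(m.group(1)), float(m.group(2))


def format_spot_id(x: float, y: float) -> str:
    """Inverse of :func:`parse_spot_id`; integral coordinates print bare."""

    def fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else repr(float(v))

    return f"{fmt(x)}x{fmt(y)}"


def coordinates_from_ids(spot_ids: Iterable[str]) -> SpotCoordinates | None:
    """Derive coordinates when *all* spot IDs parse; None otherwise."""
    positions = {}
    for spot in spot_ids:
        try:
            positions[spot] = parse_spot_id(spot)
        except SpotIdFormatError:
            return None
    return SpotCoordinates(positions)


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for it in items:
        (dupes if it in seen else seen).add(it)
    return dupes


def _all_parse(labels: Iterable[str]) -> bool:
    labels = list(labels)
    return bool(labels) and all(_SPOT_ID_RE.match(str(x)) for x in labels)


def _drop_zero_genes(df: pd.DataFrame) -> pd.DataFrame:
    totals = df.to_numpy().sum(axis=0)
    zero = totals == 0
    if zero.any():
        dropped = [g for g, z in zip(df.columns, zero) if z]
        logger.warning(
            "dropping %d genes with zero total count: %s%s",
            len(dropped),
            dropped[:5],
            "..." if len(dropped) > 5 else "",
        )
        df = df.loc[:, ~zero]
    return df


def read_counts(
    path: str | Path, layout: str = "auto"
) -> tuple[ExpressionMatrix, SpotCoordinates | None]:
    """Read a count matrix from TSV or MatrixMarket.

    ``layout`` is one of ``"auto"`` (detect by trying to parse spot IDs on
    each header axis), ``"spots-by-genes"`` or ``"genes-by-spots"``.  The
    returned matrix is always oriented spots × genes.  Coordinates are
    derived from the IDs when every ID matches the ``<x>x<y>`` dialect.
    """
    path = Path(path)
    if layout not in ("auto", "spots-by-genes", "genes-by-spots"):
        raise ValueError(f"unknown layout {layout!r}")
    if path.suffix == ".mtx":
        df = _read_mtx(path)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.isna().any().any():
            raise ValueError(f"{path}: ragged rows or missing values")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    rows_are_spots = _orient(df, layout, path)
    if not rows_are_spots:
        df = df.T

    if df.index.duplicated().any():
        raise ValueError(
            f"{path}: duplicate spot IDs {sorted(set(df.index[df.index.duplicated()]))}"
        )
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")

    df = _drop_zero_genes(df)
    matrix = ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        spot_ids=tuple(df.index),
        gene_names=tuple(df.columns),
    )
    return matrix, coordinates_from_ids(matrix.spot_ids)


def _orient(df: pd.DataFrame, layout: str, path: Path) -> bool:
    """True if rows are spots, after auto-detection or the explicit flag."""
    if layout == "spots-by-genes":
        return True
    if layout == "genes-by-spots":
        return False
    rows_parse = _all_parse(df.index)
    cols_parse = _all_parse(df.columns)
    if rows_parse and not cols_parse:
        return True
    if cols_parse and not rows_parse:
        return False
    if rows_parse and cols_parse:
        logger.warning("%s: both axes look like spot IDs; assuming rows are spots", path)
        return True
    logger.warning("%s: no axis parses as spot IDs; assuming rows are spots", path)
    return True


def _read_mtx(path: Path) -> pd.DataFrame:
    rows_file = path.with_suffix(".rows")
    cols_file = path.with_suffix(".cols")
    for sidecar in (rows_file, cols_file):
        if not sidecar.exists():
            raise FileNotFoundError(f"missing MatrixMarket sidecar {sidecar}")
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    row_names = rows_file.read_text().split()
    col_names = cols_file.read_text().split()
    if len(row_names) != mat.shape[0] or len(col_names) != mat.shape[1]:
        raise ValueError(
            f"{path}: sidecar name counts ({len(row_names)}, {len(col_names)}) "
            f"do not match matrix shape {mat.shape}"
        )
    return pd.DataFrame(np.asarray(mat, dtype=float), index=row_names, columns=col_names)


def write_counts(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as spots × genes TSV (header field ``gene``)."""
    path = Path(path)
    df = matrix.to_dataframe()
    df.index.name = "spot"
    df.to_csv(path, sep="\t")


def read_coordinates(path: str | Path) -> SpotCoordinates:
    """Read a coordinates TSV with columns ``spot``, ``x``, ``y``."""
    df = pd.read_csv(path, sep="\t")
    required = {"spot", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: coordinate table needs columns {sorted(required)}")
    return SpotCoordinates(
        {str(r.spot): (float(r.x), float(r.y)) for r in df.itertuples()}
    )


def write_coordinates(coords: SpotCoordinates, path: str | Path) -> None:
    rows = [
        {"spot": s, "x": x, "y": y} for s, (x, y) in sorted(coords.positions.items())
    ]
    pd.DataFrame(rows, columns=["spot", "x", "y"]).to_csv(path, sep="\t", index=False)


def normalize_log(matrix: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize each spot to ``scale`` total, then log1p.

    Basic plumbing in the style of standard single-cell log-normalization;
    each spot's counts are rescaled to a common total before the log
    transform so that sequencing depth differences do not dominate distances.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    totals = matrix.values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        bad = [s for s, z in zip(matrix.spot_ids, zero) if z]
        raise ValueError(f"spots with zero total count: {bad}")
    values = np.log1p(matrix.values / totals[:, None] * scale)
    return replace(matrix, values=values, normalized=True)
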