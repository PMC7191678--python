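"""Synthetic spatial tissues with known domain structure.

Real ST sections contain contiguous anatomical regions — and often nested
structure, like two ventricles inside a shared myocardial wall, or a thin
peripheral rim.  The generator emulates exactly that geometry on a W × H
rectangular spot array: axis-aligned rectangular domains grouped into
superdomains (vertical strips split horizontally into subdomains), plus an
optional peripheral rim domain of configurable width.  Each domain owns a
block of marker genes whose negative-binomial mean is up-weighted by a
multiplicative effect size; everything else draws from a shared baseline.

Counts are NB(mean, dispersion) with variance mean + dispersion * mean^2 and
a dispersion shared across genes — enough structure to exercise
normalization, clustering, cluster-graph ancestry and pie gradients, without
claiming transcriptome realism (no library-size gradients, batch effects or
zero inflation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SpotCoordinates, format_spot_id

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TissueParams:
    """Generator settings for a synthetic tissue."""

    width: int = 20
    height: int = 20
    n_domains: int = 4
    n_superdomains: int = 2
    n_genes: int = 100
    markers_per_domain: int = 10
    marker_effect: float = 8.0  # multiplicative mean up-weighting for markers
    dispersion: float = 0.1  # var = mu + dispersion * mu^2
    baseline_mean: float = 5.0
    rim_width: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")
        if self.n_domains < 1:
            raise ValueError("need at least one domain")
        if self.n_superdomains < 1 or self.n_domains % self.n_superdomains:
            raise ValueError(
                f"n_domains={self.n_domains} must be a positive multiple of "
                f"n_superdomains={self.n_superdomains}"
            )
        if self.width * self.height < self.n_domains:
            raise ValueError("grid too small for the requested domain count")
        n_marker_genes = self.markers_per_domain * (
            self.total_domains + (self.n_superdomains if self.n_superdomains > 1 else 0)
        )
        if n_marker_genes > self.n_genes:
            raise ValueError(
                f"{n_marker_genes} marker genes exceed n_genes={self.n_genes}"
            )
        if self.dispersion < 0 or self.baseline_mean <= 0 or self.marker_effect <= 0:
            raise ValueError("dispersion >= 0 and positive means/effect required")
        if self.rim_width < 0:
            raise ValueError("rim_width must be nonnegative")
        if 2 * self.rim_width >= min(self.width, self.height):
            if self.rim_width > 0:
                raise ValueError(
                    f"rim_width={self.rim_width} leaves no interior on a "
                    f"{self.width}x{self.height} grid"
                )

    @property
    def total_domains(self) -> int:
        """Rectangular domains plus the rim domain when enabled."""
        return self.n_domains + (1 if self.rim_width > 0 else 0)

    @property
    def rim_domain(self) -> int | None:
        return self.n_domains + 1 if self.rim_width > 0 else None


@dataclass(frozen=True)
class SyntheticTissue:
    """Generated counts, coordinates and ground-truth labels."""

    matrix: ExpressionMatrix
    coords: SpotCoordinates
    domain_labels: np.ndarray  # per-spot, 1..total_domains
    superdomain_labels: np.ndarray  # deterministic function of domain
    params: TissueParams
    boundary_mask: np.ndarray | None = None  # set by mixed_boundary_tissue

    def truth_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spot": list(self.matrix.spot_ids),
                "domain": self.domain_labels,
                "superdomain": self.superdomain_labels,
            }
        )


def _domain_grid(params: TissueParams) -> np.ndarray:
    """Per-spot domain labels on the (height, width) grid.

    Superdomains are vertical strips; each strip is split horizontally into
    its subdomains, so sibling subdomains share a superdomain boundary-free
    column range.  The rim, when present, overwrites the outer ring.
    """
    w, h = params.width, params.height
    sub_per_super = params.n_domains // params.n_superdomains
    col_edges = np.linspace(0, w, params.n_superdomains + 1).round().astype(int)
    row_edges = np.linspace(0, h, sub_per_super + 1).round().astype(int)
    grid = np.zeros((h, w), dtype=int)
    for sd in range(params.n_superdomains):
        for sub in range(sub_per_super):
            domain = sd * sub_per_super + sub + 1
            grid[
                row_edges[sub] : row_edges[sub + 1],
                col_edges[sd] : col_edges[sd + 1],
            ] = domain
    if params.rim_width > 0:
        rw = params.rim_width
        rim = np.ones((h, w), dtype=bool)
        rim[rw : h - rw, rw : w - rw] = False
        grid[rim] = params.rim_domain
    if (grid == 0).any():
        raise ValueError("degenerate geometry: unassigned spots")
    for d in range(1, params.total_domains + 1):
        if not (grid == d).any():
            raise ValueError(f"degenerate geometry: domain {d} has no spots")
    return grid


def _superdomain_of(domains: np.ndarray, params: TissueParams) -> np.ndarray:
    """Map domain labels to superdomains; the rim is its own superdomain."""
    sub_per_super = params.n_domains // params.n_superdomains
    out = (domains - 1) // sub_per_super + 1
    if params.rim_domain is not None:
        out = np.where(domains == params.rim_domain, params.n_superdomains + 1, out)
    return out


def _mean_profiles(params: TissueParams) -> np.ndarray:
    """(total_domains, n_genes) NB means: baseline with marker blocks raised.

    Each domain owns a block of subdomain markers; with more than one
    superdomain, every rectangular superdomain additionally owns a shared
    marker block raised in *all* of its subdomains, so sibling subdomains
    are closer in expression space than non-siblings — the nesting that the
    cluster graph is supposed to reveal.  The rim domain (when present) has
    only its own markers.
    """
    means = np.full((params.total_domains, params.n_genes), params.baseline_mean)
    m = params.markers_per_domain
    for d in range(params.total_domains):
        means[d, d * m : (d + 1) * m] *= params.marker_effect
    if params.n_superdomains > 1:
        offset = params.total_domains * m
        sub_per_super = params.n_domains // params.n_superdomains
        for sd in range(params.n_superdomains):
            lo = offset + sd * m
            for sub in range(sub_per_super):
                means[sd * sub_per_super + sub, lo : lo + m] *= params.marker_effect
    return means


def _sample_counts(means: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(means)
    size = 1.0 / dispersion  # NB with var = mu + dispersion * mu^2
    p = size / (size + means)
    return rng.negative_binomial(size, p)


def _assemble(
    params: TissueParams, grid: np.ndarray, spot_means: np.ndarray, rng: np.random.Generator
) -> SyntheticTissue:
    h, w = grid.shape
    counts = _sample_counts(spot_means, params.dispersion, rng)
    spot_ids = []
    positions = {}
    for row in range(h):
        for col in range(w):
            sid = format_spot_id(col + 1, row + 1)
            spot_ids.append(sid)
            positions[sid] = (col + 1.0, row + 1.0)
    domains = grid.reshape(-1)
    matrix = ExpressionMatrix(
        values=counts.astype(float),
        spot_ids=tuple(spot_ids),
        gene_names=tuple(f"gene_{i + 1}" for i in range(params.n_genes)),
    )
    return SyntheticTissue(
        matrix=matrix,
        coords=SpotCoordinates(positions),
        domain_labels=domains,
        superdomain_labels=_superdomain_of(domains, params),
        params=params,
    )


def generate_tissue(params: TissueParams = TissueParams()) -> SyntheticTissue:
    """Sample a tissue with pure per-domain expression profiles.

    Deterministic given ``params.seed``.  With ``marker_effect == 1`` the
    domain labels carry no expression signal (a null tissue).
    """
    rng = np.random.default_rng(params.seed)
    grid = _domain_grid(params)
    means = _mean_profiles(params)
    spot_means = means[grid.reshape(-1) - 1]
    return _assemble(params, grid, spot_means, rng)


def mixed_boundary_tissue(
    params: TissueParams = TissueParams(), blend_width: int = 1
) -> SyntheticTissue:
    """Tissue whose boundary spots mix the two adjacent domains' profiles.

    Spots within ``blend_width`` (Chebyshev distance) of a spot from another
    domain draw counts from a 50/50 mixture of their own domain's mean
    profile and the nearest other domain's; spots on such transitions should
    show visibly split pies.  The returned ``boundary_mask`` marks the
    blended spots.
    """
    if blend_width < 1:
        raise ValueError("blend_width must be >= 1")
    rng = np.random.default_rng(params.seed)
    grid = _domain_grid(params)
    h, w = grid.shape
    means = _mean_profiles(params)
    flat = grid.reshape(-1)
    spot_means = means[flat - 1].astype(float)
    boundary = np.zeros(h * w, dtype=bool)
    rows, cols = np.divmod(np.arange(h * w), w)
    for i in range(h * w):
        r, c = rows[i], cols[i]
        own = flat[i]
        r0, r1 = max(0, r - blend_width), min(h, r + blend_width + 1)
        c0, c1 = max(0, c - blend_width), min(w, c + blend_width + 1)
        window = grid[r0:r1, c0:c1]
        others = window[window != own]
        if others.size:
            # nearest foreign domain: the most frequent one inside the window
            vals, cnts = np.unique(others, return_counts=True)
            other = int(vals[np.argmax(cnts)])
            spot_means[i] = 0.5 * (means[own - 1] + means[other - 1])
            boundary[i] = True
    tissue = _assemble(params, grid, spot_means, rng)
    return replace(tissue, boundary_mask=boundary)


def write_tissue(tissue: SyntheticTissue, counts_path: str | Path, truth_path: str | Path) -> None:
    """Write counts in the readable TSV dialect plus a ground-truth table."""
    from .io import write_counts

    write_counts(tissue.matrix, counts_path)
    tissue.truth_dataframe().to_csv(truth_path, sep="\t", index=False)
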