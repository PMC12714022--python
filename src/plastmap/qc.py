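"""Spot- and cell-level quality control and Gaussian smoothing.

Bead arrays pick up "smears": low-count off-tissue signal from stray
transcripts. A smear spot is recognizable by its combination of low total
counts and spatial isolation, so the filter removes spots that are BOTH
low-count (total counts below ``min_counts``) and sparsely neighbored
(at most ``min_neighbors`` other spots within ``radius``). In-tissue spots
on a dense bead lattice always clear the neighbor threshold and survive
regardless of depth.

Gaussian smoothing denoises per-spot expression by kernel-averaging each
spot with its spatial neighborhood. Spots whose truncated kernel covers
fewer than ``min_spots_under_gaussian`` spots (the spot itself included)
carry too little support and are excluded from the smoothed output.

Neighbor counting excludes the spot itself; the kernel-coverage count
includes it (a spot always covers itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = [
    "SmoothingParams",
    "SmearFilterResult",
    "SmoothingResult",
    "count_neighbors",
    "filter_smears",
    "gaussian_smooth",
    "filter_cells",
]


@dataclass(frozen=True)
class SmoothingParams:
    """Gaussian-kernel smoothing parameters.

    gaussian_sd
        Kernel standard deviation in µm. Default 46.37 µm (roughly 2.3 bead
        spacings on a 20 µm lattice).
    min_spots_under_gaussian
        Minimum number of spots (self included) the truncated kernel must
        cover for a spot to be smoothed rather than excluded.
    truncation_radius
        Kernel support in µm; defaults to 3 x gaussian_sd.
    """

    gaussian_sd: float = 46.37
    min_spots_under_gaussian: int = 10
    truncation_radius: float | None = None

    def __post_init__(self) -> None:
        if self.gaussian_sd <= 0:
            raise ValueError("gaussian_sd must be positive")
        if self.min_spots_under_gaussian < 1:
            raise ValueError("min_spots_under_gaussian must be >= 1")
        if self.truncation_radius is None:
            object.__setattr__(self, "truncation_radius", 3.0 * self.gaussian_sd)
        if self.truncation_radius < self.gaussian_sd:
            raise ValueError("truncation_radius must be >= gaussian_sd")


@dataclass
class SmearFilterResult:
    retained: np.ndarray  # boolean mask over input spots
    report: pd.DataFrame = field(repr=False)  # removed spots with reasons


@dataclass
class SmoothingResult:
    smoothed: np.ndarray  # (n_included, n_genes)
    included: np.ndarray  # integer indices of smoothed spots
    excluded_ids: list  # spot ids (or indices) excluded for thin coverage


def _check_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError(f"coordinates must be (n_spots, 2); got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates contain non-finite values")
    return coords


def count_neighbors(coords: np.ndarray, radius: float) -> np.ndarray:
    """Number of other spots within ``radius`` µm of each spot.

    Uses a k-d tree, so no dense pairwise matrix is formed; the count is
    symmetric (i neighbors j iff j neighbors i) and excludes the spot
    itself.
    """
    coords = _check_coords(coords)
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(coords)
    counts = tree.query_ball_point(coords, r=radius, return_length=True)
    return np.asarray(counts, dtype=int) - 1  # query_ball_point includes self


def filter_smears(
    coords: np.ndarray,
    total_counts: np.ndarray,
    spot_ids: np.ndarray | None = None,
    min_counts: int = 100,
    min_neighbors: int = 15,
    radius: float = 100.0,
    literal_polarity: bool = False,
) -> SmearFilterResult:
    """Remove smear spots: low total counts AND few spatial neighbors.

    A spot is removed iff ``total_counts < min_counts`` and its neighbor
    count within ``radius`` is ``<= min_neighbors``; everything else is
    retained. ``literal_polarity=True`` selects the opposite reading
    (retain only low-count, well-neighbored spots); it exists for
    sensitivity analysis and is not the default.
    """
    if min(min_counts, min_neighbors) < 0 or radius <= 0:
        raise ValueError("thresholds must be nonnegative and radius positive")
    coords = _check_coords(np.atleast_2d(coords)) if len(coords) else np.empty((0, 2))
    total_counts = np.asarray(total_counts)
    if spot_ids is None:
        spot_ids = np.arange(len(total_counts))
    spot_ids = np.asarray(spot_ids)
    if len(coords) == 0:
        warnings.warn("filter_smears called on an empty spot table")
        return SmearFilterResult(
            retained=np.zeros(0, dtype=bool),
            report=pd.DataFrame(columns=["spot_id", "total_counts", "n_neighbors", "reason"]),
        )
    neighbors = count_neighbors(coords, radius)
    low = total_counts < min_counts
    sparse_nb = neighbors <= min_neighbors
    if literal_polarity:
        retained = low & (neighbors > min_neighbors)
    else:
        retained = ~(low & sparse_nb)
    removed = ~retained
    report = pd.DataFrame(
        {
            "spot_id": spot_ids[removed],
            "total_counts": total_counts[removed],
            "n_neighbors": neighbors[removed],
            "reason": "low_counts_and_sparse" if not literal_polarity else "literal_rule",
        }
    )
    return SmearFilterResult(retained=retained, report=report)


def gaussian_smooth(
    coords: np.ndarray,
    values: np.ndarray | sp.spmatrix,
    params: SmoothingParams | None = None,
    spot_ids: np.ndarray | None = None,
) -> SmoothingResult:
    """Gaussian-kernel smoothing of per-spot values.

    For each spot ``s`` covered by at least ``min_spots_under_gaussian``
    spots (itself included) within ``truncation_radius``, the smoothed
    value is the convex combination ``sum_j w_sj x_j`` with
    ``w_sj ∝ exp(-d_sj^2 / (2 sd^2))`` over covered spots and
    ``sum_j w_sj = 1``. Under-covered spots are excluded and listed.

    ``values`` is typically the per-spot depth-normalized expression
    matrix (spots x genes); raw counts should be kept alongside for
    methods that need them.
    """
    params = params or SmoothingParams()
    coords = _check_coords(coords)
    n = coords.shape[0]
    X = values.toarray() if sp.issparse(values) else np.asarray(values, dtype=float)
    X = np.atleast_2d(X.T).T if X.ndim == 1 else X
    if X.shape[0] != n:
        raise ValueError("values must have one row per spot")
    if spot_ids is None:
        spot_ids = np.arange(n)
    spot_ids = np.asarray(spot_ids)

    tree = cKDTree(coords)
    neighborhoods = tree.query_ball_point(coords, r=params.truncation_radius)
    included, excluded_ids = [], []
    rows, cols, weights = [], [], []
    inv_two_sd2 = 1.0 / (2.0 * params.gaussian_sd**2)
    for i, nb in enumerate(neighborhoods):
        if len(nb) < params.min_spots_under_gaussian:
            excluded_ids.append(spot_ids[i])
            continue
        nb = np.asarray(nb)
        d2 = np.sum((coords[nb] - coords[i]) ** 2, axis=1)
        w = np.exp(-d2 * inv_two_sd2)
        w /= w.sum()
        rows.extend([len(included)] * len(nb))
        cols.extend(nb.tolist())
        weights.extend(w.tolist())
        included.append(i)
    W = sp.csr_matrix((weights, (rows, cols)), shape=(len(included), n))
    smoothed = W @ X
    return SmoothingResult(
        smoothed=np.asarray(smoothed),
        included=np.asarray(included, dtype=int),
        excluded_ids=excluded_ids,
    )


def filter_cells(
    metrics: pd.DataFrame,
    max_doublet_score: float = 0.25,
    min_genes: int = 300,
    max_genes: int = 10_000,
    max_mito_fraction: float = 0.10,
) -> tuple[pd.Index, pd.DataFrame]:
    """Single-cell QC: drop doublets, outlier gene counts, high-mito cells.

    ``metrics`` is indexed by cell id with columns ``doublet_score``,
    ``n_genes`` and ``mito_fraction``. A cell is removed iff any criterion
    triggers: doublet score above ``max_doublet_score``, fewer than
    ``min_genes`` or more than ``max_genes`` genes detected, or
    mitochondrial fraction above ``max_mito_fraction``. Cells with a
    missing metric are flagged and removed, never silently kept.

    Returns the retained cell index and a removal report.
    """
    required = ["doublet_score", "n_genes", "mito_fraction"]
    missing_cols = [c for c in required if c not in metrics.columns]
    if missing_cols:
        raise ValueError(f"metrics table lacks columns: {missing_cols}")
    m = metrics[required]
    has_nan = m.isna().any(axis=1)
    doublet = m["doublet_score"] > max_doublet_score
    few_genes = m["n_genes"] < min_genes
    many_genes = m["n_genes"] > max_genes
    high_mito = m["mito_fraction"] > max_mito_fraction
    removed = has_nan | doublet | few_genes | many_genes | high_mito

    reasons = pd.DataFrame(
        {
            "missing_metric": has_nan,
            "doublet": doublet.fillna(False),
            "too_few_genes": few_genes.fillna(False),
            "too_many_genes": many_genes.fillna(False),
            "high_mito": high_mito.fillna(False),
        }
    )
    report = reasons[removed].copy()
    return metrics.index[~removed], report
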