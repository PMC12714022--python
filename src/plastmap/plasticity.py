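"""Cell-state plasticity scoring from velocity fields and transition graphs.

The plasticity score quantifies how actively a cell is transitioning
between transcriptional states. It combines two ingredients derived from an
RNA-velocity analysis:

* the speed of change — the L2 norm of each cell's velocity vector in the
  2-D visualization embedding, min-max scaled to [0, 1];
* the directionality of change — a net-flow score from the directed
  cell-to-cell transition-probability graph: the mean of a cell's nonzero
  outgoing probabilities minus the mean of its nonzero incoming ones
  (positive = source state, negative = sink), again min-max scaled.

The per-cell score is the product of the two scaled quantities. Cell-type
scores are the per-type means of cell scores, min-max scaled once more
across types. Spot-level scores project the type scores onto space by
multiplying each with the type's deconvolved proportion in the spot, and
summing over a chosen type subset when a single regional value is wanted.

Degenerate min-max scaling (all values equal) maps everything to 0: with no
variation there is no evidence of differential plasticity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ScoredVector",
    "minmax_scale",
    "velocity_magnitude",
    "net_flow",
    "cell_plasticity",
    "celltype_plasticity",
    "spot_plasticity",
]


@dataclass(frozen=True)
class ScoredVector:
    """A per-cell quantity before and after min-max scaling."""

    raw: np.ndarray
    scaled: np.ndarray

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.raw)


def minmax_scale(x: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] as (x - min) / (max - min); constant input -> zeros."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def velocity_magnitude(velocities: np.ndarray) -> ScoredVector:
    """Per-cell velocity speed: L2 norm in the 2-D embedding, min-max scaled.

    Parameters
    ----------
    velocities
        (n_cells, 2) array of velocity vectors projected into the
        visualization embedding. Higher norms mark more dynamic states.
    """
    v = np.asarray(velocities, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError(
            f"velocities must be (n_cells, 2); got shape {v.shape}. "
            "Higher-dimensional velocities must be projected upstream."
        )
    if v.shape[0] < 1:
        raise ValueError("need at least one cell")
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity vectors contain non-finite values")
    raw = np.linalg.norm(v, axis=1)
    return ScoredVector(raw=raw, scaled=minmax_scale(raw))


def net_flow(transition: np.ndarray | sp.spmatrix) -> ScoredVector:
    """Per-cell net transition flow, min-max scaled to [0, 1].

    For cell ``c`` the outflow mean is the mean of the *nonzero* entries of
    row ``c`` and the inflow mean the mean of the nonzero entries of column
    ``c`` (zero entries are excluded so unconnected pairs do not bias the
    means; a cell with no nonzero entries gets mean 0). Self-transitions on
    the diagonal carry no state-transition information and are ignored.

    raw net flow = outflow_mean - inflow_mean; sources are positive, sinks
    negative. The returned ``scaled`` vector is the min-max-scaled raw one.
    """
    T = sp.csr_matrix(transition, dtype=float)
    n, m = T.shape
    if n != m:
        raise ValueError(f"transition matrix must be square; got {T.shape}")
    if T.nnz and T.data.min() < 0:
        raise ValueError(
            "negative transition probabilities are not allowed; split or "
            "threshold a signed velocity graph upstream"
        )
    T = T.tolil()
    T.setdiag(0)
    T = T.tocsr()
    T.eliminate_zeros()

    row_sum = np.asarray(T.sum(axis=1)).ravel()
    row_nnz = np.diff(T.indptr)
    col = T.tocsc()
    col_sum = np.asarray(col.sum(axis=0)).ravel()
    col_nnz = np.diff(col.indptr)

    with np.errstate(invalid="ignore"):
        out_mean = np.where(row_nnz > 0, row_sum / np.maximum(row_nnz, 1), 0.0)
        in_mean = np.where(col_nnz > 0, col_sum / np.maximum(col_nnz, 1), 0.0)
    raw = out_mean - in_mean
    return ScoredVector(raw=raw, scaled=minmax_scale(raw))


def cell_plasticity(scaled_magnitude: np.ndarray, scaled_flow: np.ndarray) -> np.ndarray:
    """Per-cell plasticity: product of scaled speed and scaled net flow."""
    mag = np.asarray(scaled_magnitude, dtype=float)
    flow = np.asarray(scaled_flow, dtype=float)
    if mag.shape != flow.shape:
        raise ValueError(
            f"length mismatch: {mag.shape} magnitudes vs {flow.shape} flows"
        )
    for name, x in (("magnitude", mag), ("flow", flow)):
        if x.size and (x.min() < 0 or x.max() > 1):
            raise ValueError(f"scaled {name} values must lie in [0, 1]")
    return mag * flow


def celltype_plasticity(
    cell_scores: np.ndarray, annotations: pd.Series | np.ndarray
) -> pd.Series:
    """Aggregate cell scores into a min-max-scaled per-type score.

    The per-type score is the mean of the cell-level plasticity scores of
    that type, rescaled across types so the most plastic type scores 1 and
    the most stable 0 (all-equal means -> all zeros).
    """
    scores = np.asarray(cell_scores, dtype=float)
    ann = pd.Series(np.asarray(annotations), name="cell_type")
    if len(ann) != len(scores):
        raise ValueError("every cell needs an annotation")
    if ann.isna().any():
        missing = int(ann.isna().sum())
        raise ValueError(f"{missing} cells lack a cell-type annotation")
    means = pd.Series(scores).groupby(ann.values).mean()
    means = means.sort_index()
    return pd.Series(minmax_scale(means.to_numpy()), index=means.index, name="plasticity")


def spot_plasticity(
    proportions: pd.DataFrame,
    type_scores: pd.Series,
    include_types: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Project type-level plasticity onto spots by proportion weighting.

    Per spot ``s`` and type ``C``: ``score[C, s] = type_score[C] *
    proportion[C, s]``. The per-spot summary is the sum over
    ``include_types`` (default: every scored type present), *without*
    renormalizing proportions over the subset — a spot only 40% covered by
    the subset can score at most 0.4 even if every subtype is maximally
    plastic.

    Returns
    -------
    per_type
        DataFrame (spots x included types) of per-type spot scores.
    summed
        Series of per-spot summed scores over the included types.
    """
    if include_types is None:
        include_types = [t for t in proportions.columns if t in type_scores.index]
    unknown = [t for t in include_types if t not in type_scores.index]
    if unknown:
        raise ValueError(f"no plasticity score for types: {unknown}")
    missing = [t for t in include_types if t not in proportions.columns]
    if missing:
        raise ValueError(f"proportion matrix lacks types: {missing}")
    sub = proportions[include_types]
    per_type = sub * type_scores[include_types]
    summed = per_type.sum(axis=1)
    summed.name = "spot_plasticity"
    return per_type, summed
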