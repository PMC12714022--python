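"""Transmural layer-position analysis of annotated ventricular walls.

Given a region mask — the member spots of a ventricular wall plus four
single-spot-layer boundaries (inner = endocardial, outer = epicardial,
upper and bottom along the chamber's long axis) — each spot gets a
normalized transmural coordinate

    layer_position = d_outer / (d_outer + d_inner)

where ``d_outer``/``d_inner`` are Euclidean distances to the nearest outer
and inner boundary spots: 0 on the outer boundary, 1 on the inner. An
analogous axial coordinate runs 0 (upper) to 1 (bottom).

Cell-type distributions across the wall are profiled by binning the layer
position (default 10 bins) within axial segments (default 5), computing
per-bin dominant-type fractions per segment, and summarizing each bin by
the unweighted mean across segments with a 95% CI from the 2.5th/97.5th
percentiles (linear interpolation between order statistics). Empty bins
contribute nothing to a bin's mean or CI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "RegionMask",
    "LayerGeometry",
    "LayerProfile",
    "layer_position",
    "axial_position",
    "binned_profile",
]


@dataclass
class RegionMask:
    """An annotated spot region with boundary spot lists.

    Boundary lists are "single layers" of spot ids on the region's inner,
    outer, upper and bottom edges; they must be subsets of ``members`` and
    inner/outer must be disjoint. ``provenance`` records whether the mask
    came from manual annotation or a synthetic geometry.
    """

    name: str
    members: list
    inner: list
    outer: list
    upper: list = field(default_factory=list)
    bottom: list = field(default_factory=list)
    provenance: str = "manual"

    def __post_init__(self) -> None:
        members = set(self.members)
        for label in ("inner", "outer", "upper", "bottom"):
            ids = getattr(self, label)
            if label in ("inner", "outer") and not ids:
                raise ValueError(f"{label} boundary of region {self.name!r} is empty")
            stray = set(ids) - members
            if stray:
                raise ValueError(
                    f"{label} boundary of {self.name!r} contains non-member spots: "
                    f"{sorted(stray)[:5]}"
                )
        if set(self.inner) & set(self.outer):
            raise ValueError("inner and outer boundaries overlap")

    def to_json(self, path: str | Path) -> None:
        payload = {
            self.name: {
                "members": list(self.members),
                "inner": list(self.inner),
                "outer": list(self.outer),
                "upper": list(self.upper),
                "bottom": list(self.bottom),
                "provenance": self.provenance,
            }
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path, name: str | None = None) -> "RegionMask":
        data = json.loads(Path(path).read_text())
        if name is None:
            name = next(iter(data))
        d = data[name]
        return cls(name=name, **{k: d[k] for k in ("members", "inner", "outer", "upper", "bottom")},
                   provenance=d.get("provenance", "manual"))


@dataclass
class LayerGeometry:
    dist_outer: np.ndarray
    dist_inner: np.ndarray
    position: np.ndarray  # 0 = outer boundary, 1 = inner


def layer_position(
    member_coords: np.ndarray,
    inner_coords: np.ndarray,
    outer_coords: np.ndarray,
) -> LayerGeometry:
    """Normalized outer->inner position of each member spot.

    ``position = d_outer / (d_outer + d_inner)`` with nearest-boundary
    Euclidean distances; exactly 0 on the outer boundary and 1 on the
    inner. A spot at zero distance to both boundaries is geometrically
    impossible for disjoint single-layer boundaries and is rejected.
    """
    members = np.asarray(member_coords, dtype=float)
    inner = np.atleast_2d(np.asarray(inner_coords, dtype=float))
    outer = np.atleast_2d(np.asarray(outer_coords, dtype=float))
    if members.size == 0:
        raise ValueError("member spot set is empty")
    if inner.size == 0 or outer.size == 0:
        raise ValueError("boundary spot lists must be non-empty")
    d_inner, _ = cKDTree(inner).query(members)
    d_outer, _ = cKDTree(outer).query(members)
    both_zero = (d_inner == 0) & (d_outer == 0)
    if np.any(both_zero):
        raise ValueError(
            f"{int(both_zero.sum())} spot(s) lie on both boundaries; "
            "inner and outer boundaries must be disjoint"
        )
    position = d_outer / (d_outer + d_inner)
    return LayerGeometry(dist_outer=d_outer, dist_inner=d_inner, position=position)


def axial_position(
    member_coords: np.ndarray,
    upper_coords: np.ndarray,
    bottom_coords: np.ndarray,
) -> LayerGeometry:
    """Normalized upper->bottom position; same contract as layer_position
    with upper in the role of outer (position 0) and bottom of inner (1)."""
    return layer_position(member_coords, inner_coords=bottom_coords, outer_coords=upper_coords)


@dataclass
class LayerProfile:
    per_segment: pd.DataFrame  # columns: segment, layer_bin, cell_type, proportion
    summary: pd.DataFrame  # columns: layer_bin, cell_type, mean, ci_low, ci_high
    n_layer_bins: int
    n_axial_bins: int


def _bin_index(positions: np.ndarray, n_bins: int) -> np.ndarray:
    # equal-width bins on [0, 1], half-open [a, b) except the last, closed at 1
    idx = np.floor(np.asarray(positions) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def binned_profile(
    layer_positions: np.ndarray,
    axial_positions: np.ndarray,
    dominant_types: np.ndarray | pd.Series,
    n_layer_bins: int = 10,
    n_axial_bins: int = 5,
) -> LayerProfile:
    """Binned dominant-type fractions across the wall, with percentile CIs.

    Within each axial segment, the fraction of each dominant type per
    layer bin is (# spots of that type in the bin) / (# spots in the bin);
    within a non-empty bin the fractions over all types sum to 1. The
    summary gives, per (layer bin, type), the unweighted mean across
    segments whose bin is non-empty and the 2.5th/97.5th percentile CI of
    those per-segment fractions (linear interpolation).
    """
    if n_layer_bins < 1 or n_axial_bins < 1:
        raise ValueError("bin counts must be >= 1")
    layer_positions = np.asarray(layer_positions, dtype=float)
    axial_positions = np.asarray(axial_positions, dtype=float)
    types = pd.Series(np.asarray(dominant_types), name="cell_type")
    if not (len(layer_positions) == len(axial_positions) == len(types)):
        raise ValueError("positions and dominant types must align per spot")

    df = pd.DataFrame(
        {
            "segment": _bin_index(axial_positions, n_axial_bins),
            "layer_bin": _bin_index(layer_positions, n_layer_bins),
            "cell_type": types.values,
        }
    )
    all_types = sorted(types.unique())
    records = []
    for (seg, lb), grp in df.groupby(["segment", "layer_bin"]):
        n_tot = len(grp)
        counts = grp["cell_type"].value_counts()
        for t in all_types:
            records.append(
                {
                    "segment": seg,
                    "layer_bin": lb,
                    "cell_type": t,
                    "proportion": counts.get(t, 0) / n_tot,
                }
            )
    per_segment = pd.DataFrame.from_records(records)

    rows = []
    for (lb, t), grp in per_segment.groupby(["layer_bin", "cell_type"]):
        vals = grp["proportion"].to_numpy()
        lo, hi = np.percentile(vals, [2.5, 97.5], method="linear")
        rows.append(
            {"layer_bin": lb, "cell_type": t, "mean": vals.mean(), "ci_low": lo, "ci_high": hi}
        )
    summary = pd.DataFrame(rows)
    return LayerProfile(
        per_segment=per_segment,
        summary=summary,
        n_layer_bins=n_layer_bins,
        n_axial_bins=n_axial_bins,
    )
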