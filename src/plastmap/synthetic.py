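"""Synthetic spatial and single-cell inputs with planted ground truth.

The generators emulate the statistical structure of a high-resolution
bead-array spatial-transcriptomics study of the developing heart:

* :func:`gen_spots` — a jittered bead lattice tiling an annular (ventricle
  wall) or wedge (valve leaflet) footprint, negative-binomial bead depths,
  a configurable fraction of low-count off-tissue smear spots, and
  analytically derived single-layer boundary rings (inner/outer,
  upper/bottom);
* :func:`gen_proportion_field` — deconvolution-style per-spot cell-type
  abundances driven by per-type logistic profiles over the true transmural
  (radial) fraction, with truncated Gaussian noise;
* :func:`gen_transition_chain` — a velocity-style directed transition
  graph over a planted immature -> mature cell-state chain, with matching
  2-D velocity vectors; the first stage is the planted source, the last
  the sink.

All generators are pure functions of their parameters and seed. Ground
truth (true radial/axial fractions, noise-free proportions, stages and
roles) is returned alongside so recovery can be tested downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .layers import RegionMask

__all__ = [
    "TissueGeometry",
    "GroundTruth",
    "SpotTable",
    "LogisticProfile",
    "ChainResult",
    "gen_spots",
    "gen_proportion_field",
    "gen_transition_chain",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class TissueGeometry:
    """Footprint of a synthetic tissue section.

    ``annulus`` models a ventricular wall: spots between ``r_inner`` and
    ``r_outer`` around ``center``, optionally restricted to the angular
    sector [theta_min, theta_max) so the wall has upper/bottom ends.
    ``wedge`` models a valve leaflet: a triangle with its tip at ``apex``
    widening to ``base_width`` at distance ``height`` below the apex.

    ``spot_spacing`` is the bead lattice pitch and ``jitter_sd`` the
    standard deviation of the positional jitter, both in µm.
    """

    shape_kind: str = "annulus"
    center: tuple[float, float] = (0.0, 0.0)
    r_inner: float = 300.0
    r_outer: float = 600.0
    theta_min: float = 0.0
    theta_max: float = TWO_PI
    apex: tuple[float, float] = (0.0, 0.0)
    base_width: float = 400.0
    height: float = 600.0
    spot_spacing: float = 20.0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.shape_kind not in ("annulus", "wedge"):
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if self.spot_spacing <= 0:
            raise ValueError("spot_spacing must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be nonnegative")
        if self.shape_kind == "annulus":
            if self.r_inner <= 0 or self.r_outer <= 0:
                raise ValueError("annulus radii must be positive")
            if self.r_inner >= self.r_outer:
                raise ValueError(
                    f"degenerate annulus: r_inner ({self.r_inner}) must be < "
                    f"r_outer ({self.r_outer})"
                )
            if not (0 <= self.theta_min < self.theta_max <= TWO_PI + 1e-12):
                raise ValueError("need 0 <= theta_min < theta_max <= 2*pi")
        else:
            if self.base_width <= 0 or self.height <= 0:
                raise ValueError("wedge base_width and height must be positive")


@dataclass
class GroundTruth:
    """Planted truth for recovery tests.

    ``spots`` is indexed by spot id with ``radial_fraction`` (0 = outer
    boundary, 1 = inner/lumen) and ``axial_fraction`` (0 = upper/tip,
    1 = bottom/base); smear spots carry NaN. ``type_proportions`` holds
    the noise-free per-spot proportions once a proportion field has been
    generated; ``cells`` and ``roles`` are filled by the chain generator.
    """

    spots: pd.DataFrame
    type_proportions: pd.DataFrame | None = None
    cells: pd.DataFrame | None = None
    roles: dict[str, str] = field(default_factory=dict)


@dataclass
class SpotTable:
    """Spatial spots: coordinates, sparse counts, metadata, boundary rings."""

    table: pd.DataFrame  # spot_id, x, y, total_counts, is_smear
    counts: sp.csr_matrix  # spots x genes
    genes: list[str]
    boundary_ids: dict[str, list[str]]  # inner/outer/upper/bottom rings
    metadata: dict

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy()

    @property
    def spot_ids(self) -> np.ndarray:
        return self.table["spot_id"].to_numpy()

    def region_mask(self, name: str = "tissue") -> RegionMask:
        """Boundary rings of the in-tissue spots as a RegionMask."""
        members = self.table.loc[~self.table["is_smear"], "spot_id"].tolist()
        return RegionMask(
            name=name,
            members=members,
            inner=self.boundary_ids["inner"],
            outer=self.boundary_ids["outer"],
            upper=self.boundary_ids["upper"],
            bottom=self.boundary_ids["bottom"],
            provenance="synthetic",
        )


def _annulus_fractions(geom: TissueGeometry, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    rel = xy - np.asarray(geom.center)
    r = np.hypot(rel[:, 0], rel[:, 1])
    theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), TWO_PI)
    inside = (r >= geom.r_inner) & (r <= geom.r_outer)
    inside &= (theta >= geom.theta_min) & (theta <= geom.theta_max)
    radial = (geom.r_outer - r) / (geom.r_outer - geom.r_inner)
    axial = (theta - geom.theta_min) / (geom.theta_max - geom.theta_min)
    return inside, radial, axial, r


def _wedge_local(geom: TissueGeometry, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax, ay = geom.apex
    t = ay - xy[:, 1]  # depth below the apex
    lateral = np.abs(xy[:, 0] - ax)
    halfwidth = 0.5 * geom.base_width * np.clip(t, 0, None) / geom.height
    inside = (t >= 0) & (t <= geom.height) & (lateral <= halfwidth)
    return inside, t, lateral


def gen_spots(
    geometry: TissueGeometry,
    mean_depth: float = 500.0,
    smear_fraction: float = 0.0,
    seed: int = 0,
    n_genes: int = 30,
    nb_dispersion: float = 2.0,
    qc_min_counts: int = 100,
    condition: str = "normal",
    day: int = 10,
) -> tuple[SpotTable, GroundTruth]:
    """Generate a jittered bead lattice over a tissue footprint.

    In-tissue spots get total counts from a negative binomial with mean
    ``mean_depth`` and dispersion ``nb_dispersion`` (clipped to >= 1),
    distributed over ``n_genes`` pseudo-genes by a fixed random gene
    weight vector. ``smear_fraction`` plants Binomial(n_tissue,
    smear_fraction) off-tissue smear spots in a halo 4-12 spacings outside
    the footprint with uniform counts in [1, qc_min_counts/2]. Boundary
    rings (single spot layers within one spacing of the exact geometric
    boundary) are emitted analytically. Deterministic given the seed.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not (0 <= smear_fraction < 1):
        raise ValueError("smear_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    s = geometry.spot_spacing

    if geometry.shape_kind == "annulus":
        cx, cy = geometry.center
        R = geometry.r_outer
        lo, hi = np.array([cx - R, cy - R]) - s, np.array([cx + R, cy + R]) + s
    else:
        ax, ay = geometry.apex
        lo = np.array([ax - geometry.base_width / 2, ay - geometry.height]) - s
        hi = np.array([ax + geometry.base_width / 2, ay]) + s

    gx = np.arange(lo[0], hi[0] + s, s)
    gy = np.arange(lo[1], hi[1] + s, s)
    xy = np.stack(np.meshgrid(gx, gy), axis=-1).reshape(-1, 2)
    if geometry.jitter_sd > 0:
        xy = xy + rng.normal(0.0, geometry.jitter_sd, size=xy.shape)

    if geometry.shape_kind == "annulus":
        inside, radial, axial, r = _annulus_fractions(geometry, xy)
        xy_in, radial, axial, r = xy[inside], radial[inside], axial[inside], r[inside]
        rel = xy_in - np.asarray(geometry.center)
        theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), TWO_PI)
        ring_inner = r <= geometry.r_inner + s
        ring_outer = (r >= geometry.r_outer - s) & ~ring_inner
        arc_from_upper = r * (theta - geometry.theta_min)
        arc_from_bottom = r * (geometry.theta_max - theta)
        ring_upper = arc_from_upper <= s
        ring_bottom = arc_from_bottom <= s
        centroid = np.asarray(geometry.center)
        halo_base = geometry.r_outer
    else:
        inside, t, lateral = _wedge_local(geometry, xy)
        xy_in, t, lateral = xy[inside], t[inside], lateral[inside]
        halfwidth = 0.5 * geometry.base_width * t / geometry.height
        axial = t / geometry.height
        with np.errstate(divide="ignore", invalid="ignore"):
            radial = np.where(halfwidth > 0, 1.0 - lateral / halfwidth, 1.0)
        ring_inner = lateral <= s / 2  # midline
        ring_outer = (halfwidth - lateral) <= s  # lateral free edges
        ring_outer &= ~ring_inner  # near the apex the two could meet
        ring_upper = t <= s  # leaflet tip
        ring_bottom = t >= geometry.height - s  # leaflet base
        centroid = np.array([geometry.apex[0], geometry.apex[1] - 2 * geometry.height / 3])
        halo_base = float(np.max(np.hypot(*(xy_in - centroid).T))) if len(xy_in) else geometry.height

    n_tissue = len(xy_in)
    if n_tissue == 0:
        raise ValueError("geometry contains no lattice spots; check its parameters")

    n_smear = int(rng.binomial(n_tissue, smear_fraction)) if smear_fraction > 0 else 0
    smear_r = rng.uniform(halo_base + 4 * s, halo_base + 12 * s, size=n_smear)
    smear_th = rng.uniform(0, TWO_PI, size=n_smear)
    xy_smear = centroid + np.stack(
        [smear_r * np.cos(smear_th), smear_r * np.sin(smear_th)], axis=-1
    )

    totals_tissue = np.maximum(
        rng.negative_binomial(
            nb_dispersion, nb_dispersion / (nb_dispersion + mean_depth), size=n_tissue
        ),
        1,
    )
    totals_smear = rng.integers(1, max(int(qc_min_counts / 2), 2), size=n_smear, endpoint=True)

    ids_tissue = np.array([f"spot_{i:05d}" for i in range(n_tissue)])
    ids_smear = np.array([f"smear_{i:05d}" for i in range(n_smear)])
    table = pd.DataFrame(
        {
            "spot_id": np.concatenate([ids_tissue, ids_smear]),
            "x": np.concatenate([xy_in[:, 0], xy_smear[:, 0]]),
            "y": np.concatenate([xy_in[:, 1], xy_smear[:, 1]]),
            "total_counts": np.concatenate([totals_tissue, totals_smear]).astype(int),
            "is_smear": np.concatenate(
                [np.zeros(n_tissue, dtype=bool), np.ones(n_smear, dtype=bool)]
            ),
        }
    )

    gene_w = rng.dirichlet(np.ones(n_genes))
    counts = np.vstack(
        [rng.multinomial(n, gene_w) for n in table["total_counts"].to_numpy()]
    )
    genes = [f"gene_{j:03d}" for j in range(n_genes)]

    truth_spots = pd.DataFrame(
        {
            "radial_fraction": np.concatenate([radial, np.full(n_smear, np.nan)]),
            "axial_fraction": np.concatenate([axial, np.full(n_smear, np.nan)]),
        },
        index=pd.Index(table["spot_id"], name="spot_id"),
    )

    spot_table = SpotTable(
        table=table,
        counts=sp.csr_matrix(counts),
        genes=genes,
        boundary_ids={
            "inner": ids_tissue[ring_inner].tolist(),
            "outer": ids_tissue[ring_outer].tolist(),
            "upper": ids_tissue[ring_upper].tolist(),
            "bottom": ids_tissue[ring_bottom].tolist(),
        },
        metadata={
            "seed": seed,
            "condition": condition,
            "day": day,
            "shape_kind": geometry.shape_kind,
            "mean_depth": mean_depth,
            "smear_fraction": smear_fraction,
            "nb_dispersion": nb_dispersion,
            "spot_spacing": s,
        },
    )
    return spot_table, GroundTruth(spots=truth_spots)


@dataclass(frozen=True)
class LogisticProfile:
    """Logistic cell-type weight over the radial fraction.

    weight(rf) = low + (high - low) / (1 + exp(-slope * (rf - midpoint)));
    positive slope -> the type increases toward the inner boundary (rf=1).
    """

    midpoint: float = 0.5
    slope: float = 10.0
    low: float = 0.0
    high: float = 1.0

    def __call__(self, rf: np.ndarray) -> np.ndarray:
        rf = np.asarray(rf, dtype=float)
        return self.low + (self.high - self.low) / (1.0 + np.exp(-self.slope * (rf - self.midpoint)))


def gen_proportion_field(
    spots: SpotTable,
    truth: GroundTruth,
    profiles: dict[str, "LogisticProfile | object"],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Deconvolution-style per-spot cell-type abundances over in-tissue spots.

    Abundance of type C at spot s = profile_C(true radial fraction of s),
    perturbed by Gaussian noise truncated at zero. The noise-free
    proportions (row-normalized profile values) are stored in the returned
    ground truth. Smear spots get no abundances (deconvolution only sees
    tissue spots).
    """
    if len(profiles) < 2:
        raise ValueError("profiles must cover at least two cell types")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    tissue = spots.table.loc[~spots.table["is_smear"], "spot_id"]
    rf = truth.spots.loc[tissue, "radial_fraction"].to_numpy()
    types = sorted(profiles)
    clean = np.column_stack([np.asarray(profiles[t](rf), dtype=float) for t in types])
    if np.any(clean < 0):
        raise ValueError("profiles must map radial fractions to nonnegative weights")
    row_tot = clean.sum(axis=1)
    if np.all(clean == 0):
        raise ValueError("all profiles are zero everywhere")
    if np.any(row_tot == 0):
        raise ValueError("some spots receive zero weight from every profile")
    true_props = pd.DataFrame(
        clean / row_tot[:, None], index=pd.Index(tissue, name="spot_id"), columns=types
    )
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
    abundances = pd.DataFrame(
        np.clip(noisy, 0.0, None), index=pd.Index(tissue, name="spot_id"), columns=types
    )
    new_truth = replace(truth, type_proportions=true_props)
    return abundances, new_truth


@dataclass
class ChainResult:
    """Planted cell-state chain: graph, velocities, annotations, truth."""

    transition: sp.csr_matrix
    velocities: np.ndarray  # (n_cells, 2)
    embedding: np.ndarray  # (n_cells, 2)
    cells: pd.DataFrame  # cell_id, cell_type, stage, role
    truth: GroundTruth


def gen_transition_chain(
    n_per_type: list[int],
    chain: list[str],
    forward_p: float = 0.8,
    noise_p: float = 0.0,
    seed: int = 0,
    n_targets: int = 3,
) -> ChainResult:
    """Directed transition graph along a planted maturation chain.

    Cells of stage i place probability mass ``forward_p`` on up to
    ``n_targets`` random cells of stage i+1 and mass ``noise_p`` on random
    other cells; terminal-stage cells have zero outflow. Velocity vectors
    point from each cell's embedding position toward the next stage's
    centroid with magnitude proportional to (1 - stage_fraction), so the
    planted source stage moves fastest and the terminal sink stands still.
    """
    if len(chain) < 2:
        raise ValueError("chain must have at least two stages")
    if len(n_per_type) != len(chain):
        raise ValueError("n_per_type must align with the chain")
    if any(n < 1 for n in n_per_type):
        empty = chain[n_per_type.index(0)] if 0 in n_per_type else "a stage"
        raise ValueError(f"every stage needs at least one cell ({empty} is empty)")
    if not (0 <= noise_p < forward_p <= 1):
        raise ValueError("need 0 <= noise_p < forward_p <= 1")
    rng = np.random.default_rng(seed)

    L = len(chain)
    stages = np.concatenate([np.full(n, i) for i, n in enumerate(n_per_type)])
    n_cells = len(stages)
    centroids = np.column_stack([np.arange(L) * 5.0, np.zeros(L)])
    embedding = centroids[stages] + rng.normal(0.0, 0.5, size=(n_cells, 2))

    velocities = np.zeros((n_cells, 2))
    non_terminal = stages < L - 1
    targets = centroids[np.minimum(stages + 1, L - 1)]
    direction = targets - embedding
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    unit = np.divide(direction, norms, out=np.zeros_like(direction), where=norms > 0)
    magnitude = 1.0 - stages / (L - 1)
    velocities[non_terminal] = (unit * magnitude[:, None])[non_terminal]

    stage_members = [np.flatnonzero(stages == i) for i in range(L)]
    rows, cols, vals = [], [], []
    for c in range(n_cells):
        i = stages[c]
        if i == L - 1:
            continue
        nxt = stage_members[i + 1]
        k = min(n_targets, len(nxt))
        picks = rng.choice(nxt, size=k, replace=False)
        rows.extend([c] * k)
        cols.extend(picks.tolist())
        vals.extend([forward_p / k] * k)
        if noise_p > 0:
            pool = np.setdiff1d(np.arange(n_cells), np.append(picks, c))
            k2 = min(n_targets, len(pool))
            noise_picks = rng.choice(pool, size=k2, replace=False)
            rows.extend([c] * k2)
            cols.extend(noise_picks.tolist())
            vals.extend([noise_p / k2] * k2)
    transition = sp.csr_matrix((vals, (rows, cols)), shape=(n_cells, n_cells))

    roles = {
        t: ("source" if i == 0 else "sink" if i == L - 1 else "intermediate")
        for i, t in enumerate(chain)
    }
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell_{i:05d}" for i in range(n_cells)],
            "cell_type": [chain[i] for i in stages],
            "stage": stages,
            "role": [roles[chain[i]] for i in stages],
        }
    )
    truth = GroundTruth(
        spots=pd.DataFrame(index=pd.Index([], name="spot_id")),
        cells=cells.set_index("cell_id"),
        roles=roles,
    )
    return ChainResult(
        transition=transition,
        velocities=velocities,
        embedding=embedding,
        cells=cells,
        truth=truth,
    )
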