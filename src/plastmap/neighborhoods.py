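"""Valve-region sub-domain ranking and neighborhood composition.

Spatial-domain finding (external to this package) partitions the valve
region into sub-domains. Here we:

* select the number of clusters k from an ARI stability sweep: the first
  run of at least ``window`` consecutive k values with ARI above the
  threshold qualifies, and the k with maximal ARI inside that run is
  chosen (ties -> smallest k). The first analysis round uses window 5, the
  sub-domain round window 4.
* rank sub-domains by regional plasticity — the mean fibroblast
  proportion-weighted spot plasticity over the sub-domain's spots — and
  relabel 1..K from most plastic to most stable so labels are comparable
  across time points and conditions;
* summarize each sub-domain's cell-type "neighborhood": dominant-type
  fractions sorted descending, keeping only types contributing at least
  ``min_frac`` (5%) and accumulating them until the included mass first
  reaches ``cum_threshold`` (90%);
* call condition-level neighbor cell types: a type qualifies within a
  sample when it appears in the included composition of at least
  ``min_subdomains`` sub-domains, and is a neighbor for the condition when
  it qualifies on at least ``min_timepoints`` distinct days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "NoStableRangeError",
    "KSelection",
    "SampleComposition",
    "select_k_by_ari",
    "regional_plasticity",
    "composition_summary",
    "neighbor_celltypes",
    "two_round_subdomains",
]


class NoStableRangeError(ValueError):
    """Raised when no run of consecutive ARI values clears the threshold."""


@dataclass(frozen=True)
class KSelection:
    run_ks: tuple[int, ...]  # the full qualifying consecutive run
    chosen_k: int
    ari: dict = field(default_factory=dict)


def select_k_by_ari(
    ks: np.ndarray | list[int],
    ari: np.ndarray | list[float],
    threshold: float = 0.65,
    window: int = 5,
) -> KSelection:
    """Pick a cluster count from an ARI stability sweep.

    Scans the ascending candidate k values for the first maximal run of
    consecutive candidates with ARI strictly above ``threshold`` whose
    length is at least ``window``; within that run the chosen k is the one
    with maximal ARI (ties broken toward the smallest k). Candidates after
    the end of the first qualifying run cannot change the outcome.
    """
    ks = np.asarray(ks, dtype=int)
    ari = np.asarray(ari, dtype=float)
    if len(ks) != len(ari):
        raise ValueError("ks and ari must align")
    if len(ks) < window:
        raise ValueError(f"need at least window={window} candidates")
    if np.any(np.diff(ks) <= 0):
        raise ValueError("candidate k values must be strictly increasing")
    if np.any((ari < -1) | (ari > 1)):
        raise ValueError("ARI values must lie in [-1, 1]")

    above = ari > threshold
    start = None
    for i, ok in enumerate(above):
        if ok and start is None:
            start = i
        run_over = (not ok) or i == len(above) - 1
        if start is not None and run_over:
            end = i if not ok else i + 1  # exclusive
            if end - start >= window:
                run = slice(start, end)
                run_ari = ari[run]
                chosen = ks[run][int(np.argmax(run_ari))]
                return KSelection(
                    run_ks=tuple(ks[run].tolist()),
                    chosen_k=int(chosen),
                    ari=dict(zip(ks[run].tolist(), run_ari.tolist())),
                )
            start = None
    raise NoStableRangeError(
        f"no run of {window} consecutive candidates with ARI > {threshold}; "
        "consider lowering the threshold"
    )


def regional_plasticity(
    labels: pd.Series,
    spot_scores: pd.Series,
) -> pd.DataFrame:
    """Score and rank sub-domains by mean fibroblast spot plasticity.

    ``labels`` maps spot id -> sub-domain id; ``spot_scores`` maps spot id
    -> fibroblast summed spot plasticity (see
    :func:`plastmap.plasticity.spot_plasticity` over fibroblast subtypes).
    Returns one row per sub-domain with its mean score, rank (1 = most
    plastic) and relabeled id equal to the rank, so label/color coding is
    consistent across samples. Score ties are broken by original
    sub-domain id ascending.
    """
    labels = pd.Series(labels)
    spot_scores = pd.Series(spot_scores)
    missing = labels.index.difference(spot_scores.index)
    if len(missing):
        raise ValueError(f"{len(missing)} labeled spots lack a plasticity score")
    scores = spot_scores.loc[labels.index]
    table = (
        pd.DataFrame({"subdomain": labels.values, "score": scores.values})
        .groupby("subdomain", sort=True)["score"]
        .mean()
        .reset_index()
    )
    table = table.sort_values(
        ["score", "subdomain"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["relabeled"] = table["rank"]
    return table


def composition_summary(
    labels: pd.Series,
    dominant_types: pd.Series,
    cum_threshold: float = 0.90,
    min_frac: float = 0.05,
    eligibility_first: bool = True,
) -> pd.DataFrame:
    """Filtered cell-type composition of each sub-domain.

    Per sub-domain, dominant-type fractions are sorted descending (ties by
    type name). With ``eligibility_first`` (the default), types below
    ``min_frac`` are ineligible; eligible types are included in order
    until the cumulative included fraction first reaches
    ``cum_threshold`` — the crossing type is included — or eligible types
    run out. The alternative (accumulate first to the threshold, then
    drop included types below ``min_frac``) is selectable.

    Returns a long table: subdomain, cell_type, fraction, included.
    """
    if not (0 < cum_threshold <= 1):
        raise ValueError("cum_threshold must lie in (0, 1]")
    if not (0 <= min_frac < 1):
        raise ValueError("min_frac must lie in [0, 1)")
    labels = pd.Series(labels)
    dominant_types = pd.Series(dominant_types)
    missing = labels.index.difference(dominant_types.index)
    if len(missing):
        raise ValueError(f"{len(missing)} labeled spots lack a dominant type")
    types = dominant_types.loc[labels.index]

    rows = []
    for sub, grp in pd.DataFrame({"sub": labels.values, "t": types.values}).groupby("sub"):
        fracs = grp["t"].value_counts(normalize=True)
        fracs = fracs.sort_index().sort_values(ascending=False, kind="mergesort")
        included: dict[str, bool] = {}
        cum = 0.0
        if eligibility_first:
            for t, f in fracs.items():
                if f < min_frac:
                    included[t] = False
                    continue
                if cum >= cum_threshold:
                    included[t] = False
                    continue
                included[t] = True
                cum += f
        else:
            for t, f in fracs.items():
                if cum < cum_threshold:
                    included[t] = f >= min_frac
                    cum += f
                else:
                    included[t] = False
        for t, f in fracs.items():
            rows.append(
                {"subdomain": sub, "cell_type": t, "fraction": f, "included": included[t]}
            )
    return pd.DataFrame(rows)


def two_round_subdomains(
    cluster,
    spot_ids: pd.Index | list,
    dominant_types: pd.Series,
    valve_types: set[str] | list[str],
) -> tuple[object, pd.Series]:
    """Two-round orchestration: whole tissue -> valve domain -> sub-domains.

    ``cluster`` is a user-supplied callback mapping a list of spot ids to a
    pd.Series of domain labels (domain finding itself — e.g. a spatially
    informed clustering — is external to this package). Round 1 clusters
    every spot and the valve domain is the label whose member spots have
    the highest fraction of valve-type dominant assignments; round 2
    clusters only the valve domain's spots. Returns the valve domain label
    and the per-spot sub-domain labels.
    """
    spot_ids = pd.Index(spot_ids)
    first = pd.Series(cluster(spot_ids))
    valve_types = set(valve_types)
    is_valve = dominant_types.loc[first.index].isin(valve_types)
    valve_frac = is_valve.groupby(first.values).mean()
    valve_label = valve_frac.sort_index().idxmax()  # ties -> smallest label
    valve_spots = first.index[first == valve_label]
    subdomains = pd.Series(cluster(valve_spots))
    return valve_label, subdomains


@dataclass(frozen=True)
class SampleComposition:
    """Included composition of one sample (one slide at one day)."""

    condition: str
    day: int
    composition: pd.DataFrame  # output of composition_summary


def neighbor_celltypes(
    samples: list[SampleComposition],
    min_subdomains: int = 2,
    min_timepoints: int = 2,
) -> dict[str, set[str]]:
    """Condition-level neighbor cell types from per-sample compositions.

    Within a sample a type is a candidate if it is included in the
    composition of at least ``min_subdomains`` sub-domains; a type is a
    neighbor for a condition if it is a candidate on at least
    ``min_timepoints`` distinct days of that condition.
    """
    if not samples:
        raise ValueError("need at least one sample")
    universes = [set(s.composition["cell_type"]) for s in samples]
    if len(set(map(frozenset, universes))) > 1:
        warnings.warn("samples have inconsistent cell-type universes; taking the union")

    candidate_days: dict[str, dict[str, set[int]]] = {}
    for s in samples:
        comp = s.composition
        inc = comp[comp["included"]]
        counts = inc.groupby("cell_type")["subdomain"].nunique()
        for t, n_sub in counts.items():
            if n_sub >= min_subdomains:
                candidate_days.setdefault(s.condition, {}).setdefault(t, set()).add(s.day)
    return {
        cond: {t for t, days in per_type.items() if len(days) >= min_timepoints}
        for cond, per_type in candidate_days.items()
    }
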