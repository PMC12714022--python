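"""Per-spot cell-type proportions and dominant-type assignment.

Deconvolution (e.g. a Bayesian model trained on a matched single-cell
reference) yields nonnegative per-spot cell-type *abundances*. Downstream
analyses work with *proportions* — each spot's abundances normalized to sum
to one — and with a per-spot *dominant type*, the argmax proportion.

Spots whose dominant type is an excluded population (by default
erythrocytes, i.e. residual blood contamination) are flagged and dropped
from all downstream analyses. Spots with zero total abundance reflect a
deconvolution failure and are dropped rather than given uniform
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

__all__ = ["ProportionResult", "abundance_to_proportion", "assign_dominant"]

DEFAULT_EXCLUDE = ("Erythrocytes",)


@dataclass
class ProportionResult:
    proportions: pd.DataFrame  # spots x types, rows sum to 1
    dropped_spots: list = field(default_factory=list)  # zero-abundance spots
    dominant: pd.Series | None = None  # per-spot dominant type
    excluded: pd.Series | None = None  # per-spot exclusion flag

    def kept(self) -> pd.DataFrame:
        """Proportions of spots that survive exclusion."""
        if self.excluded is None:
            return self.proportions
        return self.proportions.loc[~self.excluded]


def abundance_to_proportion(abundances: pd.DataFrame) -> ProportionResult:
    """Normalize per-spot abundances to proportions.

    ``proportion[C, s] = abundance[C, s] / sum_C abundance[C, s]``. Rows
    are spots, columns cell types. Spots with zero total abundance are
    dropped and listed in the result. Scale-invariant: multiplying a row
    by any k > 0 leaves its proportions unchanged.
    """
    ab = abundances.astype(float)
    if ab.columns.duplicated().any():
        raise ValueError("cell-type names must be unique")
    vals = ab.to_numpy()
    if not np.all(np.isfinite(vals)):
        raise ValueError("abundances contain non-finite values")
    if vals.size and vals.min() < 0:
        raise ValueError("abundances must be nonnegative")
    totals = vals.sum(axis=1)
    zero = totals == 0
    props = ab.loc[~zero].div(totals[~zero], axis=0)
    return ProportionResult(proportions=props, dropped_spots=ab.index[zero].tolist())


def assign_dominant(
    result: ProportionResult | pd.DataFrame,
    exclude_types: tuple[str, ...] | list[str] = DEFAULT_EXCLUDE,
) -> ProportionResult:
    """Assign each spot to its highest-proportion cell type.

    Ties are broken deterministically by the lexicographically smallest
    cell-type name. Spots whose dominant type is in ``exclude_types`` are
    flagged ``excluded`` and should be omitted from all downstream
    analyses (use :meth:`ProportionResult.kept`). Unknown names in the
    exclude list provoke a warning, not an error.
    """
    if isinstance(result, pd.DataFrame):
        result = ProportionResult(proportions=result)
    props = result.proportions
    unknown = [t for t in exclude_types if t not in props.columns]
    if unknown:
        warnings.warn(f"exclude list names unknown cell types: {unknown}")
    # sorting columns makes idxmax pick the lexicographically smallest on ties
    ordered = props[sorted(props.columns)]
    dominant = ordered.idxmax(axis=1)
    dominant.name = "dominant_type"
    excluded = dominant.isin(exclude_types)
    excluded.name = "excluded"
    return ProportionResult(
        proportions=props,
        dropped_spots=result.dropped_spots,
        dominant=dominant,
        excluded=excluded,
    )
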