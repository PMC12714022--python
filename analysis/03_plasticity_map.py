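"""Plasticity scoring: cells -> cell types -> spatial spots.

Computes the plasticity score on the simulated transition chain (scaled
velocity magnitude x scaled net flow), aggregates per cell type, and
projects the type scores onto the simulated valve spots by deconvolved
proportion weighting. Run analysis/01_simulate_tissue.py first.
"""

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from plastmap import io, mapping, plasticity

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    chain_dir = ROOT / "sim" / "chain"
    T = sp.csr_matrix(scipy.io.mmread(chain_dir / "transition.mtx"))
    cells = pd.read_csv(chain_dir / "cells.tsv", sep="\t")

    mag = plasticity.velocity_magnitude(cells[["vx", "vy"]].to_numpy())
    flow = plasticity.net_flow(T)
    cell_scores = plasticity.cell_plasticity(mag.scaled, flow.scaled)
    type_scores = plasticity.celltype_plasticity(cell_scores, cells["cell_type"])

    out = ROOT / "plasticity"
    out.mkdir(parents=True, exist_ok=True)
    cells.assign(
        velocity_magnitude=mag.raw, scaled_magnitude=mag.scaled,
        net_flow=flow.raw, scaled_net_flow=flow.scaled, plasticity=cell_scores,
    ).to_csv(out / "cell_scores.tsv", sep="\t", index=False)
    type_scores.to_csv(out / "type_scores.tsv", sep="\t")

    # map onto valve spots: stage scores stand in for fibroblast subtypes
    ab = io.read_matrix_tsv(ROOT / "sim" / "valve" / "abundances.tsv")
    props = mapping.assign_dominant(mapping.abundance_to_proportion(ab))
    subtype_scores = pd.Series(
        {"Valve-immature-fib": type_scores["immature"],
         "Valve-mature-fib": type_scores["mature"]}
    )
    per_type, summed = plasticity.spot_plasticity(props.kept(), subtype_scores)
    per_type.assign(spot_plasticity=summed).to_csv(out / "valve_spot_scores.tsv", sep="\t")

    print("cell-type plasticity (1 = most plastic):")
    print(type_scores.to_string())
    print(f"valve spots scored: {len(summed)}; "
          f"mean spot plasticity {summed.mean():.3f}")
    print(f"tables in {out}")


if __name__ == "__main__":
    main()
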