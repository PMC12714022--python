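"""Simulate the study inputs: ventricular wall, valve leaflet, state chain.

Generates (i) a half-annular ventricular wall section on a 20 µm bead
lattice (r 300-600 µm) with 10% planted off-tissue smears and a transmural
cell-type gradient, (ii) a wedge-shaped valve leaflet with a tip-to-base
maturation gradient, and (iii) a three-stage immature -> transitional ->
mature transition chain with velocities. Everything is written under
results/sim/ as TSV/MTX plus ground truth.
"""

import json
import sys
from pathlib import Path

from plastmap import io, synthetic

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"

VENTRICLE_PROFILES = {
    "Endocardial": synthetic.LogisticProfile(midpoint=0.7, slope=12.0),   # lumenal
    "vCM-trabecular": synthetic.LogisticProfile(midpoint=0.5, slope=6.0),
    "vCM-compact": synthetic.LogisticProfile(midpoint=0.4, slope=-8.0),   # mural
}


def main() -> None:
    import numpy as np

    ventricle_geom = synthetic.TissueGeometry(
        shape_kind="annulus", r_inner=300, r_outer=600,
        theta_min=0.0, theta_max=np.pi, spot_spacing=20.0,
    )
    ventricle, vtruth = synthetic.gen_spots(
        ventricle_geom, mean_depth=500, smear_fraction=0.10, seed=SEED
    )
    vab, vtruth = synthetic.gen_proportion_field(
        ventricle, vtruth, VENTRICLE_PROFILES, noise_sd=0.05, seed=SEED + 1
    )
    io.write_spot_table(ventricle, OUT / "ventricle")
    io.write_ground_truth(vtruth, OUT / "ventricle")
    io.write_matrix_tsv(vab, OUT / "ventricle" / "abundances.tsv")
    ventricle.region_mask("LV").to_json(OUT / "ventricle" / "region_mask.json")

    valve_geom = synthetic.TissueGeometry(
        shape_kind="wedge", base_width=400, height=600, spot_spacing=20.0
    )
    valve, wtruth = synthetic.gen_spots(valve_geom, mean_depth=500, seed=SEED + 2)
    # valve maturation runs tip (axial 0, immature) to base (axial 1, mature)
    axial_truth = synthetic.GroundTruth(
        spots=wtruth.spots.assign(radial_fraction=wtruth.spots["axial_fraction"])
    )
    wab, wtruth2 = synthetic.gen_proportion_field(
        valve, axial_truth,
        {
            "Valve-immature-fib": synthetic.LogisticProfile(midpoint=0.5, slope=-10.0),
            "Valve-mature-fib": synthetic.LogisticProfile(midpoint=0.5, slope=10.0),
        },
        noise_sd=0.05, seed=SEED + 3,
    )
    io.write_spot_table(valve, OUT / "valve")
    io.write_ground_truth(wtruth2, OUT / "valve")
    io.write_matrix_tsv(wab, OUT / "valve" / "abundances.tsv")

    chain = synthetic.gen_transition_chain(
        [200, 200, 200], ["immature", "transitional", "mature"],
        forward_p=0.8, noise_p=0.0, seed=SEED + 4,
    )
    chain_dir = OUT / "chain"
    chain_dir.mkdir(parents=True, exist_ok=True)
    import scipy.io

    scipy.io.mmwrite(chain_dir / "transition.mtx", chain.transition.tocoo())
    chain.cells.assign(vx=chain.velocities[:, 0], vy=chain.velocities[:, 1]).to_csv(
        chain_dir / "cells.tsv", sep="\t", index=False
    )
    (chain_dir / "params.json").write_text(json.dumps({"seed": SEED + 4}))

    n_smear = int(ventricle.table["is_smear"].sum())
    print(f"ventricle: {len(ventricle.table)} spots ({n_smear} planted smears)")
    print(f"valve: {len(valve.table)} spots")
    print(f"chain: {len(chain.cells)} cells over 3 stages")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
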