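"""Plain-text readers and writers for the pipeline's tables.

Spot tables travel as TSV (spot_id, x, y, total_counts, is_smear) with the
sparse counts as MatrixMarket (.mtx) plus barcodes/features sidecars;
generation parameters are echoed to a JSON sidecar. Abundance/proportion
matrices, reports and profiles are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .synthetic import GroundTruth, SpotTable

__all__ = [
    "write_spot_table",
    "read_spot_table",
    "write_ground_truth",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


def write_spot_table(spots: SpotTable, out_dir: str | Path) -> Path:
    """Write spots as TSV + MTX + barcodes/features + a JSON parameter sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spots.table.to_csv(out / "spots.tsv", sep="\t", index=False)
    scipy.io.mmwrite(out / "counts.mtx", sp.coo_matrix(spots.counts))
    (out / "barcodes.txt").write_text("\n".join(spots.spot_ids) + "\n")
    (out / "features.txt").write_text("\n".join(spots.genes) + "\n")
    (out / "params.json").write_text(json.dumps(spots.metadata, indent=1, default=str))
    return out


def read_spot_table(in_dir: str | Path) -> SpotTable:
    """Round-trip reader for :func:`write_spot_table` output."""
    d = Path(in_dir)
    table = pd.read_csv(d / "spots.tsv", sep="\t")
    counts = sp.csr_matrix(scipy.io.mmread(d / "counts.mtx"))
    genes = (d / "features.txt").read_text().splitlines()
    metadata = json.loads((d / "params.json").read_text())
    # boundary rings are not serialized with the table; regenerate or load masks
    return SpotTable(
        table=table,
        counts=counts,
        genes=genes,
        boundary_ids={"inner": [], "outer": [], "upper": [], "bottom": []},
        metadata=metadata,
    )


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.spots.to_csv(out / "truth_spots.tsv", sep="\t")
    if truth.type_proportions is not None:
        truth.type_proportions.to_csv(out / "truth_proportions.tsv", sep="\t")
    if truth.cells is not None:
        truth.cells.to_csv(out / "truth_cells.tsv", sep="\t")
    return out


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
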