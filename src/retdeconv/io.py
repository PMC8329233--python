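"""Plain-text readers and writers for the pipeline's on-disk layout.

Single-cell matrices are MatrixMarket (.mtx) plus genes.tsv / cells.tsv;
bulk matrices are a genes x samples TSV plus samples.tsv; ground truth and all
stage outputs are TSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .synthetic import BulkMatrix, GroundTruth, SingleCellMatrix


def write_single_cell(sc: SingleCellMatrix, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(sc.counts))
    pd.DataFrame({"gene_id": sc.gene_ids}).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    cells = pd.DataFrame(
        {
            "cell_id": sc.cell_ids,
            "cell_type": sc.cell_types.to_numpy(),
            "region": sc.regions.to_numpy() if sc.regions is not None else "",
        }
    )
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    return outdir


def read_single_cell(indir: str | Path) -> SingleCellMatrix:
    indir = Path(indir)
    counts = sp.csr_matrix(sio.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene_id"].astype(str).tolist()
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    cell_ids = cells["cell_id"].astype(str).tolist()
    regions = None
    if "region" in cells and cells["region"].notna().any():
        regions = pd.Series(cells["region"].astype(str).to_numpy(), index=cell_ids, name="region")
    return SingleCellMatrix(
        counts=counts,
        gene_ids=genes,
        cell_ids=cell_ids,
        cell_types=pd.Series(cells["cell_type"].astype(str).to_numpy(), index=cell_ids, name="cell_type"),
        regions=regions,
    )


def write_bulk(bulk: BulkMatrix, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bulk.counts.rename_axis("gene_id").to_csv(outdir / "bulk_counts.tsv", sep="\t")
    pd.DataFrame(
        {"sample_id": bulk.sample_ids, "condition": bulk.conditions.to_numpy()}
    ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    return outdir


def read_bulk(indir: str | Path) -> BulkMatrix:
    indir = Path(indir)
    counts = pd.read_csv(indir / "bulk_counts.tsv", sep="\t", index_col="gene_id")
    samples = pd.read_csv(indir / "samples.tsv", sep="\t")
    conditions = pd.Series(
        samples["condition"].astype(str).to_numpy(),
        index=samples["sample_id"].astype(str),
        name="condition",
    )
    return BulkMatrix(counts=counts, conditions=conditions)


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.true_profiles.rename_axis("gene_id").to_csv(outdir / "true_profiles.tsv", sep="\t")
    if truth.true_proportions is not None:
        truth.true_proportions.rename_axis("sample_id").to_csv(outdir / "true_proportions.tsv", sep="\t")
    rows = [
        {"cell_type": ct, "gene": g, "planted_ctdeg": g in truth.planted_ctdegs.get(ct, {}),
         "effect": truth.planted_ctdegs.get(ct, {}).get(g, 1.0)}
        for ct, genes in truth.planted_markers.items()
        for g in genes
    ]
    pd.DataFrame(rows, columns=["cell_type", "gene", "planted_ctdeg", "effect"]).to_csv(
        outdir / "planted_markers.tsv", sep="\t", index=False
    )
    pc_rows = [
        {"condition": cond, "cell_type": ct, "true_PC": val}
        for cond, series in truth.true_PC.items()
        for ct, val in series.items()
    ]
    pd.DataFrame(pc_rows).to_csv(outdir / "true_pc.tsv", sep="\t", index=False)
    return outdir


def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
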