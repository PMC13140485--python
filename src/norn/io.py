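"""Readers and writers for the on-disk formats the pipeline exchanges.

Counts travel as MatrixMarket (MTX) plus gene/spot TSVs, spot positions and
REP centroids as CSV, marker masks as labeled TIFF and GeoJSON polygon
collections, images as OME-TIFF with named channels, and ground truth as
JSON + TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

from norn.markers import MarkerObjects


# ---------------------------------------------------------------------------
# counts


def write_counts(adata: AnnData, outdir) -> None:
    """Write spots x genes counts as genes x spots MTX + TSVs + positions CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    spio.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "spots.tsv", sep="\t", index=False, header=False)
    pos = adata.obs[["x_um", "y_um", "in_tissue"]].copy()
    pos.index.name = "spot_id"
    pos.to_csv(outdir / "spot_positions.csv")


def read_counts(indir) -> AnnData:
    indir = Path(indir)
    X = sparse.csr_matrix(spio.mmread(str(indir / "matrix.mtx"))).T.tocsr()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    spots = pd.read_csv(indir / "spots.tsv", sep="\t", header=None)[0].astype(str)
    adata = AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(spots, name="spot_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    pos_path = indir / "spot_positions.csv"
    if pos_path.exists():
        pos = pd.read_csv(pos_path, index_col=0)
        adata.obs = adata.obs.join(pos)
    return adata


# ---------------------------------------------------------------------------
# centroids


def write_centroids(rep_cells: pd.DataFrame, path) -> None:
    cols = ["cell_id", "x_um", "y_um", "section_id", "animal_id"]
    rep_cells[cols].to_csv(path, index=False)


def read_centroids(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# images and masks


def write_image(image: np.ndarray, channel_names, path, pixel_size: float) -> None:
    """OME-TIFF with named channels and µm pixel calibration."""
    tifffile.imwrite(
        path,
        np.asarray(image, dtype=np.float32),
        ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": list(channel_names)},
            "PhysicalSizeX": pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": pixel_size,
            "PhysicalSizeYUnit": "µm",
        },
    )


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)


def write_masks(markers: MarkerObjects, outdir) -> None:
    """Labeled TIFF per class plus one GeoJSON feature collection."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    features = []
    for name in markers.classes:
        tifffile.imwrite(outdir / f"{name}_labels.tif", markers.labeled(name).astype(np.int32))
        features.extend(markers.to_polygons(name))
    payload = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"pixel_size_um": markers.pixel_size},
    }
    (outdir / "masks.geojson").write_text(json.dumps(payload))


def read_masks(indir, classes=None) -> MarkerObjects:
    indir = Path(indir)
    paths = sorted(indir.glob("*_labels.tif"))
    masks = {}
    for p in paths:
        name = p.name[: -len("_labels.tif")]
        if classes is not None and name not in classes:
            continue
        masks[name] = tifffile.imread(p) > 0
    meta = json.loads((indir / "masks.geojson").read_text())
    ps = float(meta.get("properties", {}).get("pixel_size_um", 1.0))
    return MarkerObjects(masks=masks, pixel_size=ps)


# ---------------------------------------------------------------------------
# ground truth and tables


def write_ground_truth(truth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.rep_cells.to_csv(outdir / "rep_cells.tsv", sep="\t", index=False)
    if truth.compositions is not None:
        truth.compositions.to_csv(outdir / "true_compositions.tsv", sep="\t")
    if truth.signatures is not None:
        truth.signatures.to_csv(outdir / "signatures.tsv", sep="\t")
    summary = {
        "n_rep_cells": int(len(truth.rep_cells)),
        "class_counts": truth.rep_cells["true_class"].value_counts().to_dict()
        if len(truth.rep_cells)
        else {},
    }
    (outdir / "ground_truth.json").write_text(json.dumps(summary, indent=2))


def read_signatures(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# LR database


def read_lr_database(path):
    """TSV with columns ligand_subunits, receptor_subunits, pathway;
    subunits joined by '+'."""
    from norn.commun import Interaction

    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        records.append(
            Interaction(
                tuple(str(row["ligand_subunits"]).split("+")),
                tuple(str(row["receptor_subunits"]).split("+")),
                str(row.get("pathway", "")),
            )
        )
    return records


def write_lr_database(interactions, path) -> None:
    rows = [
        {
            "ligand_subunits": "+".join(i.ligand_subunits),
            "receptor_subunits": "+".join(i.receptor_subunits),
            "pathway": i.pathway,
        }
        for i in interactions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
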