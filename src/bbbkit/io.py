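"""Readers and writers for the pipeline's file formats.

Transwell series and TEER tables are CSV; image stacks are multi-page
TIFF with pixel-size metadata; counts are TSV (genes x samples) or an
MatrixMarket triplet; networks are 2-column edge-list TSV or GraphML;
gene sets are GMT; configs and geometry blocks are YAML.
"""
from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .datatypes import AssayGeometry, CountMatrix, ImageStack, TranswellSeries

__all__ = [
    "read_geometry", "write_geometry",
    "read_transwell_series", "write_transwell_series",
    "read_teer_table", "write_teer_table",
    "read_stack", "write_stack",
    "read_counts_tsv", "write_counts_tsv", "read_counts_mtx", "write_counts_mtx",
    "read_groups", "read_gene_list", "read_gmt", "write_gmt",
    "read_edge_list", "write_edge_list", "read_graphml", "write_graphml",
    "read_node_annotations", "write_node_annotations",
    "read_segments", "write_segments",
    "read_yaml", "write_json",
]


# --- geometry / config -----------------------------------------------------

_GEOM_KEYS = ("membrane_area_cm2", "lower_volume_ml", "upper_volume_ml",
              "upper_conc_um", "sample_volume_ml", "sample_interval_min",
              "duration_min")


def read_geometry(path) -> AssayGeometry:
    data = yaml.safe_load(Path(path).read_text())
    return AssayGeometry(**{k: float(data[k]) for k in _GEOM_KEYS if k in data})


def write_geometry(geom: AssayGeometry, path) -> None:
    Path(path).write_text(yaml.safe_dump(
        {k: getattr(geom, k) for k in _GEOM_KEYS}, sort_keys=False))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


# --- Transwell / TEER ------------------------------------------------------

def write_transwell_series(series: TranswellSeries, path) -> None:
    pd.DataFrame({"time_min": series.times_min,
                  "lower_conc_uM": series.lower_conc_um}).to_csv(path, index=False)


def read_transwell_series(path, geometry: AssayGeometry) -> TranswellSeries:
    df = pd.read_csv(path)
    return TranswellSeries(df["time_min"].to_numpy(),
                           df["lower_conc_uM"].to_numpy(), geometry)


def write_teer_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_teer_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("total_ohm", "blank_ohm"):
        if col not in df:
            raise ValueError(f"TEER table missing column {col}")
    return df


# --- images ----------------------------------------------------------------

def write_stack(stack: ImageStack, path) -> None:
    """Multi-page TIFF; pixel size stored as TIFF resolution (px/um)."""
    res = 1.0 / stack.pixel_size_um
    tifffile.imwrite(path, stack.voxels.astype(np.float32),
                     resolution=(res, res),
                     metadata={"z_step_um": stack.z_step_um,
                               "channel": stack.channel,
                               "pixel_size_um": stack.pixel_size_um})


def read_stack(path, pixel_size_um: float | None = None) -> ImageStack:
    with tifffile.TiffFile(path) as tf:
        voxels = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if voxels.ndim == 2:
        voxels = voxels[None, :, :]
    px = pixel_size_um or meta.get("pixel_size_um")
    if px is None:
        raise ValueError("pixel size not in metadata; pass pixel_size_um")
    return ImageStack(voxels, float(px),
                      z_step_um=float(meta.get("z_step_um", 0.2)),
                      channel=str(meta.get("channel", "")))


def write_segments(segments, path) -> None:
    pd.DataFrame(segments, columns=["x0", "y0", "x1", "y1"]).to_csv(path, index=False)


def read_segments(path) -> list[tuple[float, float, float, float]]:
    df = pd.read_csv(path)
    return [tuple(map(float, row)) for row in df[["x0", "y0", "x1", "y1"]].to_numpy()]


# --- counts ----------------------------------------------------------------

def write_counts_tsv(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path, groups: dict[str, str]) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df.astype(int), groups)


def write_counts_mtx(cm: CountMatrix, prefix) -> None:
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(cm.counts.to_numpy()))
    prefix.with_suffix(".genes.txt").write_text("\n".join(cm.counts.index) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(cm.counts.columns) + "\n")


def read_counts_mtx(prefix, groups: dict[str, str]) -> CountMatrix:
    prefix = Path(prefix)
    mat = np.asarray(mmread(str(prefix.with_suffix(".mtx"))).todense())
    genes = prefix.with_suffix(".genes.txt").read_text().split()
    samples = prefix.with_suffix(".samples.txt").read_text().split()
    return CountMatrix(pd.DataFrame(mat.astype(int), index=genes, columns=samples),
                       groups)


def read_groups(path) -> dict[str, str]:
    """Two-column TSV: sample_id<TAB>group (WT or DEL)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"])
    return dict(zip(df["sample"], df["group"]))


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")]


def read_gmt(path) -> dict[str, list[str]]:
    terms = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError("GMT lines need term, description, >=1 gene")
        terms[parts[0]] = [g for g in parts[2:] if g]
    return terms


def write_gmt(terms: dict, path) -> None:
    lines = [f"{t}\t-\t" + "\t".join(genes) for t, genes in terms.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# --- networks --------------------------------------------------------------

def write_edge_list(graph: nx.Graph, path) -> None:
    pd.DataFrame(sorted(graph.edges), columns=["source", "target"]).to_csv(
        path, sep="\t", index=False)


def read_edge_list(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [tuple(r) for r in df.iloc[:, :2].astype(str).to_numpy()]


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_node_annotations(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="node_id")


def read_node_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="node_id")
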