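"""Readers and writers for the pipeline's plain-text formats.

Connectivity matrices are dense tab-separated text with a header row of
region labels; time series are tab-separated with epoch metadata in comment
lines; atlas mappings and covariates are CSV; supra-adjacency matrices are
sparse coordinate-list text with a layer-order sidecar.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .atlas import AtlasMapping
from .backbone import BackboneGraph
from .connectivity import ConnectivityMatrix, EpochedTimeSeries
from .multilayer import SupraAdjacency
from .synthetic import LAYER_ORDER, SyntheticCohort

log = logging.getLogger("brainmux")

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_atlas",
    "write_atlas",
    "read_timeseries",
    "write_timeseries",
    "write_backbone",
    "write_supra",
    "write_cohort",
    "read_cohort_layers",
    "config_hash",
]


def write_matrix(path: str | Path, matrix: ConnectivityMatrix) -> None:
    path = Path(path)
    header = "\t".join(matrix.region_labels)
    np.savetxt(path, matrix.weights, delimiter="\t", header=header, comments="")


def read_matrix(
    path: str | Path,
    modality: str = "",
    subject_id: str = "",
    atlas: AtlasMapping | None = None,
) -> ConnectivityMatrix:
    """Read a delimited square matrix with an optional region-label header.

    If an atlas is given and the file's labels are a permutation of the
    atlas order, rows/columns are reordered to atlas order (logged).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    tokens = first.strip().split("\t") if "\t" in first else first.strip().split(",")
    has_header = any(not _is_number(t) for t in tokens if t)
    delim = "\t" if "\t" in first else ","
    labels: tuple[str, ...] = ()
    try:
        body = np.loadtxt(path, delimiter=delim, skiprows=1 if has_header else 0,
                          ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse matrix body ({exc})") from exc
    if has_header:
        labels = tuple(t for t in tokens if t)
        if len(labels) != body.shape[1]:
            raise ValueError(
                f"{path}: {len(labels)} header labels but {body.shape[1]} columns"
            )
    if body.shape[0] != body.shape[1]:
        raise ValueError(f"{path}: matrix body is {body.shape[0]}x{body.shape[1]}, not square")
    if atlas is not None and labels and labels != atlas.region_names:
        if sorted(labels) != sorted(atlas.region_names):
            raise ValueError(f"{path}: labels do not match the atlas region set")
        perm = [labels.index(name) for name in atlas.region_names]
        body = body[np.ix_(perm, perm)]
        labels = atlas.region_names
        log.info("%s: reordered matrix columns to atlas order", path)
    return ConnectivityMatrix(body, modality=modality, subject_id=subject_id,
                              region_labels=labels)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_atlas(path: str | Path, atlas: AtlasMapping) -> None:
    df = pd.DataFrame({
        "region_index": range(len(atlas)),
        "region_name": atlas.region_names,
        "subnetwork": atlas.subnetworks,
    })
    df.to_csv(path, index=False)


def read_atlas(path: str | Path) -> AtlasMapping:
    df = pd.read_csv(path)
    required = {"region_index", "region_name", "subnetwork"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: atlas file needs columns {sorted(required)}")
    idx = df["region_index"].to_numpy()
    if idx.min() == 1:  # 1-based files are converted on read
        idx = idx - 1
    if sorted(idx) != list(range(len(df))):
        raise ValueError(f"{path}: region_index must enumerate regions exactly once")
    order = np.argsort(idx)
    return AtlasMapping(
        tuple(df["region_name"].iloc[order]),
        tuple(df["subnetwork"].iloc[order]),
    )


def write_timeseries(path: str | Path, series: EpochedTimeSeries) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate={series.sampling_rate}\n")
        fh.write(f"# n_epochs={series.n_epochs}\n")
        fh.write(f"# epoch_len={series.n_samples}\n")
        fh.write("\t".join(series.region_labels) + "\n")
        np.savetxt(fh, series.flat(), delimiter="\t")


def read_timeseries(path: str | Path) -> EpochedTimeSeries:
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = float(val)
            pos = fh.tell()
            line = fh.readline()
        labels = tuple(line.strip().split("\t"))
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    n_epochs = int(meta.get("n_epochs", 1))
    epoch_len = int(meta.get("epoch_len", data.shape[0] // max(1, n_epochs)))
    fs = meta.get("sampling_rate", 1.0)
    values = data.reshape(n_epochs, epoch_len, len(labels))
    return EpochedTimeSeries(values, fs, labels)


def write_backbone(path: str | Path, tree: BackboneGraph,
                   weights: np.ndarray | None = None) -> None:
    """Edge list: i, j, original_weight (1 if no weights given)."""
    rows = []
    for i, j in tree.edge_list:
        w = weights[i, j] if weights is not None else 1.0
        rows.append((i, j, w))
    with open(path, "w") as fh:
        fh.write("i\tj\toriginal_weight\n")
        for i, j, w in rows:
            fh.write(f"{i}\t{j}\t{w!r}\n")


def write_supra(path: str | Path, supra: SupraAdjacency) -> None:
    """Coordinate-list sparse text plus a layer-order sidecar (.layers)."""
    path = Path(path)
    coo = supra.matrix.tocoo()
    with open(path, "w") as fh:
        fh.write("row\tcol\tvalue\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r}\t{c}\t{v!r}\n")
    sidecar = path.with_suffix(path.suffix + ".layers")
    with open(sidecar, "w") as fh:
        fh.write("\n".join(supra.layer_order) + "\n")


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a cohort as the pipeline's on-disk tree.

    ``<out>/atlas.csv``, ``<out>/covariates.csv`` and one file per subject
    per layer under ``<out>/<subject_id>/`` (time-series layers as .tsv
    series files, matrix layers as .tsv matrices).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_atlas(out / "atlas.csv", cohort.atlas)
    cohort.covariates().to_csv(out / "covariates.csv")
    for subj in cohort.subjects:
        sdir = out / subj.subject_id
        sdir.mkdir(exist_ok=True)
        for layer, data in subj.layers.items():
            if isinstance(data, EpochedTimeSeries):
                write_timeseries(sdir / f"{layer}.tsv", data)
            else:
                write_matrix(sdir / f"{layer}.tsv", data)


def read_cohort_layers(cohort_dir: str | Path):
    """Load a written cohort tree: (atlas, covariates, {subject: {layer: data}}).

    A subject directory missing one of the expected layers aborts with the
    subject and layer named.
    """
    cohort_dir = Path(cohort_dir)
    atlas = read_atlas(cohort_dir / "atlas.csv")
    cov = pd.read_csv(cohort_dir / "covariates.csv", index_col="subject_id")
    layers: dict[str, dict] = {}
    for sid in cov.index:
        sdir = cohort_dir / str(sid)
        layers[sid] = {}
        for layer in LAYER_ORDER:
            fp = sdir / f"{layer}.tsv"
            if not fp.exists():
                raise FileNotFoundError(
                    f"subject {sid!r} is missing layer {layer!r} ({fp})"
                )
            if layer == "dmri":
                layers[sid][layer] = read_matrix(fp, modality="dmri",
                                                 subject_id=str(sid), atlas=atlas)
            else:
                layers[sid][layer] = read_timeseries(fp)
    return atlas, cov, layers


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
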