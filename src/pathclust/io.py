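"""Plain-text readers/writers for the pipeline's tabular artifacts."""

from __future__ import annotations

import pandas as pd

from .distances import DistanceMatrix
from .quantify import SCALE_LOG2

__all__ = [
    "read_intensity_tsv",
    "write_intensity_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_distance_tsv",
    "write_distance_tsv",
]


def read_intensity_tsv(path, scale: str = SCALE_LOG2) -> pd.DataFrame:
    """Protein x sample-replicate intensity matrix (first column = protein_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "protein_id"
    df.attrs["scale"] = scale
    return df


def write_intensity_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6f")


def read_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "replicate" in ann.columns:
        ann["replicate"] = ann["replicate"].astype(int)
    required = {"sample_id", "individual_id", "group"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    return ann


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_distance_tsv(path, metric: str = "", mode: str = "") -> DistanceMatrix:
    """Labelled symmetric distance matrix (first row/column are labels)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.columns = frame.columns.astype(str)
    frame.index = frame.index.astype(str)
    return DistanceMatrix(values=frame, metric=metric, mode=mode)


def write_distance_tsv(D: DistanceMatrix, path) -> None:
    D.values.to_csv(path, sep="\t")
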