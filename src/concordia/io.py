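"""Reading and writing the plain-text formats the pipeline exchanges.

All matrices travel as TSV: first column the feature id (gene, probe or
marker), header row of sample ids. Group labels are a two-column TSV
(sample, group). Copy-number segments may arrive in SEG-like form
(sample, chrom, start, end, log2ratio; 1-based inclusive on disk) and are
rasterized onto a marker grid.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GROUPS, OmicsMatrix


def read_matrix_tsv(path: str | Path, index_name: str = "gene") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = index_name
    return df.astype(float)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_labels_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("labels TSV needs two columns: sample, group")
    labels = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    bad = set(labels.unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels in {path}: {sorted(bad)}")
    return labels


def write_labels_tsv(labels: pd.Series, path: str | Path) -> None:
    out = pd.DataFrame({"sample": labels.index, "group": labels.values})
    out.to_csv(path, sep="\t", index=False)


def read_omics_matrix(
    matrix_path: str | Path,
    labels_path: str | Path,
    modality: str = "expression",
    dataset: str = "",
) -> OmicsMatrix:
    return OmicsMatrix(
        read_matrix_tsv(matrix_path), read_labels_tsv(labels_path), modality, dataset
    )


def read_gene_map_tsv(path: str | Path) -> pd.Series:
    """Two-column TSV (probe-or-marker id, gene) -> Series id→gene."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("map TSV needs two columns: id, gene")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="gene")


def write_gene_map_tsv(mapping: pd.Series, path: str | Path, id_name: str = "marker") -> None:
    out = pd.DataFrame({id_name: mapping.index, "gene": mapping.values})
    out.to_csv(path, sep="\t", index=False)


def read_um_tsv(path: str | Path) -> pd.DataFrame:
    """Long-form methylation intensities: probe, sample, U, M."""
    df = pd.read_csv(path, sep="\t")
    need = {"probe", "sample", "U", "M"}
    if not need.issubset(df.columns):
        raise ValueError(f"U/M TSV needs columns {sorted(need)}")
    if (df[["U", "M"]] < 0).any().any():
        raise ValueError("negative U/M intensities")
    return df


def read_seg_tsv(path: str | Path) -> pd.DataFrame:
    """SEG-like TSV (sample, chrom, start, end, log2ratio), 1-based inclusive.

    Coordinates are converted to 0-based half-open on read.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "chrom", "start", "end", "log2ratio"}
    if not need.issubset(df.columns):
        raise ValueError(f"SEG TSV needs columns {sorted(need)}")
    df = df.copy()
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        raise ValueError("empty or inverted segments")
    return df


def rasterize_segments(
    seg: pd.DataFrame, markers: pd.DataFrame, baseline: float = 0.0
) -> pd.DataFrame:
    """Project segments onto a marker grid, giving a marker×sample matrix.

    ``markers`` has columns marker, chrom, pos (0-based). A marker inside a
    sample's segment takes the segment's log2 ratio; elsewhere ``baseline``.
    Overlapping segments of one sample: the last row wins (input order).
    """
    need = {"marker", "chrom", "pos"}
    if not need.issubset(markers.columns):
        raise ValueError(f"markers frame needs columns {sorted(need)}")
    samples = sorted(seg["sample"].unique())
    mat = pd.DataFrame(
        baseline, index=pd.Index(markers["marker"], name="marker"), columns=samples
    )
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    marker_ids = markers["marker"].to_numpy()
    for row in seg.itertuples(index=False):
        hit = (chrom == row.chrom) & (pos >= row.start) & (pos < row.end)
        mat.loc[marker_ids[hit], row.sample] = row.log2ratio
    return mat


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "direction" in df.columns:
        df["direction"] = df["direction"].astype(int)
    return df


def read_catalog_tsv(path: str | Path) -> pd.DataFrame:
    """Candidate-gene catalog: gene, role, stability, cancer_types (;-joined)."""
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "role", "stability", "cancer_types"}
    if not need.issubset(df.columns):
        raise ValueError(f"catalog TSV needs columns {sorted(need)}")
    df = df.copy()
    df["stability"] = df["stability"].astype(bool)
    df["cancer_types"] = df["cancer_types"].fillna("").map(
        lambda s: tuple(t for t in str(s).split(";") if t)
    )
    return df


def write_catalog_tsv(catalog: pd.DataFrame, path: str | Path) -> None:
    out = catalog.copy()
    out["cancer_types"] = out["cancer_types"].map(";".join)
    out.to_csv(path, sep="\t", index=False)
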