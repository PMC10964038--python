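"""Readers and writers for the pipeline's plain-text formats.

All numeric tables are TSV/CSV with a fixed float format so that
identical inputs produce byte-identical files; gene sets use the
standard GMT layout (name, description, tab-separated members).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_features_tsv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_features_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: feature table contains missing values")
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing cohort columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate subject ids")
    return df


def write_centroids_csv(centroids: pd.DataFrame, path) -> None:
    centroids.to_csv(path, float_format="%.12g")


def read_centroids_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    norms = (df[["x", "y", "z"]] ** 2).sum(axis=1) ** 0.5
    if ((norms - 1.0).abs() > 1e-6).any():
        raise ValueError(f"{path}: centroids are not on the unit sphere")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate region ids")
    return df


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sets[name]]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets


def write_gene_list(genes: list[str], path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gene_list(path) -> list[str]:
    return [g.strip() for g in Path(path).read_text().splitlines() if g.strip()]


def write_deg_tsv(deg: pd.DataFrame, path) -> None:
    deg.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_deg_tsv(path, value_column: str = "value") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or value_column not in df.columns:
        raise ValueError(f"{path}: need columns gene_id and {value_column}")
    if value_column != "value":
        df = df.rename(columns={value_column: "value"})
    return df


def write_probe_data(probes, intensities_path, flags_path) -> None:
    """Probe intensities (probe_id, gene_id, regions...) and 0/1 flags."""
    table = probes.intensities.copy()
    table.insert(0, "gene_id", probes.gene_map)
    table.to_csv(intensities_path, sep="\t", float_format=FLOAT_FORMAT)
    probes.flags.astype(int).to_csv(flags_path, sep="\t")


def read_probe_data(intensities_path, flags_path):
    from .synth import ProbeData

    table = pd.read_csv(intensities_path, sep="\t", index_col=0)
    if "gene_id" not in table.columns:
        raise ValueError(f"{intensities_path}: missing gene_id column")
    if table.index.duplicated().any():
        raise ValueError(f"{intensities_path}: duplicate probe ids")
    gene_map = table["gene_id"]
    intensities = table.drop(columns="gene_id")
    flags = pd.read_csv(flags_path, sep="\t", index_col=0).astype(bool)
    if not flags.index.equals(intensities.index) or list(flags.columns) != list(
        intensities.columns
    ):
        raise ValueError("probe flags do not match intensities layout")
    return ProbeData(intensities=intensities, flags=flags, gene_map=gene_map)


def write_tmap_tsv(tmap: pd.DataFrame, path) -> None:
    tmap.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_tmap_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
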