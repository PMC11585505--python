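"""Readers and writers for the pipeline's plain-text formats.

Beta / intensity / log-ratio matrices travel as TSV (probe rows, sample
columns); sample sheets as CSV; probe manifests as TSV with 1-based
positions; chromosome-arm definitions as BED (0-based half-open); segments
as SEG; gene sets as GMT; reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .preprocess import BetaMatrix, validate_sample_sheet


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "probe")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns.name = "sample"
    return df


def write_beta(beta: BetaMatrix, values_path, detection_path=None) -> None:
    write_matrix(beta.values, values_path)
    if detection_path is not None and beta.detection_p is not None:
        write_matrix(beta.detection_p, detection_path)


def read_beta(values_path, detection_path=None) -> BetaMatrix:
    values = read_matrix(values_path)
    det = read_matrix(detection_path) if detection_path else None
    return BetaMatrix(values, det)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    try:
        return validate_sample_sheet(sheet)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index_label="probe")


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", index_col="probe")
    manifest["gene"] = manifest["gene"].fillna("")
    return manifest


def write_arms_bed(arms: pd.DataFrame, path) -> None:
    arms[["chrom", "start", "end", "arm"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_arms_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "arm"]
    )


def write_seg(segments_frame: pd.DataFrame, path) -> None:
    segments_frame.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict:
    """GMT: one set per line — name, description, then gene symbols."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: GMT line needs name, description, genes")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(collections: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collections.items():
            fh.write("\t".join([name, ""] + list(genes)) + "\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
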