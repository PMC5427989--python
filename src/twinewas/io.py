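"""Plain-text I/O for pipeline artifacts.

Formats: bins as BED3 (0-based half-open, width 500, step 250), methylation
matrix as TSV with a ``bin_id`` first column (``chrom_start``) and one
column per sample-visit, cohort as CSV, reports as JSON. Everything is
diffable text; float columns are written with a fixed ``%.6g`` format so
identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .simulate import BIN_STEP, BIN_WIDTH

__all__ = [
    "read_bed", "write_bed", "read_bin_matrix", "write_bin_matrix",
    "read_cohort", "write_cohort", "write_json",
]

FLOAT_FMT = "%.6g"


def write_bed(bins: pd.DataFrame, path) -> None:
    bins[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, strict: bool = True) -> pd.DataFrame:
    """Read BED3 bin definitions; under ``strict`` validate the 500 bp /
    250 bp-step grid and the 0-based convention."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("expected 3 tab-separated BED fields", ln)
            chrom, start, end = parts[0], parts[1], parts[2]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError("non-integer BED coordinates", ln)
            if start_i < 0 or end_i <= start_i:
                raise ParseError("invalid half-open interval", ln)
            if strict:
                if end_i - start_i != BIN_WIDTH:
                    raise ParseError(
                        f"bin width {end_i - start_i} != {BIN_WIDTH} (strict grid)", ln
                    )
                if start_i % BIN_STEP != 0:
                    raise ParseError(
                        f"start {start_i} not a multiple of {BIN_STEP}; "
                        "1-based coordinates? bins must be 0-based half-open", ln
                    )
            rows.append((chrom, start_i, end_i))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    bins.index = bins["chrom"] + "_" + bins["start"].astype(str)
    bins.index.name = "bin_id"
    return bins


def write_bin_matrix(matrix: pd.DataFrame, bins: pd.DataFrame, bed_path, tsv_path) -> None:
    """Write bins as BED3 and the matrix as TSV (rows = bins, columns =
    sample-visits, first column ``bin_id``)."""
    write_bed(bins, bed_path)
    matrix.T.to_csv(tsv_path, sep="\t", index_label="bin_id", float_format=FLOAT_FMT)


def read_bin_matrix(bed_path, tsv_path, strict: bool = True):
    """Read (BinGrid, MethylationMatrix); bin ids in the TSV must match the
    BED grid exactly."""
    bins = read_bed(bed_path, strict=strict)
    mat = pd.read_csv(tsv_path, sep="\t", index_col="bin_id")
    if list(mat.index) != list(bins.index):
        raise ParseError("matrix bin ids do not match BED bin definitions")
    matrix = mat.T
    matrix.index.name = "sample_id"
    matrix.columns.name = "bin_id"
    return bins, matrix


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_cohort(path) -> pd.DataFrame:
    cohort = pd.read_csv(path, dtype={"smoking": str})
    required = {"sample_id", "individual_id", "family_id", "zygosity", "cwp",
                "age", "bmi", "visit"}
    missing = required - set(cohort.columns)
    if missing:
        raise ParseError(f"cohort table missing columns: {sorted(missing)}")
    return cohort


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True) + "\n")
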