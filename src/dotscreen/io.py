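"""Readers and writers for every on-disk format the pipeline touches.

Membrane images are multi-page 16-bit grayscale TIFFs (page 0 signal,
page 1 loading control); all tables are UTF-8, newline-terminated,
tab-separated with a header row and 1-based grid indices; sequences are
FASTA; configuration is YAML. Readers validate required columns and report
offending columns/rows by name and number; unknown extra columns are
preserved.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO


class SchemaError(ValueError):
    """A file does not match its expected schema."""


def write_membrane_tiff(path: str | os.PathLike, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[0] != 2 or image.dtype != np.uint16:
        raise ValueError("membrane image must be uint16 with shape (2, H, W)")
    tifffile.imwrite(path, image, photometric="minisblack")


def read_membrane_tiff(path: str | os.PathLike) -> np.ndarray:
    if not Path(path).exists():
        raise FileNotFoundError(f"membrane image not found: {path}")
    image = tifffile.imread(path)
    if image.ndim != 3 or image.shape[0] != 2:
        raise SchemaError(
            f"{path}: expected a 2-page TIFF (signal, loading control), "
            f"got shape {image.shape}"
        )
    return image


def write_tsv(path: str | os.PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv(
    path: str | os.PathLike,
    required: Mapping[str, type] | Iterable[str],
    numeric_check: Iterable[str] = (),
) -> pd.DataFrame:
    """Read a TSV table, enforcing required columns and numeric parses.

    Missing columns are reported by name; unparseable numeric values are
    reported with their 1-based data row number. Extra columns pass
    through untouched.
    """
    if not Path(path).exists():
        raise FileNotFoundError(f"table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    names = list(required.keys()) if isinstance(required, Mapping) else list(required)
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in numeric_check:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            rows = ", ".join(str(i + 1) for i in bad[:5])
            raise SchemaError(
                f"{path}: column {col!r} has non-numeric values at row(s) {rows}"
            )
        df[col] = parsed
    return df


PLATE_MAP_COLUMNS = [
    "membrane_id", "row", "col", "bait_id", "prey_id", "bio_rep", "tech_rep",
]


def read_plate_map(path: str | os.PathLike) -> pd.DataFrame:
    return read_tsv(
        path, PLATE_MAP_COLUMNS, numeric_check=["row", "col", "bio_rep", "tech_rep"]
    )


def read_od_table(path: str | os.PathLike) -> pd.DataFrame:
    return read_tsv(path, ["strain_id", "od600"], numeric_check=["od600"])


DOTS_COLUMNS = [
    "membrane_id", "row", "col", "signal_raw", "control_raw",
    "signal_background", "control_background",
    "signal_corrected", "control_corrected", "flags",
]


def read_dots(path: str | os.PathLike) -> pd.DataFrame:
    df = read_tsv(
        path,
        [c for c in DOTS_COLUMNS if c != "flags"],
        numeric_check=["row", "col", "signal_corrected", "control_corrected"],
    )
    if "flags" in df.columns:
        df["flags"] = df["flags"].fillna("")
    return df


def read_annotations(path: str | os.PathLike) -> pd.DataFrame:
    df = read_tsv(path, ["protein_id", "has_sp", "has_tmd", "has_mts"])
    for col in ("has_sp", "has_tmd", "has_mts"):
        df[col] = df[col].map(_parse_bool)
    if "sp_sequence" in df.columns:
        df["sp_sequence"] = df["sp_sequence"].fillna("")
    else:
        df["sp_sequence"] = ""
    return df


def read_preferences(path: str | os.PathLike) -> pd.DataFrame:
    df = read_tsv(
        path, ["prey_id", "signal_A", "signal_B", "category"],
        numeric_check=["signal_A", "signal_B"],
    )
    return df


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "t", "1", "yes", "y"):
        return True
    if s in ("false", "f", "0", "no", "n", "", "nan"):
        return False
    raise SchemaError(f"cannot parse boolean value {v!r}")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA as an id -> sequence mapping; duplicate ids are an error."""
    if not Path(path).exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    seqs: dict[str, str] = {}
    dups = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            dups.append(rec.id)
        seqs[rec.id] = str(rec.seq)
    if dups:
        raise SchemaError(f"{path}: duplicate FASTA ids: {sorted(set(dups))}")
    return seqs


def write_fasta(path: str | os.PathLike, seqs: Mapping[str, str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def load_yaml(path: str | os.PathLike) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(path: str | os.PathLike, data: Mapping) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=False)
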