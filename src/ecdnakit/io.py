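"""Readers and writers for the plain-text formats used across the package.

Conventions: genomic intervals are 0-based half-open (BED); 1-based closed
input is accepted only via an explicit ``one_based=True`` reader flag.
Spot coordinates are micrometres internally; nanometre tables are converted
on read/write via ``unit="nm"``.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path

import pandas as pd


class ConfigError(ValueError):
    """Invalid configuration (bad field value, inconsistent schema)."""


class DataError(ValueError):
    """Malformed or inconsistent input data."""


SPOT_COLUMNS = ["cell_id", "locus", "x_um", "y_um", "z_um"]
READ_BLOCK_COLUMNS = ["read_id", "chrom", "start", "end"]
BED_COLUMNS = ["chrom", "start", "end"]

_SAMPLE_RE = re.compile(r"^d(?P<day>\d+(?:\.\d+)?)_r(?P<rep>\d+)$")


def sample_columns(df: pd.DataFrame) -> list[str]:
    """Guide-count sample columns, named ``d<day>_r<replicate>``."""
    return [c for c in df.columns if _SAMPLE_RE.match(str(c))]


def parse_sample(col: str) -> tuple[float, int]:
    m = _SAMPLE_RE.match(col)
    if m is None:
        raise DataError(f"sample column {col!r} does not parse as d<day>_r<rep>")
    return float(m.group("day")), int(m.group("rep"))


# ---------------------------------------------------------------------------
# Spot tables

def read_spot_table(path, unit: str = "um") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if unit == "nm":
        rename = {c: c.replace("_nm", "_um") for c in cols if c.endswith("_nm")}
        df = df.rename(columns=rename)
        for c in ("x_um", "y_um", "z_um"):
            df[c] = df[c] / 1000.0
    elif unit != "um":
        raise ConfigError(f"unit must be 'um' or 'nm', got {unit!r}")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"spot table missing columns {missing}")
    return df[SPOT_COLUMNS + [c for c in df.columns if c not in SPOT_COLUMNS]]


def write_spot_table(df: pd.DataFrame, path, unit: str = "um") -> None:
    out = df.copy()
    if unit == "nm":
        for c in ("x_um", "y_um", "z_um"):
            out[c.replace("_um", "_nm")] = out[c] * 1000.0
        out = out.drop(columns=["x_um", "y_um", "z_um"])
    elif unit != "um":
        raise ConfigError(f"unit must be 'um' or 'nm', got {unit!r}")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED intervals

def read_bed(path, one_based: bool = False) -> pd.DataFrame:
    """Read a BED-like file; column 4 (if present) is kept as ``name``.

    With ``one_based=True`` coordinates are interpreted as 1-based closed
    and converted to 0-based half-open on read.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name"})
    if one_based:
        df["start"] = df["start"] - 1
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        raise DataError(f"{len(bad)} intervals with start >= end in {path}")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Contact matrices (bg2-style text)

def read_contacts(path):
    """Read a headered contact TSV (chrom1 start1 chrom2 start2 count).

    A comment line ``# bin_size=<bp>`` declares the bin size. Returns a
    :class:`~ecdnakit.eie_discovery.ContactMatrix`.
    """
    from .eie_discovery import ContactMatrix

    bin_size = None
    with open(path) as fh:
        head = []
        for line in fh:
            if line.startswith("#"):
                m = re.search(r"bin_size\s*=\s*(\d+)", line)
                if m:
                    bin_size = int(m.group(1))
            else:
                head.append(line)
                break
        body = "".join(head) + fh.read()
    if bin_size is None:
        raise DataError(f"no '# bin_size=' comment line in {path}")
    df = pd.read_csv(_io.StringIO(body), sep="\t")
    need = ["chrom1", "start1", "chrom2", "start2", "count"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise DataError(f"contact table missing columns {missing}")
    return ContactMatrix(bin_size=bin_size, pairs=df[need])


def write_contacts(cm, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_size={cm.bin_size}\n")
        cm.pairs.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Guide count and read-block tables

def read_guide_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = ["guide_id", "element", "is_ntc", "specificity"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise DataError(f"guide table missing columns {missing}")
    if not sample_columns(df):
        raise DataError("guide table has no d<day>_r<rep> sample columns")
    df["is_ntc"] = df["is_ntc"].astype(bool)
    return df


def write_guide_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_read_blocks(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in READ_BLOCK_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"read-block table missing columns {missing}")
    return df


def write_read_blocks(df: pd.DataFrame, path) -> None:
    df[READ_BLOCK_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
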