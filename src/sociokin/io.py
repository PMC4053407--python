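"""Readers and writers for telemetry fixes, genotype tables, dyadic
matrices and individual metadata.

All formats are plain CSV.  Every reader/writer pair is a lossless round
trip at the declared write precision (12 significant digits for floats).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .genetics import GenotypeTable
from .matrices import DyadicMatrix, MatrixFormatError

logger = logging.getLogger(__name__)

FIX_COLUMNS = ["individual_id", "timestamp", "x", "y"]
_FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    pass


class EmptyInputError(ParseError):
    pass


# ---------------------------------------------------------------------------
# telemetry fixes
# ---------------------------------------------------------------------------

def read_fixes(path: str | Path, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Read telemetry fixes (columns id, timestamp, x, y) from CSV.

    Returns a DataFrame with columns ``individual_id`` (str), ``timestamp``
    (datetime64), ``x``, ``y`` (float metres, projected CRS), sorted by
    (individual_id, timestamp).  Duplicate (id, timestamp) rows are
    dropped with a warning; malformed rows raise :class:`ParseError`
    naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise EmptyInputError(f"{path}: no fix records")
    cols = {c.lower().strip(): c for c in df.columns}
    rename = {}
    for want, aliases in {
        "individual_id": ("individual_id", "id", "individual"),
        "timestamp": ("timestamp", "time", "datetime"),
        "x": ("x",),
        "y": ("y",),
    }.items():
        found = next((cols[a] for a in aliases if a in cols), None)
        if found is None:
            raise ParseError(f"{path}: missing required column {want!r}")
        rename[found] = want
    df = df.rename(columns=rename)[FIX_COLUMNS]

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0])
        raise ParseError(
            f"{path}: unparseable timestamp {df['timestamp'].iloc[row]!r} "
            f"on data line {row + 2}"
        )
    out = pd.DataFrame({"individual_id": df["individual_id"].astype(str)})
    out["timestamp"] = ts
    for c in ("x", "y"):
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = ~np.isfinite(vals)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: non-numeric coordinate {df[c].iloc[row]!r} in column "
                f"{c!r} on data line {row + 2}"
            )
        out[c] = vals.astype(float)

    n_raw = len(out)
    out = out.drop_duplicates(subset=["individual_id", "timestamp"])
    dropped = n_raw - len(out)
    if dropped:
        logger.warning("%s: dropped %d duplicate (id, timestamp) rows", path, dropped)
    out = out.sort_values(["individual_id", "timestamp"], kind="stable").reset_index(drop=True)
    logger.info("%s: parsed %d fixes for %d individuals (%d dropped)",
                path, len(out), out["individual_id"].nunique(), dropped)
    return out


def write_fixes(fixes: pd.DataFrame, path: str | Path) -> None:
    df = fixes[FIX_COLUMNS].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, missing_token: str = "0") -> GenotypeTable:
    """Read a genotype table: first column individual id, one column per
    locus, cells "allele1/allele2" or the missing token."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, index_col=0)
    if df.empty or not len(df.columns):
        raise EmptyInputError(f"{path}: no genotype records")
    table = GenotypeTable.from_frame(df, missing_token=missing_token)
    logger.info("%s: missing fraction %.4f", path, table.missing_fraction())
    return table


def write_genotypes(g: GenotypeTable, path: str | Path, missing_token: str = "0") -> None:
    g.to_frame(missing_token=missing_token).to_csv(path)


# ---------------------------------------------------------------------------
# dyadic matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, kind: str = "association") -> DyadicMatrix:
    """Read a labelled square symmetric matrix CSV (first row and first
    column are id labels).  Asymmetries beyond 1e-9 and out-of-range
    values for the declared kind are rejected."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if len(ids) != len(col_ids):
        raise MatrixFormatError(f"{path}: matrix is not square "
                                f"({len(ids)} rows, {len(col_ids)} columns)")
    if ids != col_ids:
        raise MatrixFormatError(f"{path}: row and column labels differ")
    try:
        return DyadicMatrix(ids, df.to_numpy(dtype=float), kind=kind)
    except MatrixFormatError as err:
        raise MatrixFormatError(f"{path}: {err}") from err


def write_matrix(m: DyadicMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.values, index=m.ids, columns=m.ids)
    df.to_csv(path, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# individual metadata (sex / age class per tracking year)
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read metadata.csv with columns id, sex, age_class and optional year."""
    df = pd.read_csv(path, dtype=str)
    need = {"id", "sex", "age_class"}
    missing = need - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    df["id"] = df["id"].astype(str)
    return df
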