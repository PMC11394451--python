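"""Readers and writers for the plain-text formats used by the pipeline.

* GenomeStudio-style "final report" tables: tab-separated text with a
  header line declaring at least Sample ID, SNP Name, Chr, Position,
  B Allele Freq and Log R Ratio (any column order; extra columns ignored).
* STR panel tables: CSV, one row per individual/tissue, allele pairs
  rendered ``"a/b"`` in base pairs and presence flags ``"+"``/``"-"``.
* Pedigree tables: CSV with id, sire, dam (0 or empty = unknown parent).
"""

from __future__ import annotations

import io as _io
import logging
from typing import Iterable, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("equicna")

FINAL_REPORT_COLUMNS = {
    "sample id": "sample_id",
    "snp name": "snp_name",
    "chr": "chrom",
    "position": "position",
    "b allele freq": "baf",
    "log r ratio": "lrr",
}

RECORD_SCHEMA = ["sample_id", "snp_name", "chrom", "position", "baf", "lrr"]


def read_final_report(source) -> pd.DataFrame:
    """Parse a final-report stream/path into the SNP record frame.

    Returns a DataFrame with columns sample_id, snp_name, chrom (str),
    position (int), baf, lrr (float, NaN when unparsable).  Raises
    ``ValueError`` when a required column is missing.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, comment=None)
    colmap = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in FINAL_REPORT_COLUMNS:
            colmap[col] = FINAL_REPORT_COLUMNS[key]
    missing = set(FINAL_REPORT_COLUMNS.values()) - set(colmap.values())
    if missing:
        raise ValueError(f"final report is missing required columns: {sorted(missing)}")
    df = df.rename(columns=colmap)[RECORD_SCHEMA]
    df["chrom"] = df["chrom"].astype(str).str.strip()
    pos = pd.to_numeric(df["position"], errors="coerce")
    bad_pos = pos.isna()
    if bad_pos.any():
        logger.info("final report: skipped %d lines with unparsable position", int(bad_pos.sum()))
        df = df[~bad_pos]
        pos = pos[~bad_pos]
    df["position"] = pos.astype(np.int64)
    for col in ("baf", "lrr"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    n_miss = int(df[["baf", "lrr"]].isna().any(axis=1).sum())
    if n_miss:
        logger.info("final report: %d records carry missing BAF and/or LRR", n_miss)
    return df.reset_index(drop=True)


def write_final_report(records: pd.DataFrame, path_or_buf) -> None:
    """Write SNP records as GenomeStudio-style final-report text.

    BAF and LRR are rounded to 4 decimals; missing values are written as
    ``NaN`` (as GenomeStudio does for failed calls).
    """
    out = records[RECORD_SCHEMA].copy()
    out.columns = ["Sample ID", "SNP Name", "Chr", "Position", "B Allele Freq", "Log R Ratio"]
    out["B Allele Freq"] = out["B Allele Freq"].round(4)
    out["Log R Ratio"] = out["Log R Ratio"].round(4)
    out.to_csv(path_or_buf, sep="\t", index=False, na_rep="NaN")


def format_genotype(alleles: Union[tuple, list]) -> str:
    """Render one or two allele lengths as Table-style text, e.g. '194/210'."""
    uniq = sorted(set(int(a) for a in alleles))
    return "/".join(str(a) for a in uniq)


def parse_genotype(text) -> tuple:
    """Parse '194/210' (or a single length) into a tuple of ints."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return ()
    parts = str(text).strip().split("/")
    return tuple(int(float(p)) for p in parts if p not in ("", "-"))


def format_flag(present: bool) -> str:
    return "+" if present else "-"


def parse_flag(text) -> bool:
    t = str(text).strip()
    if t in {"+", "1", "True", "true"}:
        return True
    if t in {"-", "−", "0", "False", "false", ""}:  # ASCII or Unicode minus
        return False
    raise ValueError(f"cannot parse presence flag {text!r}")


def read_pedigree_csv(source) -> pd.DataFrame:
    """Read an id/sire/dam CSV (optional birth date and sex columns)."""
    df = pd.read_csv(source, dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    for required in ("id", "sire", "dam"):
        if required not in df.columns:
            raise ValueError(f"pedigree CSV is missing column {required!r}")
    for col in ("sire", "dam"):
        df[col] = df[col].replace({"0": "", "0.0": ""})
    return df


def write_pedigree_csv(rows: Iterable[dict], path_or_buf) -> None:
    df = pd.DataFrame(rows)
    df.to_csv(path_or_buf, index=False)


def as_stream(text: str):
    """Wrap literal text as a readable stream (handy for fixtures/tests)."""
    return _io.StringIO(text)
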