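"""Reading and writing the study's delimited-text formats.

Input is a delimited table (comma or tab, autodetected) with one row per
(individual, phase) and wide cortisol columns, optionally accompanied by a
long-form retreat-record file. Because supplementary data files rarely agree
on column names, the reader accepts a user-configurable schema mapping from
the canonical column names to whatever the file uses.

Result tables are written as TSV at full precision so that a write/read
round trip is lossless.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

from .data import SAMPLING_TIMES, StudyDataset
from .errors import SchemaError

log = logging.getLogger(__name__)

#: Canonical wide-table columns (one row per individual x phase).
WIDE_COLUMNS = (
    "individual_id", "group_id", "phase", "age_days",
    "weight_start", "weight_end",
    "cortisol_baseline", "cortisol_resp_1h", "cortisol_resp_2h",
    "rank_index",
)

#: Canonical retreat-file columns (one row per observed retreat).
RETREAT_COLUMNS = ("focal_id", "opponent_id", "phase", "day_index", "focal_won")

PathLike = Union[str, Path]


def _sniff_sep(path: Path) -> str:
    sample = path.read_text().splitlines()[0] if path.stat().st_size else ""
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def _read_delimited(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sniff_sep(path))


def _apply_schema(df: pd.DataFrame, schema: Optional[Mapping[str, str]],
                  required: tuple, what: str) -> pd.DataFrame:
    """Rename file columns to canonical names and check completeness."""
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what}: missing required column(s) {', '.join(missing)} "
            f"(have: {', '.join(map(str, df.columns))})"
        )
    return df


def read_dataset(
    path: PathLike,
    schema: Optional[Mapping[str, str]] = None,
    retreats_path: Optional[PathLike] = None,
    retreats_schema: Optional[Mapping[str, str]] = None,
) -> StudyDataset:
    """Read a wide per-test table (and optional retreat file) and validate.

    Parameters
    ----------
    path
        Delimited text file, one row per (individual, phase), with the
        columns in :data:`WIDE_COLUMNS` (after schema mapping).
    schema
        Optional mapping ``canonical_name -> file_column_name``.
    retreats_path, retreats_schema
        Optional long-form retreat records with :data:`RETREAT_COLUMNS`.
    """
    df = _apply_schema(_read_delimited(path), schema, WIDE_COLUMNS, str(path))
    df = df.copy()
    df["phase"] = df["phase"].astype(int)

    individuals = (
        df[["individual_id", "group_id"]].drop_duplicates("individual_id")
        .reset_index(drop=True)
    )
    tests = df[["individual_id", "phase", "age_days",
                "weight_start", "weight_end"]].copy()
    tests["weight_change_abs"] = (
        (tests["weight_start"] - tests["weight_end"]).abs()
    )
    samples = df.melt(
        id_vars=["individual_id", "phase"],
        value_vars=[f"cortisol_{t}" for t in SAMPLING_TIMES],
        var_name="sampling_time",
        value_name="concentration",
    )
    samples["sampling_time"] = samples["sampling_time"].str.removeprefix(
        "cortisol_"
    )
    rank = df[["individual_id", "phase", "rank_index"]].rename(
        columns={"rank_index": "index"}
    )

    retreats = None
    if retreats_path is not None:
        rdf = _apply_schema(
            _read_delimited(retreats_path), retreats_schema,
            RETREAT_COLUMNS, str(retreats_path),
        ).copy()
        rdf["phase"] = rdf["phase"].astype(int)
        rdf["day_index"] = rdf["day_index"].astype(int)
        rdf["focal_won"] = rdf["focal_won"].astype(bool)
        retreats = rdf[list(RETREAT_COLUMNS)]

    ds = StudyDataset(individuals, tests, samples, rank, retreats)
    ds.validate()
    log.info(
        "read %d individuals, %d tests, %d samples, %d rank records%s",
        len(individuals), len(tests), len(samples), len(rank),
        f", {len(retreats)} retreats" if retreats is not None else "",
    )
    return ds


def write_dataset(dataset: StudyDataset, path: PathLike,
                  retreats_path: Optional[PathLike] = None,
                  sep: str = "\t") -> None:
    """Write a StudyDataset back to the wide per-test layout."""
    wide = dataset.per_test_table()[list(WIDE_COLUMNS)]
    wide.to_csv(path, sep=sep, index=False)
    if retreats_path is not None and dataset.retreats is not None:
        dataset.retreats[list(RETREAT_COLUMNS)].to_csv(
            retreats_path, sep=sep, index=False
        )


# ----------------------------------------------------------------------
# result tables


def write_report(bundle, outdir: PathLike) -> dict:
    """Write the result bundle as TSV tables; returns name -> path.

    Tables: adjusted repeatability per trait, fixed-effect tables for the
    rank-index and weight-change models, the rank-cortisol model table with
    its marginal means and pairwise contrasts, and the paired-bootstrap
    variance-component comparisons.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, frame in bundle.tables().items():
        p = outdir / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        written[name] = p
    return written


def read_table(path: PathLike) -> pd.DataFrame:
    """Read back a TSV result table at full precision."""
    return pd.read_csv(path, sep="\t")


# ----------------------------------------------------------------------
# configuration


def read_config(path: PathLike) -> dict:
    """Read a YAML key-value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: expected a YAML mapping at top level")
    return cfg
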