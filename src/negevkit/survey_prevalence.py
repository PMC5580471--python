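"""Field-survey screening tabulation: totals, positives and prevalence.

Rows are (site, country, lat, lon, species, stage, n screened, n positive).
Missing site x species x stage cells are absent rows, never zeros, so they
do not contribute to denominators.  A fixture with the geometrid-moth
screening survey of the Abisko virus (six Fennoscandian sites, larvae /
pupae / adults of *Epirrita autumnata* and *Operophtera brumata*) ships with
the package.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .genome_annotation import InputError

STAGES = ("larva", "pupa", "adult")
COLUMNS = ["site", "country", "lat", "lon", "species", "stage", "n", "n_pos"]


def fixture_path() -> Path:
    """Path of the bundled moth screening-survey table."""
    return Path(resources.files("negevkit") / "data" / "moth_survey.csv")


def read_survey(path: str | Path) -> pd.DataFrame:
    """Read and validate a survey CSV."""
    df = pd.read_csv(path)
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"survey table missing columns: {sorted(missing)}")
    return validate_survey(df)


def validate_survey(df: pd.DataFrame) -> pd.DataFrame:
    if (df["n_pos"] > df["n"]).any():
        raise InputError("n_pos exceeds n in at least one row")
    if (df["n"] < 0).any() or (df["n_pos"] < 0).any():
        raise InputError("negative counts")
    if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
        raise InputError("coordinates out of range")
    bad = set(df["stage"]) - set(STAGES)
    if bad:
        raise InputError(f"unknown life stages: {sorted(bad)}")
    return df


def tally(table: pd.DataFrame, by: Sequence[str] = ("species", "stage")) -> pd.DataFrame:
    """Screening totals and prevalence per group.

    Returns one row per group with n, n_pos and prevalence = n_pos / n
    (NaN where n = 0).  An empty input yields an empty result.
    """
    validate_survey(table)
    if table.empty:
        return pd.DataFrame(columns=[*by, "n", "n_pos", "prevalence"])
    g = table.groupby(list(by), as_index=False)[["n", "n_pos"]].sum()
    g["prevalence"] = g["n_pos"] / g["n"].where(g["n"] > 0)
    return g


def positive_sites(table: pd.DataFrame) -> int:
    """Number of distinct sites with at least one positive sample."""
    validate_survey(table)
    return int(table.loc[table["n_pos"] > 0, "site"].nunique())
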