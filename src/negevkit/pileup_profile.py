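"""Per-position consensus, coverage and minor-allele-frequency profiles.

Input is a simplified per-position base-count table (pos, A, C, G, T, other)
— the minimal sufficient statistic of a read pileup; indels and clipped
bases belong in "other".  The profile gives, per position, the majority-base
consensus, total coverage, and the minor allele frequency (MAF): the
frequency of the most frequent non-consensus base relative to coverage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genome_annotation import InputError

BASE_COLS = ["A", "C", "G", "T"]
COUNT_COLS = BASE_COLS + ["other"]


def read_pileup_tsv(path: str | Path) -> pd.DataFrame:
    """Read a base-count TSV with columns pos, A, C, G, T[, other]."""
    df = pd.read_csv(path, sep="\t")
    missing = {"pos", *BASE_COLS} - set(df.columns)
    if missing:
        raise InputError(f"pileup table missing columns: {sorted(missing)}")
    if "other" not in df.columns:
        df["other"] = 0
    return df[["pos"] + COUNT_COLS]


def profile(columns: pd.DataFrame) -> pd.DataFrame:
    """Consensus / coverage / MAF per position.

    Consensus is the majority base among A/C/G/T (ties broken
    lexicographically and flagged, never silently); "other" counts enter
    coverage but are never the consensus.  Zero coverage yields consensus N
    and undefined (NaN) MAF.  Positions must be strictly increasing.
    """
    pos = columns["pos"].to_numpy()
    if len(pos) == 0:
        raise InputError("empty pileup")
    if (np.diff(pos) <= 0).any():
        raise InputError("positions must be strictly increasing (no duplicates)")
    counts = columns[BASE_COLS].to_numpy(dtype=np.int64)
    if (counts < 0).any() or (columns["other"].to_numpy() < 0).any():
        raise InputError("negative counts")
    coverage = counts.sum(axis=1) + columns["other"].to_numpy(dtype=np.int64)

    order = np.argsort(-counts, axis=1, kind="stable")  # stable => lexicographic ties
    top_idx = order[:, 0]
    top = np.take_along_axis(counts, order[:, :2], axis=1)
    consensus = np.array(BASE_COLS)[top_idx]
    tie = top[:, 0] == top[:, 1]

    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(coverage > 0, top[:, 1] / coverage, np.nan)
    zero = coverage == 0
    consensus = np.where(zero, "N", consensus)
    maf = np.where(zero, np.nan, maf)
    return pd.DataFrame(
        {
            "pos": pos,
            "coverage": coverage,
            "consensus": consensus,
            "maf": maf,
            "tie": tie & ~zero,
        }
    )


def consensus_sequence(prof: pd.DataFrame) -> str:
    """Consensus string over the profiled positions (N where uncovered)."""
    return "".join(prof["consensus"])


def summarize_profile(prof: pd.DataFrame, maf_threshold: float = 0.1) -> dict:
    """Genome-level summary: coverage moments and variable-site statistics."""
    if prof.empty:
        raise InputError("empty profile")
    maf = prof["maf"]
    defined = maf.notna()
    variable = (maf > maf_threshold) & defined
    max_idx = maf.idxmax() if defined.any() else None
    return {
        "n_positions": int(len(prof)),
        "mean_coverage": float(prof["coverage"].mean()),
        "median_coverage": float(prof["coverage"].median()),
        "maf_threshold": maf_threshold,
        "variable_fraction": float(variable.sum() / len(prof)),
        "n_variable": int(variable.sum()),
        "max_maf": float(maf.max()) if defined.any() else None,
        "max_maf_pos": int(prof.loc[max_idx, "pos"]) if max_idx is not None else None,
    }


def write_outputs(prof: pd.DataFrame, outdir: str | Path, name: str = "pileup") -> None:
    """Write profile CSV, consensus FASTA and summary JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prof.to_csv(outdir / f"{name}_profile.csv", index=False)
    seq = consensus_sequence(prof)
    (outdir / f"{name}_consensus.fasta").write_text(f">{name}_consensus\n{seq}\n")
    with open(outdir / f"{name}_summary.json", "w") as fh:
        json.dump(summarize_profile(prof), fh, indent=2)
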