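"""Compositional statistics of viral sequences.

Mononucleotide and dinucleotide frequencies, dinucleotide relative-abundance
ratios (observed / expected under mononucleotide independence) decomposed by
codon region, codon usage with RSCU, and translation-initiation-context
frequency matrices.  These are the inputs of the correspondence-analysis
host-attribution step: virus genomes tend to mimic the compositional biases
of their hosts, so insect- and plant-infecting viruses separate on these
statistics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .genome_annotation import InputError, KozakContext

BASES = "ACGT"
DINUCLEOTIDES = [a + b for a in BASES for b in BASES]
FrameMode = Literal["all", "p12", "p23", "p31"]
FRAME_MODES: tuple[FrameMode, ...] = ("all", "p12", "p23", "p31")

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(_table.stop_codons)
SENSE_CODONS = tuple(sorted(_table.forward_table))
ALL_CODONS = tuple(sorted(SENSE_CODONS + STOP_CODONS))

#: synonymous families of the standard genetic code, amino acid -> codons
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in _table.forward_table.items() if a == aa))
    for aa in sorted(set(_table.forward_table.values()))
}


def mono_freqs(seq: str) -> dict[str, float]:
    """Frequencies of A, C, G, T among the unambiguous bases of ``seq``."""
    counts = {b: seq.count(b) for b in BASES}
    total = sum(counts.values())
    if total == 0:
        raise InputError("no unambiguous bases to count")
    return {b: c / total for b, c in counts.items()}


def _pair_starts(n: int, frame_mode: FrameMode) -> range:
    if frame_mode == "all":
        return range(n - 1)
    if frame_mode == "p12":
        return range(0, n - 1, 3)
    if frame_mode == "p23":
        return range(1, n - 1, 3)
    if frame_mode == "p31":
        # codon position 3 bridging into position 1 of the next codon
        return range(2, n - 1, 3)
    raise InputError(f"unknown frame mode {frame_mode!r}")


def dinuc_freqs(seq: str, frame_mode: FrameMode = "all") -> dict[str, float]:
    """Observed dinucleotide frequencies for one codon-region mode.

    Pairs containing ambiguity codes are skipped.  For the positional modes
    the sequence must be a CDS (length divisible by 3).
    """
    if len(seq) < 2:
        raise InputError("need at least 2 bases")
    if frame_mode != "all" and len(seq) % 3:
        raise InputError("positional frame modes require a CDS (length % 3 == 0)")
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    total = 0
    for i in _pair_starts(len(seq), frame_mode):
        pair = seq[i : i + 2]
        if pair in counts:
            counts[pair] += 1
            total += 1
    if total == 0:
        raise InputError("no countable dinucleotide pairs")
    return {d: c / total for d, c in counts.items()}


def dinuc_bias(seq: str, frame_mode: FrameMode = "all") -> dict[str, float]:
    """Dinucleotide relative abundance rho(XY) = f_obs(XY) / (f(X) * f(Y)).

    Expected frequencies are products of the whole-sequence mononucleotide
    frequencies; rho is 1 under independence.  Ratios whose expected
    frequency is zero are undefined and returned as NaN.
    """
    obs = dinuc_freqs(seq, frame_mode)
    mono = mono_freqs(seq)
    out = {}
    for d in DINUCLEOTIDES:
        exp = mono[d[0]] * mono[d[1]]
        out[d] = obs[d] / exp if exp > 0 else math.nan
    return out


@dataclass
class CodonUsage:
    codon_freq: dict[str, float]
    rscu: dict[str, float]
    n_codons: int
    undefined_families: list[str] = field(default_factory=list)


def codon_usage(cds: str, include_stops: bool = False) -> CodonUsage:
    """Codon frequencies and relative synonymous codon usage of a CDS.

    RSCU(c) = count(c) / mean count over c's synonymous family, so each
    family with nonzero usage averages to 1.  A single terminal stop codon is
    trimmed unless ``include_stops``; codons with ambiguity codes are skipped.
    Families never used are flagged undefined (NaN), not divided by zero.
    """
    if len(cds) % 3:
        raise InputError("CDS length must be divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if not include_stops and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    counted = ALL_CODONS if include_stops else SENSE_CODONS
    counts = dict.fromkeys(counted, 0)
    for c in codons:
        if c in counts:
            counts[c] += 1
    n = sum(counts.values())
    if n == 0:
        raise InputError("no countable codons")
    freq = {c: k / n for c, k in counts.items()}
    rscu: dict[str, float] = {}
    undefined = []
    for aa, family in SYNONYMOUS_FAMILIES.items():
        total = sum(counts[c] for c in family)
        if total == 0:
            undefined.append(aa)
            for c in family:
                rscu[c] = math.nan
        else:
            mean = total / len(family)
            for c in family:
                rscu[c] = counts[c] / mean
    return CodonUsage(codon_freq=freq, rscu=rscu, n_codons=n, undefined_families=undefined)


# six scored flank positions of the -3..+6 initiation window
INIT_POSITIONS = ("-3", "-2", "-1", "+4", "+5", "+6")
_CTX_INDEX = {"-3": 0, "-2": 1, "-1": 2, "+4": 6, "+5": 7, "+6": 8}


@dataclass
class InitContextMatrix:
    """Per-position base counts/frequencies over initiation-context flanks."""

    counts: pd.DataFrame  # index INIT_POSITIONS, columns BASES
    frequencies: pd.DataFrame
    n_contexts: int

    def to_csv(self, path) -> None:
        self.frequencies.to_csv(path, index_label="position")


def init_context_matrix(contexts: Iterable[KozakContext]) -> InitContextMatrix:
    """Tabulate base frequencies at -3..-1 and +4..+6 over full 9-mer contexts.

    Truncated contexts are excluded.  With no usable context the count matrix
    is zero and frequencies are NaN.
    """
    counts = pd.DataFrame(0, index=list(INIT_POSITIONS), columns=list(BASES))
    n = 0
    for ctx in contexts:
        if ctx.truncated or len(ctx.sequence) != 9:
            continue
        for pos, idx in _CTX_INDEX.items():
            base = ctx.sequence[idx]
            if base in BASES:
                counts.loc[pos, base] += 1
        n += 1
    if n:
        freqs = counts.div(counts.sum(axis=1), axis=0)
    else:
        freqs = counts.astype(float) * math.nan
    return InitContextMatrix(counts=counts, frequencies=freqs, n_contexts=n)


HostType = Literal["insect", "plant", "unknown"]


@dataclass
class CompositionProfile:
    """Full compositional fingerprint of one (concatenated-CDS) sequence."""

    label: str
    host_type: HostType
    mono: dict[str, float]
    dinuc_bias: dict[FrameMode, dict[str, float]]
    codon_freq: dict[str, float]
    rscu: dict[str, float]
    n_codons: int

    @classmethod
    def from_cds(cls, label: str, cds: str, host_type: HostType = "unknown") -> "CompositionProfile":
        usage = codon_usage(cds)
        return cls(
            label=label,
            host_type=host_type,
            mono=mono_freqs(cds),
            dinuc_bias={m: dinuc_bias(cds, m) for m in FRAME_MODES},
            codon_freq=usage.codon_freq,
            rscu=usage.rscu,
            n_codons=usage.n_codons,
        )


def profile_matrix(
    profiles: Iterable[CompositionProfile],
    statistic: str = "rscu",
) -> pd.DataFrame:
    """Stack profiles into a (sequences x categories) nonnegative matrix.

    ``statistic`` is ``"rscu"``, ``"codon_freq"`` or ``"dinuc:<mode>"``
    (e.g. ``dinuc:all``).  NaN entries (undefined families/ratios) become 0;
    correspondence analysis downstream drops zero-mass columns explicitly.
    """
    if statistic not in ("rscu", "codon_freq") and not (
        statistic.startswith("dinuc:") and statistic.split(":", 1)[1] in FRAME_MODES
    ):
        raise InputError(f"unknown statistic {statistic!r}")
    rows = {}
    for p in profiles:
        if statistic == "rscu":
            rows[p.label] = p.rscu
        elif statistic == "codon_freq":
            rows[p.label] = p.codon_freq
        elif statistic.startswith("dinuc:"):
            mode = statistic.split(":", 1)[1]
            if mode not in FRAME_MODES:
                raise InputError(f"unknown dinucleotide mode {mode!r}")
            rows[p.label] = p.dinuc_bias[mode]  # type: ignore[index]
        else:
            raise InputError(f"unknown statistic {statistic!r}")
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)


def profiles_to_tidy(profiles: Iterable[CompositionProfile]) -> pd.DataFrame:
    """Tidy long-format table: one row per sequence x statistic x category."""
    records = []
    for p in profiles:
        for b, v in p.mono.items():
            records.append((p.label, p.host_type, "mono", "all", b, v))
        for mode, ratios in p.dinuc_bias.items():
            for d, v in ratios.items():
                records.append((p.label, p.host_type, "dinuc_bias", mode, d, v))
        for c, v in p.codon_freq.items():
            records.append((p.label, p.host_type, "codon_freq", "all", c, v))
        for c, v in p.rscu.items():
            records.append((p.label, p.host_type, "rscu", "all", c, v))
    return pd.DataFrame(
        records, columns=["label", "host_type", "statistic", "mode", "category", "value"]
    )
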