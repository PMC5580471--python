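"""Absolute quantification from strand-specific RT-qPCR measurements.

The quantification cycle Cq is linear in log10 of the starting template:
Cq = slope * log10(copies) + intercept, fitted on a 10-fold dilution series
of a cloned standard of known concentration.  Amplification efficiency is
10^(-1/slope) - 1 (100% at slope = -1/log10(2) ~ -3.32).  Copies per
reaction are scaled to copies per individual insect through the sample
dilution chain.  Positivity is called against a detection threshold of
Cq = 35 with melting-curve gating; matched positive/negative-strand assay
pairs yield strand ratios, and comparing assays in the genomic-only region
against the genomic+subgenomic region tests for subgenomic-RNA excess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_annotation import InputError

#: default detection threshold (Cq); at or above it a measurement is negative
DEFAULT_CQ_THRESHOLD = 35.0
#: |mean Cq - threshold| below which a call is flagged near-threshold
NEAR_THRESHOLD_CQ = 0.5

Strand = Literal["positive", "negative"]
Region = Literal["g", "g_sg"]  # genomic-only vs genomic+subgenomic


@dataclass
class CalibrationCurve:
    slope: float  # Cq per log10(copies); negative
    intercept: float  # Cq at 1 copy
    r2: float
    efficiency: float  # fraction; 1.0 = doubling every cycle
    range_log10: tuple[float, float]  # fitted dynamic range in log10(copies)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise InputError("calibration slope must be negative")


def fit_calibration(series: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Least-squares calibration line from (known_copies, cq) pairs.

    Requires at least three points at distinct concentrations.
    """
    if len(series) < 3:
        raise InputError("calibration needs >= 3 points")
    copies = np.array([c for c, _ in series], dtype=float)
    cqs = np.array([q for _, q in series], dtype=float)
    if (copies <= 0).any():
        raise InputError("calibration copies must be positive")
    x = np.log10(copies)
    if np.ptp(x) == 0:
        raise InputError("calibration points must span distinct concentrations")
    fit = stats.linregress(x, cqs)
    slope = float(fit.slope)
    if slope >= 0:
        raise InputError("calibration slope is nonnegative; check input")
    return CalibrationCurve(
        slope=slope,
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        efficiency=10 ** (-1 / slope) - 1,
        range_log10=(float(x.min()), float(x.max())),
    )


@dataclass
class CopyEstimate:
    copies: Optional[float]  # None when below detection / no amplification
    extrapolated: bool = False
    below_detection: bool = False


def cq_to_copies(curve: CalibrationCurve, cq: Optional[float]) -> CopyEstimate:
    """Invert the calibration line; an absent Cq reports below-detection.

    Values outside the fitted dynamic range are flagged extrapolated, not
    rejected.
    """
    if cq is None or (isinstance(cq, float) and math.isnan(cq)):
        return CopyEstimate(copies=None, below_detection=True)
    log_copies = (cq - curve.intercept) / curve.slope
    lo, hi = curve.range_log10
    return CopyEstimate(copies=10**log_copies, extrapolated=not (lo <= log_copies <= hi))


@dataclass
class DilutionChain:
    """Ordered multiplicative factors from reaction back to whole individual.

    e.g. cDNA dilution x5, reaction template fraction x50, extracted-RNA
    fraction x4.  The product converts copies/reaction to copies/individual.
    """

    factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, f in self.factors.items():
            if f <= 0:
                raise InputError(f"dilution factor {name!r} must be positive")

    @property
    def total(self) -> float:
        return float(np.prod(list(self.factors.values()))) if self.factors else 1.0


def copies_per_insect(copies_per_reaction: float, chain: DilutionChain) -> float:
    """Scale a per-reaction copy number to copies per individual."""
    return copies_per_reaction * chain.total


@dataclass
class QpcrMeasurement:
    sample_id: str
    assay_id: str
    strand: Strand
    region: Region
    replicate_cqs: list[Optional[float]]  # None = no amplification
    melt_ok: list[bool]

    def __post_init__(self) -> None:
        if self.region not in ("g", "g_sg"):
            raise InputError(f"unknown region {self.region!r}")
        if len(self.replicate_cqs) != len(self.melt_ok):
            raise InputError("replicate_cqs and melt_ok must align")


@dataclass
class PositivityCall:
    positive: bool
    near_threshold: bool
    mean_cq: Optional[float]
    sd_cq: Optional[float]
    n_replicates: int
    n_usable: int  # amplified with passing melting curve


def _usable_cqs(m: QpcrMeasurement) -> list[float]:
    return [
        cq
        for cq, ok in zip(m.replicate_cqs, m.melt_ok)
        if ok and cq is not None and not math.isnan(cq)
    ]


def call_positive(
    m: QpcrMeasurement, cq_threshold: float = DEFAULT_CQ_THRESHOLD
) -> PositivityCall:
    """Positivity of one measurement under melting-curve gating.

    Positive iff the mean Cq of melt-passing amplified replicates is strictly
    below the threshold and at least half of the replicates amplified with a
    passing melting curve (a tie at exactly the threshold is negative: the
    threshold marks the limit of detection).  Calls within 0.5 Cq of the
    threshold are flagged near-threshold on either side.
    """
    if not m.replicate_cqs:
        raise InputError("measurement has no replicates")
    usable = _usable_cqs(m)
    n = len(m.replicate_cqs)
    if not usable:
        return PositivityCall(False, False, None, None, n, 0)
    mean_cq = float(np.mean(usable))
    sd_cq = float(np.std(usable, ddof=1)) if len(usable) > 1 else None
    positive = mean_cq < cq_threshold and len(usable) * 2 >= n
    near = abs(mean_cq - cq_threshold) < NEAR_THRESHOLD_CQ
    return PositivityCall(positive, near, mean_cq, sd_cq, n, len(usable))


def measurement_copies(
    m: QpcrMeasurement,
    curve: CalibrationCurve,
    cq_threshold: float = DEFAULT_CQ_THRESHOLD,
    geometric: bool = False,
) -> CopyEstimate:
    """Copies per reaction for one measurement, or below-detection.

    Replicates are aggregated as the arithmetic mean of Cq before inversion
    (instrument-software convention); ``geometric=True`` instead averages
    copies on the log scale per replicate, which is numerically identical for
    this log-linear model and provided for explicitness.
    """
    call = call_positive(m, cq_threshold)
    if not call.positive:
        return CopyEstimate(copies=None, below_detection=True)
    if geometric:
        vals = [cq_to_copies(curve, cq).copies for cq in _usable_cqs(m)]
        return CopyEstimate(copies=float(np.exp(np.mean(np.log(vals)))))
    return cq_to_copies(curve, call.mean_cq)


@dataclass
class StrandRatioResult:
    mean: Optional[float]
    sd: Optional[float]
    ratios: list[float]
    n_pairs: int
    excluded_pairs: int  # negative strand below detection
    lower_bound: Optional[float]  # from excluded pairs, if any
    reason: Optional[str] = None


def strand_ratio(
    panel: Sequence[QpcrMeasurement],
    curve: CalibrationCurve,
    cq_threshold: float = DEFAULT_CQ_THRESHOLD,
) -> StrandRatioResult:
    """Positive:negative strand copy ratio over matched assay pairs.

    Measurements sharing an ``assay_id`` with both strands form a pair; the
    per-pair ratio uses per-reaction copy estimates.  Pairs whose negative
    strand is below detection cannot yield a ratio — they are counted as
    excluded and contribute a one-sided lower bound (positive-strand copies
    over the detection-limit copies at the Cq threshold).
    """
    pairs: dict[str, dict[str, QpcrMeasurement]] = {}
    for m in panel:
        pairs.setdefault(m.assay_id, {})[m.strand] = m
    ratios: list[float] = []
    excluded = 0
    bounds: list[float] = []
    detection_limit = cq_to_copies(curve, cq_threshold).copies
    for assay, by_strand in sorted(pairs.items()):
        if "positive" not in by_strand or "negative" not in by_strand:
            continue
        pos = measurement_copies(by_strand["positive"], curve, cq_threshold)
        neg = measurement_copies(by_strand["negative"], curve, cq_threshold)
        if pos.copies is None:
            continue
        if neg.copies is None:
            excluded += 1
            bounds.append(pos.copies / detection_limit)
            continue
        ratios.append(pos.copies / neg.copies)
    if not ratios:
        reason = (
            "all negative-strand measurements below detection"
            if excluded
            else "no usable assay pair"
        )
        return StrandRatioResult(
            mean=None,
            sd=None,
            ratios=[],
            n_pairs=0,
            excluded_pairs=excluded,
            lower_bound=min(bounds) if bounds else None,
            reason=reason,
        )
    return StrandRatioResult(
        mean=float(np.mean(ratios)),
        sd=float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0,
        ratios=ratios,
        n_pairs=len(ratios),
        excluded_pairs=excluded,
        lower_bound=min(bounds) if bounds else None,
    )


@dataclass
class SubgenomicResult:
    excess: Optional[float]
    verdict: str  # "sgRNA evidence" | "no sgRNA evidence" | "undefined"
    mean_g: Optional[float]
    mean_g_sg: Optional[float]
    reason: Optional[str] = None


def subgenomic_excess(
    panel: Sequence[QpcrMeasurement],
    curve: CalibrationCurve,
    cq_threshold: float = DEFAULT_CQ_THRESHOLD,
    threshold: float = 2.0,
) -> SubgenomicResult:
    """Test for subgenomic-RNA excess on the positive strand of one sample.

    Assays in the genomic-only region (g) see genomic RNA; assays in the
    downstream region (g_sg) see genomic plus any subgenomic RNA.  The excess
    is mean(g_sg copies) / mean(g copies) over positive assays; a ratio
    above ``threshold`` (default 2x) is called evidence of subgenomic RNA,
    equality of the two regions is evidence against.
    """
    by_region: dict[str, list[float]] = {"g": [], "g_sg": []}
    for m in panel:
        if m.strand != "positive":
            continue
        est = measurement_copies(m, curve, cq_threshold)
        if est.copies is not None:
            by_region[m.region].append(est.copies)
    if not by_region["g"] or not by_region["g_sg"]:
        missing = [r for r, v in by_region.items() if not v]
        return SubgenomicResult(
            excess=None,
            verdict="undefined",
            mean_g=float(np.mean(by_region["g"])) if by_region["g"] else None,
            mean_g_sg=float(np.mean(by_region["g_sg"])) if by_region["g_sg"] else None,
            reason=f"no positive assay in region(s): {missing}",
        )
    mean_g = float(np.mean(by_region["g"]))
    mean_gsg = float(np.mean(by_region["g_sg"]))
    excess = mean_gsg / mean_g
    verdict = "sgRNA evidence" if excess > threshold else "no sgRNA evidence"
    return SubgenomicResult(excess=excess, verdict=verdict, mean_g=mean_g, mean_g_sg=mean_gsg)


@dataclass
class ControlGate:
    """Contamination gate from a sample's no-template/no-primer/no-RT controls."""

    clean: bool
    failed_controls: list[str]


def check_controls(
    controls: Sequence[QpcrMeasurement],
    cq_threshold: float = DEFAULT_CQ_THRESHOLD,
) -> ControlGate:
    """Any amplifying control (positive call) invalidates the sample's suite."""
    failed = [
        m.assay_id for m in controls if call_positive(m, cq_threshold).positive
    ]
    return ControlGate(clean=not failed, failed_controls=failed)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_measurements(path: str | Path) -> list[QpcrMeasurement]:
    """Read a measurements CSV with columns sample_id, assay_id, strand,
    region, cq_rep1..n (blank = no amplification), melt_ok_rep1..n."""
    df = pd.read_csv(path)
    cq_cols = sorted(c for c in df.columns if c.startswith("cq_rep"))
    melt_cols = sorted(c for c in df.columns if c.startswith("melt_ok_rep"))
    if not cq_cols or len(cq_cols) != len(melt_cols):
        raise InputError("need matching cq_rep*/melt_ok_rep* columns")
    out = []
    for _, row in df.iterrows():
        cqs = [None if pd.isna(row[c]) else float(row[c]) for c in cq_cols]
        melts = [bool(row[c]) for c in melt_cols]
        out.append(
            QpcrMeasurement(
                sample_id=str(row["sample_id"]),
                assay_id=str(row["assay_id"]),
                strand=str(row["strand"]),
                region=str(row["region"]),
                replicate_cqs=cqs,
                melt_ok=melts,
            )
        )
    return out


def read_calibration(path: str | Path) -> CalibrationCurve:
    """Fit a calibration curve from a CSV with columns copies, cq."""
    df = pd.read_csv(path)
    return fit_calibration(list(zip(df["copies"], df["cq"])))
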