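"""Synthetic inputs with known truth for every pipeline stage.

Generators for (a) viral genomes with a prescribed ORF-1 / IGR / ORF-2 /
ORF-3 / 3'UTR / poly-A layout and host-regime-like codon composition,
(b) strand-specific qPCR measurement tables produced by a log-linear Cq
model with Gaussian cycle noise, (c) per-position pileup base counts with a
dominant consensus, sequencing-error noise and planted minor-allele sites,
and (d) field-survey tables with Bernoulli positivity at a stated
prevalence.

Every generator is a pure function of its spec and seed; per-component
random sub-streams are derived from stable tags so adding one component
never perturbs the others.  Each generator returns a machine-readable truth
record consumed by the test suite.

Genome generation enforces its own truth with an internal ORF scanner that
is independent of :mod:`negevkit.genome_annotation`: candidate sequences are
redrawn until the set of maximal AUG-initiated ORFs of at least
``clean_min_aa`` residues equals exactly the specified layout, so annotation
round-trips are exact by construction, not by luck.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .composition import SENSE_CODONS
from .genome_annotation import (
    GenomeLayout,
    GenomeRecord,
    InputError,
    OrfAnnotation,
    Span,
)

_STOPS = ("TAA", "TAG", "TGA")
#: stops at all three phases, ATG-free; planted at IGR starts so that no
#: reading frame runs uninterrupted from one ORF into the next
_TRIPHASE_STOPS = "TAATTAATTAA"


def substream(seed: int, *tags) -> np.random.Generator:
    """Deterministic child RNG keyed by ``seed`` and stable string/int tags."""
    digest = hashlib.sha256("|".join(map(str, tags)).encode()).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + words.tolist()))


# ---------------------------------------------------------------------------
# genome generator
# ---------------------------------------------------------------------------

def load_host_regimes() -> dict:
    from importlib import resources

    with (resources.files("negevkit") / "data" / "host_regimes.json").open() as fh:
        return json.load(fh)


def codon_weights(regime: str | dict) -> dict[str, float]:
    """Sampling weight per sense codon for a named preset or explicit map."""
    if isinstance(regime, dict):
        missing = set(SENSE_CODONS) - set(regime)
        if missing:
            raise InputError(f"custom codon weights missing {len(missing)} codons")
        return {c: float(regime[c]) for c in SENSE_CODONS}
    presets = load_host_regimes()
    if regime not in presets:
        raise InputError(f"unknown host regime {regime!r}")
    third = presets[regime]["third_base_weight"]
    return {c: float(third[c[2]]) for c in SENSE_CODONS}


@dataclass
class GenomeSpec:
    """Layout and composition of a synthetic negevirus-like genome.

    Defaults model the study organism: a ~10.2 kb positive-sense genome with
    a short 5'UTR, a large replicase ORF, a 229 nt intergenic region, a coat
    protein ORF ending in a leaky UAG, a 3 nt gap, a small downstream ORF,
    a 782 nt 3'UTR and a natural poly-A tail.
    """

    five_utr_len: int = 26
    orf_aa: tuple[tuple[str, int], ...] = (("ORF-1", 2669), ("ORF-2", 233), ("ORF-3", 125))
    igr_lens: tuple[int, ...] = (229, 3)
    three_utr_len: int = 782
    polya_len: int = 25
    host_regime: str | dict = "insect_like"
    orf_stop_codons: Optional[tuple[str, ...]] = None  # default: TAA, second ORF TAG
    kozak_flanks: Optional[dict[str, tuple[str, str]]] = None  # label -> (up3, codon2)
    clean_min_aa: int = 120  # no non-truth ORF of this size may survive

    def __post_init__(self) -> None:
        if len(self.igr_lens) != len(self.orf_aa) - 1:
            raise InputError("need exactly one IGR length per ORF junction")
        if any(aa < 1 for _, aa in self.orf_aa):
            raise InputError("ORF lengths must be positive")
        if self.clean_min_aa > min(aa for _, aa in self.orf_aa):
            raise InputError("clean_min_aa exceeds the shortest specified ORF")
        if self.polya_len < 0:
            raise InputError("polya_len must be >= 0")
        _ = self.stops  # validate any explicit stop codons eagerly

    @property
    def stops(self) -> tuple[str, ...]:
        if self.orf_stop_codons is not None:
            if any(s not in _STOPS for s in self.orf_stop_codons):
                raise InputError("invalid stop codon in spec")
            return self.orf_stop_codons
        out = ["TAA"] * len(self.orf_aa)
        if len(out) >= 2:
            out[1] = "TAG"  # leaky coat-protein stop, read-through capable
        return tuple(out)

    @property
    def total_length(self) -> int:
        orf_nt = sum((aa + 1) * 3 for _, aa in self.orf_aa)
        return (
            self.five_utr_len
            + orf_nt
            + sum(self.igr_lens)
            + self.three_utr_len
            + self.polya_len
        )


@dataclass
class SyntheticGenome:
    record: GenomeRecord
    layout: GenomeLayout
    contexts: dict[str, str]  # ORF label -> 9-mer initiation context
    spec: GenomeSpec
    attempts: int

    def write(self, outdir: str | Path, name: str = "synthetic_genome") -> None:
        from .genome_annotation import write_gff3

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"{name}.fasta").write_text(
            f">{self.record.id} {self.record.description}\n{self.record.sequence}\n"
        )
        write_gff3(self.layout, self.record, outdir / f"{name}_truth.gff3")
        truth = {
            "orfs": [
                {
                    "label": o.label,
                    "start": o.start,
                    "end": o.end,
                    "frame": o.frame,
                    "aa_length": o.aa_length,
                    "alt_starts": o.alt_starts,
                }
                for o in self.layout.orfs
            ],
            "polya_start": self.layout.polya_start,
            "contexts": self.contexts,
            "clean_min_aa": self.spec.clean_min_aa,
        }
        (outdir / f"{name}_truth.json").write_text(json.dumps(truth, indent=2))


def _strip_atg(seq: list[str], rng: np.random.Generator) -> None:
    """Remove every ATG trinucleotide in-place by resampling its middle base."""
    s = "".join(seq)
    while "ATG" in s:
        i = s.index("ATG")
        seq[i + 1] = rng.choice(["A", "C", "G"])
        s = "".join(seq)


def _noncoding(rng: np.random.Generator, length: int, atg_free: bool) -> str:
    seg = list(rng.choice(list("ACGT"), size=length)) if length else []
    if atg_free and length >= 3:
        _strip_atg(seg, rng)
    return "".join(seg)


def _scan_truth(seq: str, min_aa: int) -> set[tuple[int, int]]:
    """Independent maximal-ORF scanner used to verify generated genomes."""
    found = set()
    for frame in range(3):
        first_atg = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if first_atg is not None and (i - first_atg) // 3 >= min_aa:
                    found.add((first_atg + 1, i + 3))
                first_atg = None
            elif codon == "ATG" and first_atg is None:
                first_atg = i
    return found


def generate_genome(spec: GenomeSpec, seed: int) -> SyntheticGenome:
    """Generate a genome realizing ``spec`` exactly, with truth layout.

    Codons are sampled from the host-regime weights; 5'UTR and intergenic
    sequences are kept free of AUG and IGRs open with stop codons in all
    three phases, so the specified starts are the first AUGs of their
    reading-frame segments.  Candidates are redrawn until the independent
    truth scanner confirms that the maximal ORFs of >= ``clean_min_aa``
    residues are exactly the specified ones.
    """
    weights = codon_weights(spec.host_regime)
    codons = list(SENSE_CODONS)
    p = np.array([weights[c] for c in codons], dtype=float)
    p /= p.sum()
    stops = spec.stops
    flanks = spec.kozak_flanks or {}

    # truth coordinates are fixed by the layout alone
    starts, ends = [], []
    cursor = spec.five_utr_len  # 0-based position where next ORF begins
    for k, (_, aa) in enumerate(spec.orf_aa):
        starts.append(cursor + 1)
        cursor += (aa + 1) * 3
        ends.append(cursor)
        if k < len(spec.igr_lens):
            cursor += spec.igr_lens[k]

    truth_set = set(zip(starts, ends))
    for attempt in range(500):
        rng = substream(seed, "genome", attempt)
        parts: list[str] = [_noncoding(rng, spec.five_utr_len, atg_free=True)]
        for k, (label, aa) in enumerate(spec.orf_aa):
            body = list(rng.choice(codons, size=aa - 1, p=p))
            if label in flanks:
                up3, codon2 = flanks[label]
                if len(up3) != 3 or up3 == "ATG":
                    raise InputError("kozak up3 must be a non-AUG triplet")
                if codon2 not in SENSE_CODONS:
                    raise InputError("kozak codon2 must be a sense codon")
                if body:
                    body[0] = codon2
            parts.append("ATG" + "".join(body) + stops[k])
            if k < len(spec.igr_lens):
                igr_len = spec.igr_lens[k]
                igr = _noncoding(rng, igr_len, atg_free=True)
                if igr_len >= len(_TRIPHASE_STOPS):
                    igr = _TRIPHASE_STOPS + igr[len(_TRIPHASE_STOPS) :]
                next_label = spec.orf_aa[k + 1][0]
                if next_label in flanks and igr_len >= 3:
                    igr = igr[:-3] + flanks[next_label][0]
                parts.append(igr)
        utr3 = _noncoding(rng, spec.three_utr_len, atg_free=False)
        if spec.polya_len and spec.three_utr_len:
            # keep the poly-A run from bleeding into the 3'UTR
            if utr3.endswith("A"):
                utr3 = utr3[:-1] + rng.choice(["C", "G", "T"])
        parts.append(utr3)
        parts.append("A" * spec.polya_len)
        seq = "".join(parts)
        assert len(seq) == spec.total_length
        if _scan_truth(seq, spec.clean_min_aa) == truth_set:
            break
    else:
        raise RuntimeError("genome generation did not converge in 500 attempts")

    orfs = []
    contexts = {}
    for (label, aa), start, end in zip(spec.orf_aa, starts, ends):
        alt = [
            i + 1
            for i in range(start - 1 + 3, end - 3, 3)
            if seq[i : i + 3] == "ATG"
        ]
        orfs.append(
            OrfAnnotation(
                orf_id=f"orf_{start}_f{(start - 1) % 3}",
                start=start,
                end=end,
                frame=(start - 1) % 3,
                aa_length=aa,
                label=label,
                alt_starts=alt,
            )
        )
        if start >= 4:
            contexts[label] = seq[start - 4 : start + 5]

    L = len(seq)
    polya_start = L - spec.polya_len + 1 if spec.polya_len else None
    three_end = (polya_start - 1) if polya_start else L
    layout = GenomeLayout(
        five_utr=Span(1, spec.five_utr_len) if spec.five_utr_len else None,
        orfs=orfs,
        igrs=[
            Span(ends[k] + 1, starts[k + 1] - 1) if spec.igr_lens[k] else None
            for k in range(len(spec.igr_lens))
        ],
        three_utr=Span(ends[-1] + 1, three_end) if three_end > ends[-1] else None,
        polya_start=polya_start,
        genome_length=L,
    )
    record = GenomeRecord(
        id=f"synthetic_{seed}",
        description=f"synthetic negevirus-like genome (regime={spec.host_regime}, seed={seed})",
        sequence=seq,
    )
    return SyntheticGenome(
        record=record, layout=layout, contexts=contexts, spec=spec, attempts=attempt + 1
    )


# ---------------------------------------------------------------------------
# qPCR generator
# ---------------------------------------------------------------------------

@dataclass
class AssayTruth:
    assay_id: str
    strand: str  # positive | negative
    region: str  # g | g_sg
    copies: float  # true copies per reaction


@dataclass
class QpcrSpec:
    """Measurement model: Cq = slope*log10(copies) + intercept + N(0, sd)."""

    samples: dict[str, list[AssayTruth]]
    slope: float = -3.32
    intercept: float = 37.0
    noise_sd: float = 0.15
    replicates: int = 3
    dropout_copies: float = 1.0  # below this, amplification fails (absent Cq)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise InputError("slope must be negative")
        if self.noise_sd < 0:
            raise InputError("noise sd must be >= 0")


def strand_panel(pos_copies: float, ratio: float, n_pairs: int = 4) -> list[AssayTruth]:
    """Matched strand-assay panel: half the pairs in the genomic-only region,
    half in the genomic+subgenomic region, with positive:negative copy ratio
    ``ratio`` on every pair."""
    out = []
    for k in range(1, n_pairs + 1):
        region = "g" if k <= n_pairs // 2 else "g_sg"
        out.append(AssayTruth(f"assay{k}", "positive", region, pos_copies))
        out.append(AssayTruth(f"assay{k}", "negative", region, pos_copies / ratio))
    return out


def generate_qpcr(spec: QpcrSpec, seed: int):
    """Simulate the measurement table for ``spec``; returns (measurements, truth).

    Truth is a DataFrame of the per-assay true copies.  Reactions whose true
    copy number falls below the dropout rule emit no Cq and a failing
    melting curve.
    """
    from .qpcr_quant import QpcrMeasurement

    measurements = []
    truth_rows = []
    for sample_id in spec.samples:
        for a in spec.samples[sample_id]:
            rng = substream(seed, "qpcr", sample_id, a.assay_id, a.strand)
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "assay_id": a.assay_id,
                    "strand": a.strand,
                    "region": a.region,
                    "true_copies": a.copies,
                }
            )
            if a.copies < spec.dropout_copies:
                cqs: list[Optional[float]] = [None] * spec.replicates
                melts = [False] * spec.replicates
            else:
                base = spec.slope * np.log10(a.copies) + spec.intercept
                noise = rng.normal(0.0, spec.noise_sd, size=spec.replicates)
                cqs = [float(base + e) for e in noise]
                melts = [True] * spec.replicates
            measurements.append(
                QpcrMeasurement(
                    sample_id=sample_id,
                    assay_id=a.assay_id,
                    strand=a.strand,
                    region=a.region,
                    replicate_cqs=cqs,
                    melt_ok=melts,
                )
            )
    return measurements, pd.DataFrame(truth_rows)


def measurements_to_csv(measurements, path: str | Path) -> None:
    rows = []
    for m in measurements:
        row = {
            "sample_id": m.sample_id,
            "assay_id": m.assay_id,
            "strand": m.strand,
            "region": m.region,
        }
        for i, (cq, ok) in enumerate(zip(m.replicate_cqs, m.melt_ok), start=1):
            row[f"cq_rep{i}"] = cq
            row[f"melt_ok_rep{i}"] = ok
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pileup generator
# ---------------------------------------------------------------------------

def generate_pileup(
    sequence: str,
    mean_coverage: float = 350.0,
    error_rate: float = 0.005,
    planted_variants: Sequence[tuple[int, str, float]] = (),
    seed: int = 0,
):
    """Per-position base counts around a known consensus; returns (table, truth).

    Coverage is Poisson(``mean_coverage``).  Background positions put
    ``error_rate`` mass on the three non-consensus bases (split evenly);
    each planted variant ``(pos, base, freq)`` puts ``freq`` on its minor
    base instead of that base's error share.
    """
    if not 0 <= error_rate < 0.5:
        raise InputError("error_rate must be in [0, 0.5)")
    L = len(sequence)
    planted = {}
    for pos, base, freq in planted_variants:
        if not 1 <= pos <= L:
            raise InputError(f"variant position {pos} out of range")
        if not 0 < freq < 0.5:
            raise InputError("planted variant frequencies must be in (0, 0.5)")
        if base == sequence[pos - 1]:
            raise InputError("planted minor base equals the consensus base")
        planted[pos] = (base, freq)

    rng = substream(seed, "pileup")
    bases = "ACGT"
    coverage = rng.poisson(mean_coverage, size=L)
    counts = np.zeros((L, 4), dtype=np.int64)
    for i in range(L):
        ref = sequence[i]
        probs = np.full(4, error_rate / 3)
        probs[bases.index(ref)] = 1 - error_rate
        if i + 1 in planted:
            mb, f = planted[i + 1]
            probs[bases.index(mb)] = f
            probs[bases.index(ref)] = 1 - f - 2 * error_rate / 3
        counts[i] = rng.multinomial(coverage[i], probs)
    table = pd.DataFrame(
        {
            "pos": np.arange(1, L + 1),
            "A": counts[:, 0],
            "C": counts[:, 1],
            "G": counts[:, 2],
            "T": counts[:, 3],
            "other": 0,
        }
    )
    truth = {
        "consensus": sequence,
        "planted": {pos: {"base": b, "freq": f} for pos, (b, f) in planted.items()},
        "error_rate": error_rate,
        "mean_coverage": mean_coverage,
    }
    return table, truth


# ---------------------------------------------------------------------------
# survey generator
# ---------------------------------------------------------------------------

def generate_survey(
    sites: Sequence[tuple[str, str, float, float]],
    species: Sequence[str],
    stages: Sequence[str],
    n_per_cell: int,
    prevalence: float,
    seed: int = 0,
):
    """Binomial screening outcomes per site x species x stage cell."""
    if not 0 <= prevalence <= 1:
        raise InputError("prevalence must be in [0, 1]")
    rows = []
    for site, country, lat, lon in sites:
        for sp in species:
            for stage in stages:
                rng = substream(seed, "survey", site, sp, stage)
                n_pos = int(rng.binomial(n_per_cell, prevalence))
                rows.append(
                    {
                        "site": site,
                        "country": country,
                        "lat": lat,
                        "lon": lon,
                        "species": sp,
                        "stage": stage,
                        "n": n_per_cell,
                        "n_pos": n_pos,
                    }
                )
    table = pd.DataFrame(rows)
    truth = {"prevalence": prevalence, "n_total": int(table["n"].sum())}
    return table, truth
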