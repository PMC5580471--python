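"""ORF annotation of positive-sense RNA virus genomes.

Finds AUG-initiated open reading frames in the three forward frames, derives
the 5'UTR / ORF / intergenic-region / 3'UTR / poly-A partition of the genome,
extracts and scores Kozak translation-initiation contexts (positions -3..+6
around the AUG), and detects potential C-terminal read-through extensions
past a leaky UAG stop codon.

Coordinates are 1-based and inclusive throughout (GenBank convention).
RNA input (U) is normalized to DNA (T) on load.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

# IUPAC nucleotide codes accepted on input; only ACGT enter statistics.
_IUPAC = frozenset("ACGTRYSWKMBDHVN")


class InputError(ValueError):
    """Raised on malformed or out-of-contract input."""


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U->T, and validate against the IUPAC DNA alphabet."""
    s = seq.upper().replace("U", "T")
    if not s:
        raise InputError("empty sequence")
    bad = set(s) - _IUPAC
    if bad:
        raise InputError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class GenomeRecord:
    """A single (viral) genome sequence, normalized to the DNA alphabet."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Load all records of a FASTA file as normalized :class:`GenomeRecord`."""
    records = [
        GenomeRecord(id=r.id, description=r.description, sequence=str(r.seq))
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


@dataclass(frozen=True)
class Span:
    """1-based inclusive genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise InputError(f"invalid span [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class OrfAnnotation:
    """An AUG-initiated open reading frame, stop codon included in [start, end]."""

    orf_id: str
    start: int
    end: int
    frame: int
    aa_length: int
    label: str = ""
    alt_starts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.end - self.start + 1) % 3:
            raise InputError("ORF length must be divisible by 3")
        if self.start < 1:
            raise InputError("ORF start before genome origin")


@dataclass
class ReadthroughExtension:
    """In-frame span past a leaky UAG stop, up to (and including) the next stop."""

    start: int
    end: int
    aa_extension: int
    stop_found: bool

    @property
    def empty(self) -> bool:
        return self.end < self.start


@dataclass
class GenomeLayout:
    """Partition of a genome into 5'UTR, ORFs, IGRs, 3'UTR and poly-A tail."""

    five_utr: Optional[Span]
    orfs: list[OrfAnnotation]
    igrs: list[Optional[Span]]
    three_utr: Optional[Span]
    polya_start: Optional[int]
    genome_length: int


@dataclass
class KozakContext:
    """The 9-mer covering positions -3..-1, AUG, +4..+6 around a start codon.

    ``truncated`` is set when the window does not fit the genome; truncated
    contexts carry no score and are excluded from frequency matrices.
    """

    sequence: str
    aug_pos: int
    truncated: bool
    key_matches: Optional[int] = None
    score: Optional[int] = None


def find_orfs(
    genome: GenomeRecord,
    min_aa: int = 50,
    require_aug: bool = True,
    both_strands: bool = False,
) -> list[OrfAnnotation]:
    """Find AUG-initiated ORFs of >= ``min_aa`` residues in the forward frames.

    Within each stop-bounded segment of a frame, the first AUG opens the ORF
    (longest-ORF resolution); later in-frame AUGs are recorded in
    ``alt_starts``.  ORFs lacking a terminal stop codon are not reported.
    Results are ordered by start coordinate.  ``both_strands`` additionally
    scans the reverse complement (off by default: these viruses are
    positive-sense), reporting reverse ORFs in forward coordinates of the
    reverse-complemented sequence with ids suffixed ``_rc``.
    """
    if min_aa < 1:
        raise InputError("min_aa must be >= 1")
    seq = genome.sequence
    orfs = _scan_forward(seq, min_aa, require_aug, suffix="")
    if both_strands:
        rc = _revcomp(seq)
        orfs += _scan_forward(rc, min_aa, require_aug, suffix="_rc")
    orfs.sort(key=lambda o: (o.start, o.frame))
    return orfs


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
    return seq.translate(comp)[::-1]


def _scan_forward(seq: str, min_aa: int, require_aug: bool, suffix: str) -> list[OrfAnnotation]:
    out: list[OrfAnnotation] = []
    n = len(seq)
    for frame in range(3):
        aug_positions: list[int] = []  # 0-based codon starts since last stop
        seg_start = frame
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                start0 = None
                if aug_positions:
                    start0 = aug_positions[0]
                elif not require_aug:
                    start0 = seg_start
                if start0 is not None:
                    aa = (i - start0) // 3
                    if aa >= min_aa:
                        inner = [p + 1 for p in aug_positions[1:]]
                        out.append(
                            OrfAnnotation(
                                orf_id=f"orf{suffix}_{start0 + 1}_f{frame}",
                                start=start0 + 1,
                                end=i + 3,
                                frame=frame,
                                aa_length=aa,
                                alt_starts=inner,
                            )
                        )
                aug_positions = []
                seg_start = i + 3
            elif codon == START_CODON:
                aug_positions.append(i)
    return out


def major_orfs(orfs: Sequence[OrfAnnotation], n: int = 3) -> list[OrfAnnotation]:
    """The ``n`` longest ORFs, relabelled ORF-1..ORF-n in genome order."""
    top = sorted(orfs, key=lambda o: o.aa_length, reverse=True)[:n]
    top.sort(key=lambda o: o.start)
    out = []
    for k, orf in enumerate(top, start=1):
        out.append(dataclasses.replace(orf, label=f"ORF-{k}"))
    return out


def annotate_layout(
    genome: GenomeRecord,
    orfs: Sequence[OrfAnnotation],
    polya_min_run: int = 8,
) -> GenomeLayout:
    """Derive the UTR/IGR layout around a set of non-overlapping ORFs.

    The 3'UTR runs from the nucleotide after the last ORF's stop codon to the
    last nucleotide before the terminal poly-A run (>= ``polya_min_run`` A's),
    or to the genome end if no tail is detected.  Empty spans are ``None``.
    """
    if polya_min_run < 5:
        raise InputError("polya_min_run must be >= 5")
    L = len(genome)
    ordered = sorted(orfs, key=lambda o: o.start)
    for orf in ordered:
        if orf.end > L:
            raise InputError(f"ORF {orf.orf_id} extends past genome end")
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise InputError(f"ORFs {a.orf_id} and {b.orf_id} overlap")

    five = None
    if ordered and ordered[0].start > 1:
        five = Span(1, ordered[0].start - 1)
    igrs: list[Optional[Span]] = []
    for a, b in zip(ordered, ordered[1:]):
        igrs.append(Span(a.end + 1, b.start - 1) if b.start - a.end > 1 else None)

    run = 0
    while run < L and genome.sequence[L - 1 - run] == "A":
        run += 1
    polya_start = L - run + 1 if run >= polya_min_run else None

    three = None
    if ordered:
        utr_start = ordered[-1].end + 1
        utr_end = (polya_start - 1) if polya_start is not None else L
        if utr_end >= utr_start:
            three = Span(utr_start, utr_end)
    return GenomeLayout(
        five_utr=five,
        orfs=list(ordered),
        igrs=igrs,
        three_utr=three,
        polya_start=polya_start,
        genome_length=L,
    )


def extract_kozak(genome: GenomeRecord, aug_pos: int) -> KozakContext:
    """Extract the -3..+6 initiation context of the AUG starting at ``aug_pos``.

    Full contexts are scored on extraction; windows truncated at genome edges
    are flagged and left unscored.
    """
    seq = genome.sequence
    if aug_pos < 1 or aug_pos + 2 > len(seq):
        raise InputError(f"AUG position {aug_pos} out of bounds")
    if seq[aug_pos - 1 : aug_pos + 2] != START_CODON:
        raise InputError(f"no AUG at position {aug_pos}")
    lo, hi = aug_pos - 4, aug_pos + 5  # 0-based slice bounds
    truncated = lo < 0 or hi > len(seq)
    window = seq[max(lo, 0) : min(hi, len(seq))]
    ctx = KozakContext(sequence=window, aug_pos=aug_pos, truncated=truncated)
    if not truncated:
        ctx.key_matches, ctx.score = score_kozak(ctx)
    return ctx


#: weights of the key Kozak positions: -3 (A/G) > +4 (G) > -1 (C/G)
KOZAK_WEIGHTS = {"-3": 3, "+4": 2, "-1": 1}


def score_kozak(ctx: KozakContext) -> tuple[int, int]:
    """Count and weight the satisfied key Kozak positions of a full context.

    Keys: -3 in {A, G}; -1 in {C, G}; +4 == G.  Returns
    ``(key_matches, score)`` with score = 3*[-3] + 2*[+4] + 1*[-1], giving a
    deterministic total order over contexts that refines the match count.
    """
    if ctx.truncated or len(ctx.sequence) != 9:
        raise InputError("cannot score a truncated Kozak context")
    s = ctx.sequence
    hits = {
        "-3": s[0] in "AG",
        "-1": s[2] in "CG",
        "+4": s[6] == "G",
    }
    key_matches = sum(hits.values())
    score = sum(w for pos, w in KOZAK_WEIGHTS.items() if hits[pos])
    return key_matches, score


def find_readthrough(genome: GenomeRecord, orf: OrfAnnotation) -> Optional[ReadthroughExtension]:
    """Potential read-through extension past a leaky UAG stop codon.

    Returns the in-frame span from the nucleotide after the ORF's stop to the
    next in-frame stop (included), or ``None`` if the ORF does not end in UAG.
    If no downstream stop exists the span runs to the genome end with
    ``stop_found=False``; an ORF ending exactly at the genome end yields an
    empty, flagged extension.
    """
    seq = genome.sequence
    if orf.end > len(seq):
        raise InputError("ORF out of bounds")
    if seq[orf.end - 3 : orf.end] != "TAG":
        return None
    codons = 0
    for i in range(orf.end, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return ReadthroughExtension(
                start=orf.end + 1, end=i + 3, aa_extension=codons, stop_found=True
            )
        codons += 1
    return ReadthroughExtension(
        start=orf.end + 1, end=len(seq), aa_extension=codons, stop_found=False
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_gff3(layout: GenomeLayout, genome: GenomeRecord, path: str | Path) -> None:
    """Write the layout as GFF3 (1-based inclusive, native to the convention)."""
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {layout.genome_length}"]

    def row(ftype: str, start: int, end: int, attrs: str) -> str:
        return "\t".join(
            [genome.id, "negevkit", ftype, str(start), str(end), ".", "+", ".", attrs]
        )

    if layout.five_utr:
        lines.append(row("five_prime_UTR", layout.five_utr.start, layout.five_utr.end, "ID=5utr"))
    for orf in layout.orfs:
        name = orf.label or orf.orf_id
        lines.append(row("CDS", orf.start, orf.end, f"ID={orf.orf_id};Name={name}"))
    for k, igr in enumerate(layout.igrs, start=1):
        if igr:
            lines.append(row("region", igr.start, igr.end, f"ID=igr{k};Note=intergenic_region"))
    if layout.three_utr:
        lines.append(row("three_prime_UTR", layout.three_utr.start, layout.three_utr.end, "ID=3utr"))
    if layout.polya_start is not None:
        lines.append(row("polyA_site", layout.polya_start, layout.genome_length, "ID=polya"))
    Path(path).write_text("\n".join(lines) + "\n")


def orf_summary_table(genome: GenomeRecord, orfs: Iterable[OrfAnnotation]):
    """Per-ORF summary as a DataFrame: coordinates, length and Kozak context."""
    import pandas as pd

    rows = []
    for orf in orfs:
        ctx = extract_kozak(genome, orf.start)
        rows.append(
            {
                "orf_id": orf.orf_id,
                "label": orf.label,
                "start": orf.start,
                "end": orf.end,
                "frame": orf.frame,
                "aa_length": orf.aa_length,
                "kozak_context": ctx.sequence,
                "kozak_truncated": ctx.truncated,
                "key_matches": ctx.key_matches,
                "kozak_score": ctx.score,
            }
        )
    return pd.DataFrame(rows)
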