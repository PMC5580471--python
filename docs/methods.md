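# Methods notes

This note records the models, conventions and design choices behind
negevkit, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and alphabets

All coordinates are 1-based and inclusive (GenBank convention); GFF3 output
uses the same convention natively. RNA input (U) is normalized to DNA (T) on
load; IUPAC ambiguity codes are accepted but excluded from every statistic
(pairs and codons containing them are skipped, never imputed).

## ORF model

An ORF is an AUG-initiated reading frame extended to its first in-frame stop
codon, stop included in `[start, end]`; `aa_length` counts residues
excluding the stop. Within a stop-bounded segment of a frame the first AUG
opens the reported ORF and later in-frame AUGs are kept in `alt_starts`
(this mirrors genomes where two candidate starts of a coat-protein ORF are
both plausible). ORFs lacking a terminal stop are not reported. Only the
three forward frames are searched by default — the target viruses are
positive-sense — with a flag for six-frame search.

Layout derivation: 5′UTR = `[1, first start − 1]`; IGR between consecutive
ORFs = `[prev end + 1, next start − 1]` (empty allowed); the poly-A tail is
the terminal run of ≥ 8 A's (default; shorter runs are indistinguishable
from A-rich UTR sequence); the 3′UTR runs from after the last stop codon to
the nucleotide before the poly-A run, or to the genome end.

Read-through detection applies only to ORFs ending in UAG — the classical
leaky stop — and returns the in-frame span to the next stop (included), with
an explicit flag when no downstream stop exists.

## Kozak scoring

Contexts are the 9-mers at −3..+6 around an AUG. The key positions are −3
(A/G), −1 (C/G) and +4 (G); `key_matches` counts them. Because several
contexts share a match count, a deterministic total order is useful for
comparing candidate starts, so a weighted score 3·[−3] + 2·[+4] + 1·[−1] is
reported alongside — −3 and +4 are the canonically strong positions. The
weighting is a package convention, not an empirical model; `key_matches` is
always available for alternative weightings. Windows truncated at genome
edges are flagged, unscored and excluded from frequency matrices.

## Compositional statistics

Dinucleotide relative abundance is ρ(XY) = f_obs(XY)/(f(X)·f(Y)), with
expected frequencies from whole-sequence mononucleotide frequencies; ρ = 1
under independence. Because codon structure induces position-specific
biases, ρ is computed in four modes: all overlapping pairs, codon positions
1–2, 2–3, and 3–1 bridging into the next codon — the standard decomposition
by codon region. RSCU uses the standard genetic code; a single terminal stop
codon is trimmed and stop codons are excluded by default; families with zero
usage are flagged undefined rather than divided. Whether bias is computed on
whole genomes or concatenated CDSs is the caller's choice; CDS input is the
default route since codon-region modes require it.

## Correspondence analysis

CA is implemented directly: with P the table over its grand total, r and c
the margins, the matrix S = (P − rcᵀ)/√(rcᵀ) is decomposed by SVD. Centering
by the expected table removes the trivial unit singular value, so every
retained dimension is informative; total inertia Σσ² equals the Pearson χ²
statistic over the grand total (tested to 1e−9 against an independent χ²
computation on random tables, and cross-checked against scikit-bio's CA).
Row-principal scaling is used because sequences are plotted as points.
Numerical choices: singular values below √1e−12 are treated as null; signs
are fixed by making each dimension's largest-magnitude row coordinate
positive; zero rows/columns are dropped and recorded rather than
pseudo-counted, since CA is undefined on zero-mass profiles and pseudo-counts
distort small synonymous families; a single-row/column or rank-1 table yields
a zero-dimensional result with inertia 0.

Host attribution fits CA on the reference profiles only and projects the
query with the transition formula (supplementary point), so the query cannot
pull the ordination toward itself. The call is the nearer host centroid in
the first 2 dimensions (default) unless |d_insect − d_plant| <
0.25 × pooled within-group mean distance-to-centroid, in which case it is
*ambiguous*. The margin rule is an explicit operationalization of
"not convincingly assignable"; no quantitative criterion exists in the
source analyses, so both the margin fraction and the dimension count are
configuration, not science.

## qPCR model

Cq = slope·log₁₀(copies) + intercept, fitted by ordinary least squares on a
dilution series (≥ 3 distinct concentrations); efficiency = 10^(−1/slope) − 1,
exactly 1 at slope −1/log₁₀2 ≈ −3.3219. Replicates are aggregated as the
arithmetic mean of Cq before inversion, matching instrument-software
convention (a geometric-mean-of-copies alternative is provided and is
identical under this log-linear model). Estimates outside the fitted range
are flagged extrapolated, not rejected. "No amplification" is an absent Cq,
never a sentinel like 40 or 0.

Positivity: mean Cq of melt-passing amplified replicates strictly below the
threshold (default 35), with at least half the replicates amplified and
melt-passing. A tie at exactly 35.000 is negative — the threshold marks the
detection limit itself. Calls within 0.5 Cq of the threshold are flagged
near-threshold on either side. Any amplifying no-template/no-primer/no-RT
control fails its sample's control gate.

Strand ratios average per-pair (positive copies)/(negative copies) over
matched assays; pairs whose negative strand is below detection are excluded
and counted, contributing a one-sided lower bound (positive copies over the
detection-limit copies) instead of a number. Subgenomic excess is
mean(g+sg-region copies)/mean(g-region copies) over positive-strand assays;
values above 2× (default) are called evidence of subgenomic RNA — equal
detection in both regions argues against a subgenomic messenger.

## Pileup profile

Input is a per-position base-count table (pos, A, C, G, T, other) — the
minimal sufficient statistic of a pileup; a converter from raw alignment
pileups should count indels and clipped bases as "other". Consensus is the
majority base among A/C/G/T; "other" enters coverage but can never be the
consensus. Ties are broken lexicographically and always flagged. MAF is the
second-highest base count over coverage; zero coverage gives consensus N and
undefined MAF.

## Survey tabulation

Missing cells are absent rows, never zeros, so they cannot deflate
prevalence denominators. The bundled fixture follows the published survey
table; its winter-moth pupae sum to 52 even though the collection narrative
mentions 53 — the table is taken as authoritative and the discrepancy left
unresolved.

## Synthetic-data generators

All generators are pure functions of (spec, seed); per-component RNG
sub-streams are keyed by stable tags (SHA-256 of the component path mixed
into the seed sequence), so adding a sample or component never perturbs the
others, and reruns are byte-identical.

**Genomes.** The default spec realizes the study-like organization: 26 nt
5′UTR; ORFs of 2669, 233 and 125 residues (so the second ORF starts at
8266 and the third at 8971); IGRs of 229 and 3 nt; 782 nt 3′UTR; 25 nt
poly-A; second ORF ending in leaky UAG. Codons are drawn from host-regime
weights — the shipped insect-like/plant-like presets weight third-base A/T
vs G/C at 4:1 and are explicit stand-ins, not estimates from real genomes.
5′UTR and IGR sequences are kept AUG-free and IGRs open with stop codons in
all three phases, so each specified start is the first AUG of its reading
frame segment. A candidate sequence is accepted only when an internal,
independently coded scanner confirms that the maximal ORFs of ≥ 120 residues
(`clean_min_aa`) are exactly the specified ones; otherwise it is redrawn.
This makes annotation round-trips exact by construction and means the
round-trip tests genuinely test the annotator. Kozak flanks (the −3..−1
triplet and the second codon) can be pinned per ORF to emulate printed
initiation contexts.

**qPCR.** Cq = slope·log₁₀(true copies) + intercept + N(0, sd) per
replicate; defaults slope −3.32, intercept 37, sd 0.15, triplicates,
mirroring a typical instrument calibration and run-to-run noise. Reactions
below the dropout threshold (1 copy/reaction) emit no Cq and a failing
melting curve. The four-pair strand panel builder places two assay pairs in
the genomic-only region and two in the genomic+subgenomic region.

**Pileups.** Poisson coverage (default 350×, a deep-sequencing depth) with
multinomial base counts: error mass 0.005 spread over non-consensus bases,
planted variants receiving their stated minor-allele frequency.

**Surveys.** Binomial positives per site × species × stage cell.

What passing tests show — and do not. The generators reproduce the
*statistical structure the analyses assume* (log-linear Cq, multinomial
counts, i.i.d. codon draws), so recovery tests validate the estimators and
their plumbing, not robustness to real-data pathologies: no PCR inhibition
or efficiency drift, no strand-leakage in cDNA priming, no alignment
artifacts or strand-biased errors in pileups, no phylogenetic correlation
among reference genomes, and codon draws are i.i.d. rather than
autocorrelated as in real coding sequence. Conclusions about real samples
therefore rest on the modelled mechanisms being adequate, exactly as in the
original instrument-software conventions these modules re-implement.

## Problem sizes

The test suite and the acceptance script run at the sizes the analyses
themselves use: ~10 kb genomes (50-seed round-trips), 100 simulated panels
for ratio/titer recovery, 100 random tables for the CA identity, 10⁵–3×10⁵ nt
sequences for the dinucleotide law-of-large-numbers check, and
1–2 kb pileups at 400–1000× for variant recovery. These are full-scale for
every quantity reported; nothing is scaled down from the study conditions.

## Known limitations

Reverse-strand ORF search is off by default; no IRES or subgenomic-promoter
motif search (none was found in the source analyses); no domain/motif
annotation (that is a database-search task); melting-curve waveforms are
reduced to pass/fail flags; CA supports two host classes only; no
confidence intervals on prevalence.
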