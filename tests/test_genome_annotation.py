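"""ORF finding, layout derivation, Kozak scoring and read-through detection."""

import itertools

import pytest

from negevkit import genome_annotation as ga
from negevkit import synthetic_data as syn
from negevkit.genome_annotation import GenomeRecord, InputError, OrfAnnotation


def rec(seq: str) -> GenomeRecord:
    return GenomeRecord(id="t", description="", sequence=seq)


class TestNormalization:
    def test_rna_maps_to_dna(self):
        assert rec("augc").sequence == "ATGC"

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            rec("")

    def test_bad_alphabet_rejected(self):
        with pytest.raises(InputError):
            rec("ATGXZ")


class TestFindOrfs:
    def test_minimal_orf(self):
        orfs = ga.find_orfs(rec("ATGAAATAA"), min_aa=1)
        assert len(orfs) == 1
        o = orfs[0]
        assert (o.start, o.end, o.aa_length, o.frame) == (1, 9, 2, 0)

    def test_no_orf_is_empty_list(self):
        assert ga.find_orfs(rec("CCCCCCCCC"), min_aa=1) == []

    def test_orf_without_stop_not_reported(self):
        assert ga.find_orfs(rec("ATGAAAAAA"), min_aa=1) == []

    def test_inner_aug_recorded_as_alt_start(self):
        # ATG AAA ATG CCC TAA: first AUG opens, inner AUG at 7 is an alt start
        orfs = ga.find_orfs(rec("ATGAAAATGCCCTAA"), min_aa=1)
        assert len(orfs) == 1
        assert orfs[0].start == 1 and orfs[0].alt_starts == [7]

    def test_min_aa_filters(self):
        seq = "ATGAAATAA"  # 2 residues
        assert ga.find_orfs(rec(seq), min_aa=3) == []

    def test_orfs_ordered_by_start(self):
        seq = "ATGAAATAA" + "C" + "ATGCCCGGGTAA"
        orfs = ga.find_orfs(rec(seq), min_aa=1)
        assert [o.start for o in orfs] == sorted(o.start for o in orfs)

    def test_no_internal_stop_invariant(self, default_genome):
        g = default_genome
        for o in ga.find_orfs(g.record, min_aa=120):
            inner = g.record.sequence[o.start - 1 : o.end - 3]
            codons = [inner[i : i + 3] for i in range(0, len(inner), 3)]
            assert not any(c in ga.STOP_CODONS for c in codons)


class TestLayout:
    def test_layout_definition(self):
        seq = "C" * 9 + "ATG" + "GGG" * 8 + "TAA" + "C" * 10 + "ATG" + "CCC" * 8 + "TGA" + "G" * 20
        g = rec(seq)
        orfs = ga.find_orfs(g, min_aa=5)
        lay = ga.annotate_layout(g, orfs)
        assert (lay.five_utr.start, lay.five_utr.end) == (1, 9)
        assert (lay.igrs[0].start, lay.igrs[0].end) == (40, 49)
        assert (lay.three_utr.start, lay.three_utr.end) == (80, len(seq))
        assert lay.polya_start is None

    def test_polya_run_detection(self):
        seq = "ATGAAATAA" + "CCC" + "A" * 10
        lay = ga.annotate_layout(rec(seq), ga.find_orfs(rec(seq), min_aa=1), polya_min_run=8)
        assert lay.polya_start == len(seq) - 9
        assert lay.three_utr.end == lay.polya_start - 1

    def test_short_a_run_is_not_polya(self):
        seq = "ATGAAATAA" + "CCC" + "A" * 5
        lay = ga.annotate_layout(rec(seq), ga.find_orfs(rec(seq), min_aa=1), polya_min_run=8)
        assert lay.polya_start is None

    def test_overlapping_orfs_rejected(self):
        g = rec("ATGAAATAACCC")
        a = OrfAnnotation("a", 1, 9, 0, 2)
        b = OrfAnnotation("b", 7, 12, 0, 1)
        with pytest.raises(InputError):
            ga.annotate_layout(g, [a, b])

    def test_out_of_bounds_rejected(self):
        g = rec("ATGAAATAA")
        with pytest.raises(InputError):
            ga.annotate_layout(g, [OrfAnnotation("a", 4, 12, 0, 2)])

    def test_spans_tile_genome(self, default_genome):
        g = default_genome
        lay = ga.annotate_layout(g.record, g.layout.orfs)
        total = len(lay.five_utr)
        total += sum(o.end - o.start + 1 for o in lay.orfs)
        total += sum(len(s) for s in lay.igrs if s)
        total += len(lay.three_utr)
        total += lay.genome_length - lay.polya_start + 1
        assert total == lay.genome_length


class TestKozak:
    def test_suboptimal_printed_context_scores_zero(self):
        # the nominal downstream-ORF context UCU-AUG-UUA: no key satisfied
        g = rec("TCTATGTTA")
        ctx = ga.extract_kozak(g, 4)
        assert ctx.sequence == "TCTATGTTA"
        assert (ctx.key_matches, ctx.score) == (0, 0)

    @pytest.mark.parametrize(
        "context, matches, score",
        [
            ("GCCATGGGG", 3, 6),  # -3=G, -1=C, +4=G: all keys
            ("TAAATGCGC", 0, 0),  # coat-protein candidate UAA-AUG-CGC
            ("AATATGACT", 1, 3),  # candidate AAU-AUG-ACU: only -3=A
            ("ACCATGGAA", 3, 6),
            ("TCTATGGTT", 1, 2),  # only +4=G
            ("TCCATGTTT", 1, 1),  # only -1=C
        ],
    )
    def test_key_position_rule(self, context, matches, score):
        ctx = ga.extract_kozak(rec(context), 4)
        assert (ctx.key_matches, ctx.score) == (matches, score)

    def test_truncated_context_flagged_and_unscored(self):
        ctx = ga.extract_kozak(rec("ATGAAATAA"), 1)
        assert ctx.truncated
        assert ctx.score is None
        with pytest.raises(InputError):
            ga.score_kozak(ctx)

    def test_non_aug_position_rejected(self):
        with pytest.raises(InputError):
            ga.extract_kozak(rec("TCTATGTTA"), 1)

    def test_score_monotone_in_key_positions(self):
        # satisfying any additional key position never decreases the score
        def make(m3, m1, p4):
            return ga.KozakContext(f"{m3}C{m1}ATG{p4}AA", 4, False)

        options = {"-3": ("T", "A"), "-1": ("T", "C"), "+4": ("T", "G")}
        for m3, m1, p4 in itertools.product(*options.values()):
            _, s = ga.score_kozak(make(m3, m1, p4))
            for pos, (off, on) in options.items():
                vals = {"-3": m3, "-1": m1, "+4": p4}
                if vals[pos] == off:
                    vals[pos] = on
                    _, s2 = ga.score_kozak(make(vals["-3"], vals["-1"], vals["+4"]))
                    assert s2 > s


class TestReadthrough:
    def test_extension_past_leaky_uag(self):
        orf_seq = "ATG" + "AAA" * 2 + "TAG"
        ext_seq = "CCC" * 30 + "TAA"
        g = rec(orf_seq + ext_seq + "GG")
        orf = ga.find_orfs(g, min_aa=1)[0]
        ext = ga.find_readthrough(g, orf)
        assert ext is not None and ext.stop_found
        assert (ext.start, ext.end) == (13, 13 + 92)
        assert ext.aa_extension == 30

    def test_non_uag_stop_gives_none(self):
        g = rec("ATGAAATAACCCCCC")
        orf = ga.find_orfs(g, min_aa=1)[0]
        assert ga.find_readthrough(g, orf) is None

    def test_uag_at_genome_end_is_empty_flagged(self):
        g = rec("ATGAAATAG")
        orf = ga.find_orfs(g, min_aa=1)[0]
        ext = ga.find_readthrough(g, orf)
        assert ext.empty and not ext.stop_found

    def test_default_synthetic_coat_orf_is_leaky(self, default_genome):
        g = default_genome
        orf2 = g.layout.orfs[1]
        ext = ga.find_readthrough(g.record, orf2)
        assert ext is not None


class TestGeneratorRoundTrip:
    @pytest.mark.parametrize("seed", range(10))
    def test_layout_recovered_exactly(self, seed):
        g = syn.generate_genome(syn.GenomeSpec(), seed=seed)
        orfs = ga.find_orfs(g.record, min_aa=g.spec.clean_min_aa)
        got = [(o.start, o.end, o.frame, o.aa_length, o.alt_starts) for o in orfs]
        want = [(o.start, o.end, o.frame, o.aa_length, o.alt_starts) for o in g.layout.orfs]
        assert got == want
        lay = ga.annotate_layout(g.record, ga.major_orfs(orfs, 3))
        assert lay.three_utr == g.layout.three_utr
        assert lay.polya_start == g.layout.polya_start
        assert lay.five_utr == g.layout.five_utr

    def test_truth_contexts_match_extraction(self, default_genome):
        g = default_genome
        for orf in g.layout.orfs:
            assert ga.extract_kozak(g.record, orf.start).sequence == g.contexts[orf.label]
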