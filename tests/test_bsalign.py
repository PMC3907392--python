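"""Conversion, the built-in aligner, discard rules, non-conversion rate."""

import random

import pytest

import bsmeth as b
from bsmeth.bsalign import (
    AlignmentRecord,
    BuiltinAligner,
    convert_read,
    convert_reference,
    filter_alignments,
    nonconversion_rate,
)
from bsmeth.types import A_RICH, T_RICH, Genome, Read, revcomp


def mk_read(seq, richness=T_RICH, quals=None, id="r", mate=0):
    return Read(id, seq, tuple(quals or [40] * len(seq)), mate, richness)


def mk_record(**kw):
    defaults = dict(
        read_id="r", richness=T_RICH, chrom="c", pos=0, strand="+",
        conversion_used="CT", mapq=40, cigar="4M", n_hits=1,
        mismatches_restored=(), watson_seq="ACGT", watson_qual=(40,) * 4,
    )
    defaults.update(kw)
    return AlignmentRecord(**defaults)


class TestConvertRead:
    def test_t_rich_c_to_t(self):
        out = convert_read(mk_read("ACGC"), mark_quality=20)
        assert out.converted_seq == "ATGT"
        assert out.marked == {1, 3}

    def test_a_rich_g_to_a(self):
        out = convert_read(mk_read("AGGT", richness=A_RICH), mark_quality=20)
        assert out.converted_seq == "AAAT"
        assert out.marked == {1, 2}

    def test_no_target_base_identity(self):
        out = convert_read(mk_read("ATGT"))
        assert out.converted_seq == "ATGT" and out.marked == frozenset()

    def test_mark_respects_quality(self):
        out = convert_read(mk_read("CC", quals=[3, 30]), mark_quality=5)
        assert out.marked == {1}

    def test_restoring_marked_positions_is_identity(self):
        seq = "CCATGCTTAC"
        out = convert_read(mk_read(seq), mark_quality=0)
        restored = "".join(
            "C" if i in out.marked else bch for i, bch in enumerate(out.converted_seq)
        )
        assert restored == seq


class TestConvertReference:
    def test_both_conversions(self):
        ct, ga = convert_reference(Genome({"c": "ACGT"}))
        assert ct["c"] == "ATGT" and ga["c"] == "ACAT"

    def test_all_a_unchanged(self):
        ct, ga = convert_reference(Genome({"c": "AAAA"}))
        assert ct["c"] == ga["c"] == "AAAA"

    def test_lambda_carried_through(self):
        g = Genome({"c": "ACGT", "chrLam": "ACGT"}, lambda_name="chrLam")
        ct, ga = convert_reference(g)
        assert "chrLam" in ct and "chrLam" in ga
        assert ct.lambda_name == ga.lambda_name == "chrLam"


@pytest.fixture(scope="module")
def fixture_genome():
    rng = random.Random(21)
    seq = "".join(rng.choice("ACGT") for _ in range(4000))
    return Genome({"chrA": seq})


class TestBuiltinAligner:
    def test_unique_exact_hit_only_bisulfite_mismatches(self, fixture_genome):
        seq = fixture_genome["chrA"][100:180]
        read = mk_read(seq.replace("C", "T"))  # fully converted Watson read
        rec = BuiltinAligner(fixture_genome, max_mismatches=2).align_read(read)
        assert rec is not None
        assert (rec.chrom, rec.pos, rec.strand, rec.n_hits) == ("chrA", 100, "+", 1)
        assert all(rb == "T" and fb == "C" for rb, fb, _ in rec.mismatches_restored)

    def test_crick_strand_read(self, fixture_genome):
        # T-rich read from the Crick strand: revcomp of Watson, then C->T
        wseq = fixture_genome["chrA"][200:280]
        read = mk_read(revcomp(wseq).replace("C", "T"))
        rec = BuiltinAligner(fixture_genome, max_mismatches=2).align_read(read)
        assert rec is not None
        assert (rec.pos, rec.strand, rec.conversion_used) == (200, "-", "CT")

    def test_a_rich_mate_maps_to_watson_sites(self, fixture_genome):
        # mate 2 of a Watson fragment: revcomp of the converted segment
        wseq = fixture_genome["chrA"][300:380]
        read = mk_read(revcomp(wseq.replace("C", "T")), richness=A_RICH, mate=2)
        rec = BuiltinAligner(fixture_genome, max_mismatches=2).align_read(read)
        assert rec is not None
        assert (rec.pos, rec.strand, rec.conversion_used) == (300, "+", "GA")
        # watson_seq restores the original Watson bases including Cs
        assert rec.watson_seq == wseq.replace("C", "T")

    def test_duplicated_region_gives_two_hits(self):
        unit = "ATGTTAGGATCAATTGGCCATAGATTGGCCATTGCAATTGGACCATAGAAT"
        g = Genome({"c": unit + "TT" + unit})
        read = mk_read(unit.replace("C", "T")[:40])
        rec = BuiltinAligner(g, max_mismatches=0).align_read(read)
        assert rec.n_hits == 2
        assert rec.mapq == 0

    def test_unalignable_random_read(self, fixture_genome):
        rng = random.Random(5)
        read = mk_read("".join(rng.choice("ACGT") for _ in range(80)))
        rec = BuiltinAligner(fixture_genome, max_mismatches=2).align_read(read)
        assert rec is None

    def test_tolerates_up_to_k_mismatches(self, fixture_genome):
        seq = list(fixture_genome["chrA"][500:580].replace("C", "T"))
        for i in (10, 40, 70):
            seq[i] = "G" if seq[i] != "G" else "A"
        rec = BuiltinAligner(fixture_genome, max_mismatches=3).align_read(
            mk_read("".join(seq))
        )
        assert rec is not None and rec.pos == 500


class TestFilterRules:
    def test_multi_hit_discarded(self):
        kept, counts = filter_alignments([mk_record(n_hits=3)])
        assert kept == [] and counts["multi_hit"] == 1

    def test_wrong_strand_discarded(self):
        rec = mk_record(conversion_used="GA")  # T-rich on a G->A strand
        kept, counts = filter_alignments([rec])
        assert kept == [] and counts["wrong_strand"] == 1
        rec2 = mk_record(richness=A_RICH, conversion_used="CT")
        kept, counts = filter_alignments([rec2])
        assert kept == [] and counts["wrong_strand"] == 1

    def test_unconverted_c_over_t_discarded(self):
        rec = mk_record(mismatches_restored=(("C", "T", 2),))
        kept, counts = filter_alignments([rec])
        assert kept == [] and counts["unconverted_c"] == 1
        # minus-strand mirror: read G over reference A
        rec2 = mk_record(strand="-", mismatches_restored=(("G", "A", 2),))
        kept, _ = filter_alignments([rec2])
        assert kept == []

    def test_ct_mismatch_threshold_configurable(self):
        rec = mk_record(mismatches_restored=(("C", "T", 2),))
        kept, _ = filter_alignments([rec], max_ct_mismatch=1)
        assert kept == [rec]

    def test_benign_mismatches_kept(self):
        # T over C is ordinary bisulfite conversion, not an offence
        rec = mk_record(mismatches_restored=(("T", "C", 1), ("A", "G", 3)))
        kept, counts = filter_alignments([rec])
        assert kept == [rec] and counts["unconverted_c"] == 0

    def test_dedup_keeps_highest_quality(self):
        lo = mk_record(read_id="lo", watson_qual=(10,) * 4)
        hi = mk_record(read_id="hi", watson_qual=(40,) * 4)
        kept, counts = filter_alignments([lo, hi], dedup=True)
        assert [r.read_id for r in kept] == ["hi"]
        assert counts["duplicate"] == 1

    def test_dedup_order_independent(self):
        recs = [
            mk_record(read_id=f"r{i}", watson_qual=(q,) * 4)
            for i, q in enumerate([20, 20, 35, 10])
        ]
        fwd, _ = filter_alignments(list(recs), dedup=True)
        rev, _ = filter_alignments(list(reversed(recs)), dedup=True)
        assert [r.read_id for r in fwd] == [r.read_id for r in rev] == ["r2"]

    def test_rules_commute_with_input_order(self):
        recs = [
            mk_record(read_id="a", n_hits=2),
            mk_record(read_id="b"),
            mk_record(read_id="c", conversion_used="GA"),
            mk_record(read_id="d", mismatches_restored=(("C", "T", 0),)),
        ]
        k1, c1 = filter_alignments(list(recs))
        k2, c2 = filter_alignments(list(reversed(recs)))
        assert {r.read_id for r in k1} == {r.read_id for r in k2} == {"b"}
        assert c1 == c2


class TestNonconversion:
    def _lambda_genome(self):
        return Genome({"chrLam": "AC" * 50}, lambda_name="chrLam")

    def _records(self, n_c, n_t):
        g = self._lambda_genome()
        recs = []
        for i in range(n_c + n_t):
            base = "C" if i < n_c else "T"
            recs.append(
                mk_record(
                    read_id=f"r{i}", chrom="chrLam", pos=0,
                    watson_seq="A" + base, watson_qual=(40, 40), cigar="2M",
                    mismatches_restored=(),
                )
            )
        return g, recs

    def test_ratio(self):
        g, recs = self._records(5, 995)
        est = nonconversion_rate(recs, g)
        assert est.rate == pytest.approx(0.005)
        assert (est.n_unconverted, est.n_total) == (5, 1000)

    def test_zero_c_gives_zero(self):
        g, recs = self._records(0, 10)
        assert nonconversion_rate(recs, g).rate == 0.0

    def test_no_lambda_is_an_error(self):
        with pytest.raises(ValueError, match="manually"):
            nonconversion_rate([], Genome({"c": "ACGT"}))

    def test_uncovered_lambda_is_an_error(self):
        g = self._lambda_genome()
        with pytest.raises(ValueError, match="manually"):
            nonconversion_rate([], g)

    def test_recovery_from_simulated_lambda(self):
        """chrLam simulated at ~20x with nonconversion 0.005 recovers p-hat."""
        genome = b.add_lambda_control(
            b.make_toy_genome(2_000, n_islands=0, seed=2), length=20_000
        )
        truth = b.TruthModel(0.7, 0.02, 0.02, nonconversion=0.005, seed=1)
        m1, m2, _ = b.simulate_wgbs(
            genome, truth, coverage=20, error_rate=0.0, random_frac=0.0, seed=3
        )
        aligner = BuiltinAligner(genome, max_mismatches=2)
        kept, _ = filter_alignments(list(b.align(m1 + m2, aligner=aligner)))
        est = nonconversion_rate(kept, genome)
        assert 0.004 <= est.rate <= 0.006


class TestSamRoundTrip:
    def test_records_survive_sam(self, tmp_path, fixture_genome):
        seq = fixture_genome["chrA"][100:180]
        reads = [
            mk_read(seq.replace("C", "T"), id="w"),
            mk_read(revcomp(fixture_genome["chrA"][200:280]).replace("C", "T"), id="c"),
        ]
        aligner = BuiltinAligner(fixture_genome, max_mismatches=2)
        recs = [aligner.align_read(r) for r in reads]
        path = str(tmp_path / "x.sam")
        from bsmeth.bsalign import read_sam, write_sam

        write_sam(recs, fixture_genome, path)
        back = read_sam(path, fixture_genome)
        assert [(r.read_id, r.chrom, r.pos, r.strand, r.conversion_used,
                 r.n_hits, r.watson_seq, r.mismatches_restored) for r in back] == [
            (r.read_id, r.chrom, r.pos, r.strand, r.conversion_used,
             r.n_hits, r.watson_seq, r.mismatches_restored) for r in recs
        ]
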