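import pytest

from spliceimpact import intervals as iv
from spliceimpact import isoforms, proteins
from spliceimpact.models import AltExonEvent, GenomeInterval

from conftest import make_transcript

from oracles import revcomp


def _event(cls, start, end, chrom="chr1", strand="+", host="T1"):
    return AltExonEvent(
        probeset_id="PS1",
        gene_symbol="GENE1",
        region=GenomeInterval(chrom, start, end, strand),
        event_class=cls,
        host_transcript_id=host,
    )


THREE_EXONS = ((0, 10), (20, 30), (40, 50))


class TestBuildPair:
    def test_skipped_exon_removes_middle_exon(self):
        host = make_transcript(exons=THREE_EXONS)
        pair = isoforms.build_pair(_event("skipped_exon", 20, 30), host)
        assert pair.inclusion is host
        assert pair.exclusion.exon_spans == [(0, 10), (40, 50)]

    def test_alt_splice_site_trims_exon_edge(self):
        host = make_transcript(exons=THREE_EXONS)
        pair = isoforms.build_pair(_event("alt_5ss", 25, 30), host)
        assert pair.exclusion.exon_spans == [(0, 10), (20, 25), (40, 50)]

    def test_intron_retention_merges_flanking_exons(self):
        host = make_transcript(exons=THREE_EXONS)
        pair = isoforms.build_pair(_event("intron_retention", 10, 20), host)
        assert pair.exclusion is host
        assert pair.inclusion.exon_spans == [(0, 30), (40, 50)]

    def test_retention_region_must_be_fully_intronic(self):
        host = make_transcript(exons=THREE_EXONS)
        with pytest.raises(isoforms.PairBuildError, match="intronic"):
            isoforms.build_pair(_event("intron_retention", 5, 20), host)

    def test_region_must_overlap_host_exons(self):
        host = make_transcript(exons=THREE_EXONS)
        with pytest.raises(isoforms.PairBuildError, match="overlap"):
            isoforms.build_pair(_event("skipped_exon", 12, 18), host)

    def test_alt_polya_drops_region_and_downstream(self):
        host = make_transcript(exons=THREE_EXONS)
        pair = isoforms.build_pair(_event("alt_polyA", 25, 30), host)
        assert pair.exclusion.exon_spans == [(0, 10), (20, 25)]

    def test_alt_promoter_drops_region_and_upstream(self):
        host = make_transcript(exons=THREE_EXONS)
        pair = isoforms.build_pair(_event("alt_promoter", 0, 10), host)
        assert pair.exclusion.exon_spans == [(20, 30), (40, 50)]

    def test_minus_strand_polya_drops_genomic_left(self):
        # transcript-orientation downstream = genomically left on the minus strand
        host = make_transcript(strand="-", exons=THREE_EXONS)
        pair = isoforms.build_pair(
            _event("alt_polyA", 20, 25, strand="-"), host
        )
        assert pair.exclusion.exon_spans == [(25, 30), (40, 50)]

    def test_complex_requires_two_explicit_transcripts(self):
        host = make_transcript(exons=THREE_EXONS)
        alt = make_transcript(tid="T2", exons=((0, 10), (40, 50)))
        pair = isoforms.build_pair(
            _event("complex", 20, 30, host="T1|T2"),
            host,
            {"T1": host, "T2": alt},
        )
        assert pair.inclusion is host and pair.exclusion is alt
        with pytest.raises(isoforms.PairBuildError):
            isoforms.build_pair(_event("complex", 20, 30, host="T1"), host, {"T1": host})

    @pytest.mark.parametrize(
        "cls,region",
        [("skipped_exon", (20, 30)), ("alt_5ss", (25, 30)), ("alt_3ss", (20, 24))],
    )
    def test_exon_unions_differ_exactly_by_region(self, cls, region):
        host = make_transcript(exons=THREE_EXONS)
        pair = isoforms.build_pair(_event(cls, *region), host)
        removed = iv.subtract(pair.inclusion.exon_spans, region)
        assert removed == pair.exclusion.exon_spans

    def test_strand_symmetry_of_spliced_sequences(self):
        # mirror the whole locus: identical mRNAs before and after the event
        seq = "ACGTAACCGGTTACGTTGCAACGGTTAACCGGTTAACCGGTTACGTACGT"
        genome_fwd = {"chr1": seq}
        genome_rev = {"chr1": revcomp(seq)}
        L = len(seq)
        host_fwd = make_transcript(exons=THREE_EXONS)
        mirror = tuple(sorted((L - e, L - s) for s, e in THREE_EXONS))
        host_rev = make_transcript(strand="-", exons=mirror)
        ev_fwd = _event("skipped_exon", 20, 30)
        ev_rev = _event("skipped_exon", L - 30, L - 20, strand="-")
        for pick in ("inclusion", "exclusion"):
            fwd = getattr(isoforms.build_pair(ev_fwd, host_fwd), pick)
            rev = getattr(isoforms.build_pair(ev_rev, host_rev), pick)
            assert proteins.splice(fwd, genome_fwd) == proteins.splice(rev, genome_rev)


class TestPickHost:
    def test_explicit_host_id_wins(self):
        t1 = make_transcript(tid="T1", exons=((0, 10),))
        t2 = make_transcript(tid="T2", exons=((0, 10),), cds=((0, 9),))
        assert isoforms.pick_host(_event("skipped_exon", 0, 5, host="T1"), [t1, t2]) is t1

    def test_fallback_prefers_longest_cds_then_lexicographic_id(self):
        short = make_transcript(tid="TA", exons=((0, 30),), cds=((0, 9),))
        long1 = make_transcript(tid="TC", exons=((0, 30),), cds=((0, 21),))
        long2 = make_transcript(tid="TB", exons=((0, 30),), cds=((3, 24),))
        ev = _event("skipped_exon", 0, 5, host="")
        assert isoforms.pick_host(ev, [short, long1, long2]) is long2

    def test_missing_host_transcript_is_an_error(self):
        t1 = make_transcript(tid="T1", exons=((0, 10),))
        with pytest.raises(isoforms.PairBuildError, match="TX"):
            isoforms.pick_host(_event("skipped_exon", 0, 5, host="TX"), [t1])


class TestClassifyRegion:
    def _coding_host(self):
        return make_transcript(
            exons=THREE_EXONS, cds=((5, 10), (20, 30), (40, 45))
        )

    def test_region_inside_internal_cds_exon_is_coding(self):
        host = self._coding_host()
        ev = _event("skipped_exon", 20, 30)
        pair = isoforms.build_pair(ev, host)
        assert isoforms.classify_region(ev, pair) == "coding"

    def test_region_in_utr_is_utr_only(self):
        host = self._coding_host()
        ev = _event("alt_polyA", 45, 50)
        pair = isoforms.build_pair(ev, host)
        assert isoforms.classify_region(ev, pair) == "utr_only"

    def test_region_straddling_cds_boundary_is_mixed(self):
        host = self._coding_host()
        ev = _event("alt_polyA", 40, 50)
        pair = isoforms.build_pair(ev, host)
        assert isoforms.classify_region(ev, pair) == "mixed"

    def test_non_coding_inclusion_is_not_determined(self):
        host = make_transcript(exons=THREE_EXONS)
        ev = _event("skipped_exon", 20, 30)
        pair = isoforms.build_pair(ev, host)
        assert isoforms.classify_region(ev, pair) == "not_determined"
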