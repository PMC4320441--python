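import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spliceimpact import proteins
from spliceimpact.models import ProteinRecord

from conftest import make_transcript

from oracles import brute_translate, revcomp


def _protein(seq):
    return ProteinRecord(sequence=seq, coding_status="coding" if seq else "non_coding")


class TestTranslate:
    def test_simple_plus_strand_cds(self):
        genome = {"chr1": "ATGGAATAA"}
        t = make_transcript(exons=((0, 9),), cds=((0, 9),))
        rec = proteins.translate(t, genome)
        assert rec.sequence == "ME"
        assert rec.coding_status == "coding"

    def test_minus_strand_reverse_complement(self):
        genome = {"chr1": revcomp("ATGGAATAA")}
        t = make_transcript(strand="-", exons=((0, 9),), cds=((0, 9),))
        assert proteins.translate(t, genome).sequence == "ME"

    def test_non_coding_transcript_gives_empty_record(self):
        t = make_transcript(exons=((0, 9),))
        rec = proteins.translate(t, {"chr1": "ATGGAATAA"})
        assert rec.sequence == "" and rec.coding_status == "non_coding"

    def test_frameshift_tail_diverges_to_new_stop(self):
        # removing one nucleotide of an internal codon shifts the frame;
        # the tail is hand-translated from the shifted sequence
        cds = "ATG" + "GCTAAGGTTCCAGAC" + "TGGTAA"  # MAKVPDW*
        genome = {"chr1": cds}
        full = make_transcript(exons=((0, len(cds)),), cds=((0, len(cds)),))
        assert proteins.translate(full, genome).sequence == "MAKVPDW"
        # exclusion drops base 7 (the 'A' of AAG): frame shifts after "ATGGCTA"
        shifted = make_transcript(
            exons=((0, 7), (8, len(cds))), cds=((0, 7), (8, len(cds)))
        )
        expected = brute_translate(cds[:7] + cds[8:])
        rec = proteins.translate(shifted, genome)
        assert rec.sequence == expected
        assert rec.sequence[:2] == "MA" and rec.sequence != "MAKVPDW"

    def test_start_loss_rescans_for_downstream_orf(self):
        rng = np.random.default_rng(5)
        body = "".join(rng.choice(list("CGT"), size=31 * 3))
        mrna = "CCCCCC" + "ATG" + body + "TAA"
        genome = {"chr1": mrna}
        # annotated CDS begins at 0, which is not an ATG -> rescan finds base 6
        t = make_transcript(exons=((0, len(mrna)),), cds=((0, len(mrna)),))
        rec = proteins.translate(t, genome)
        assert rec.sequence == brute_translate("ATG" + body)
        assert rec.coding_status == "coding"

    def test_rescan_requires_minimum_orf(self):
        mrna = "CCCCCC" + "ATG" + "GGTCCT" + "TAA" + "C" * 30
        t = make_transcript(exons=((0, len(mrna)),), cds=((0, len(mrna)),))
        rec = proteins.translate(t, {"chr1": mrna})
        assert rec.sequence == "" and rec.coding_status == "non_coding"

    def test_premature_stop_far_from_last_junction_is_flagged(self):
        exon1 = "ATGAAATAA" + "C" * 71  # stop at offset 6, junction at 80
        genome = {"chr1": exon1 + "G" * 10 + "CCCCCCCCCC"}
        t = make_transcript(exons=((0, 80), (90, 100)), cds=((0, 9),))
        rec = proteins.translate(t, genome)
        assert rec.sequence == "MK"
        assert rec.coding_status == "premature_stop_flagged"

    def test_stop_near_last_junction_not_flagged(self):
        exon1 = "ATGAAATAA" + "C" * 11  # junction at 20, distance 14 <= 50
        genome = {"chr1": exon1 + "G" * 10 + "CCCCCCCCCC"}
        t = make_transcript(exons=((0, 20), (30, 40)), cds=((0, 9),))
        assert proteins.translate(t, genome).coding_status == "coding"

    def test_unknown_nucleotide_translates_to_x_with_warning(self):
        genome = {"chr1": "ATGGRATAA"}
        t = make_transcript(exons=((0, 9),), cds=((0, 9),))
        with pytest.warns(UserWarning, match="unknown nucleotide"):
            rec = proteins.translate(t, genome)
        assert rec.sequence == "MX"

    def test_agrees_with_codon_table_on_random_multiexon_cds(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for trial in range(100):
            ncod = int(rng.integers(5, 40))
            cds = "ATG" + "".join(rng.choice(bases, size=3 * ncod)) + "TAA"
            n_exons = int(rng.integers(1, 4))
            cut_points = sorted(
                rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False)
            )
            pieces = np.split(np.array(list(cds)), cut_points)
            strand = "+" if trial % 2 == 0 else "-"
            segs, introns, pos = [], [], 0
            layout = []
            for i, piece in enumerate(pieces):
                seg = "".join(piece)
                layout.append(seg)
                segs.append((pos, pos + len(seg)))
                pos += len(seg)
                if i < len(pieces) - 1:
                    intron = "".join(rng.choice(bases, size=int(rng.integers(5, 20))))
                    layout.append(intron)
                    pos += len(intron)
            contig = "".join(layout)
            if strand == "-":
                contig = revcomp(contig)
                L = len(contig)
                segs = sorted((L - e, L - s) for s, e in segs)
            t = make_transcript(strand=strand, exons=tuple(segs), cds=tuple(segs))
            assert proteins.translate(t, {"chr1": contig}).sequence == brute_translate(
                cds
            ), f"trial {trial}"


class TestDiff:
    def test_identical_sequences_unchanged(self):
        d = proteins.diff(_protein("MKLAV"), _protein("MKLAV"))
        assert d.n_altered == 0 and d.frac_altered == 0.0
        assert not d.protein_changed

    def test_internal_deletion_hand_example(self):
        d = proteins.diff(_protein("MKLAVGDE"), _protein("MKLDE"))
        assert (d.prefix_len, d.suffix_len) == (3, 2)
        assert (d.altered_incl, d.altered_excl) == (3, 0)
        assert d.n_altered == 3
        assert d.frac_altered == pytest.approx(0.375)

    def test_empty_exclusion_is_total_loss(self):
        d = proteins.diff(_protein("MKLAV"), _protein(""))
        assert d.n_altered == 5 and d.frac_altered == 1.0

    @pytest.mark.parametrize(
        "incl,excl,k",
        [("MABCDEFGHIK", "MABCGHIK", 3), ("MQWERTYX", "MQWYX", 3), ("MAVD", "MAD", 1)],
    )
    def test_inframe_deletion_with_distinct_flanks_counts_exactly(
        self, incl, excl, k
    ):
        assert proteins.diff(_protein(incl), _protein(excl)).n_altered == k

    @given(
        a=st.text(alphabet="ACDEFG", max_size=30),
        b=st.text(alphabet="ACDEFG", max_size=30),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_diff_invariants(self, a, b):
        d = proteins.diff(_protein(a), _protein(b))
        assert d.prefix_len + d.suffix_len + d.altered_incl == d.len_incl
        assert d.prefix_len + d.suffix_len + d.altered_excl == d.len_excl
        assert 0.0 <= d.frac_altered <= 1.0
        assert d.protein_changed == (d.n_altered > 0)
        swapped = proteins.diff(_protein(b), _protein(a))
        assert swapped.n_altered == d.n_altered
        assert swapped.frac_altered == d.frac_altered
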