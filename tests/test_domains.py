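import numpy as np
import pytest

from spliceimpact import domains as dom
from spliceimpact.models import DomainHit, ResidueDiff

from oracles import domain_status_by_sets, prefix_suffix_scan


def _hit(start, end, acc="D1", desc="protein kinase domain"):
    return DomainHit(
        protein_key="G", accession=acc, name="Kin", description=desc,
        res_start=start, res_end=end,
    )


def _diff(prefix, suffix, len_incl, len_excl):
    return ResidueDiff(
        prefix_len=prefix, suffix_len=suffix, len_incl=len_incl, len_excl=len_excl
    )


class TestResidueMap:
    def test_identity_for_identical_proteins(self):
        rmap = dom.residue_map(_diff(8, 0, 8, 8))
        assert [rmap(i) for i in range(8)] == list(range(8))

    def test_prefix_suffix_offsets_hand_example(self):
        rmap = dom.residue_map(_diff(3, 2, 8, 5))
        assert [rmap(i) for i in range(3)] == [0, 1, 2]
        assert [rmap(i) for i in (3, 4, 5)] == [None, None, None]
        assert [rmap(i) for i in (6, 7)] == [3, 4]

    def test_empty_exclusion_maps_everything_absent(self):
        rmap = dom.residue_map(_diff(0, 0, 6, 0))
        assert all(rmap(i) is None for i in range(6))

    def test_out_of_bounds_residue_rejected(self):
        rmap = dom.residue_map(_diff(3, 2, 8, 5))
        with pytest.raises(IndexError):
            rmap(8)


class TestClassifyImpact:
    def test_alteration_past_single_domain_is_c_terminal(self):
        # domain [9,49) untouched; altered block is residues 59-69
        diff = _diff(59, 10, 80, 70)
        statuses, changed, region = dom.classify_impact([_hit(9, 49)], diff)
        assert statuses[0].status == "intact"
        assert not changed
        assert region == "c_term"

    def test_truncation_into_domain(self):
        # exclusion protein ends at residue 30 inside domain [9,49)
        diff = _diff(30, 0, 80, 30)
        statuses, changed, region = dom.classify_impact([_hit(9, 49)], diff)
        assert statuses[0].status == "truncated"
        assert changed and region == "domain"

    def test_fully_absent_domain_is_lost(self):
        diff = _diff(5, 10, 80, 40)
        (s,), changed, _ = dom.classify_impact([_hit(10, 60)], diff)
        assert s.status == "lost" and changed

    def test_partial_overlap_with_conserved_suffix_is_internal(self):
        diff = _diff(20, 30, 80, 75)
        (s,), _, _ = dom.classify_impact([_hit(10, 40)], diff)
        assert s.status == "internally_altered"

    def test_alteration_before_first_domain_is_n_terminal(self):
        diff = _diff(2, 70, 80, 76)
        _, changed, region = dom.classify_impact([_hit(20, 40)], diff)
        assert not changed and region == "n_term"

    def test_alteration_between_domains_is_linker(self):
        diff = _diff(30, 40, 80, 76)
        _, _, region = dom.classify_impact([_hit(5, 20), _hit(60, 75)], diff)
        assert region == "linker"

    def test_zero_domain_protein_positional_fallback(self):
        assert dom.classify_impact([], _diff(0, 70, 80, 76))[2] == "n_term"
        assert dom.classify_impact([], _diff(70, 0, 80, 76))[2] == "c_term"
        assert dom.classify_impact([], _diff(30, 40, 80, 76))[2] == "linker"

    def test_unchanged_protein_has_no_affected_region(self):
        _, changed, region = dom.classify_impact([_hit(5, 20)], _diff(80, 0, 80, 80))
        assert not changed and region == "none"

    def test_domain_beyond_protein_length_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            dom.classify_impact([_hit(10, 90)], _diff(20, 10, 80, 70))

    def test_monotone_under_block_growth(self):
        # enlarging the altered block can never turn a changed domain intact
        hit = _hit(20, 40)
        changed_states = []
        for grow in range(0, 36, 5):
            diff = _diff(max(0, 35 - grow), 30, 80, 80 - 15 - grow)
            statuses, changed, _ = dom.classify_impact([hit], diff)
            changed_states.append(changed)
        first_changed = changed_states.index(True)
        assert all(changed_states[first_changed:])

    def test_matches_per_residue_set_oracle_on_random_pairs(self):
        rng = np.random.default_rng(17)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(300):
            la = int(rng.integers(1, 120))
            incl = "".join(rng.choice(alphabet, size=la))
            mode = rng.integers(0, 3)
            if mode == 0:  # deletion
                a, b = sorted(rng.integers(0, la + 1, size=2))
                excl = incl[:a] + incl[b:]
            elif mode == 1:  # divergent tail
                cut = int(rng.integers(0, la + 1))
                excl = incl[:cut] + "".join(
                    rng.choice(alphabet, size=int(rng.integers(0, 30)))
                )
            else:  # unrelated sequence
                excl = "".join(rng.choice(alphabet, size=int(rng.integers(0, 120))))
            p, s = prefix_suffix_scan(incl, excl)
            diff = ResidueDiff(
                prefix_len=p, suffix_len=s, len_incl=len(incl), len_excl=len(excl)
            )
            ds = int(rng.integers(0, la))
            de = int(rng.integers(ds + 1, la + 1))
            (status,), _, _ = dom.classify_impact([_hit(ds, de)], diff)
            assert status.status == domain_status_by_sets(incl, excl, ds, de)
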