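"""Profile construction, local-alignment DP (vs exhaustive oracle), E-values.

The central check is oracle equivalence: the affine-gap local DP must agree
exactly with an independent enumeration of all monotone match pairings on
tiny instances.
"""

import math

import numpy as np
import pytest

from rnrscape.formats_io import GeneFeature, GenomeRecord, SequenceRecord
from rnrscape.profile_engine import (
    AMINO_ACIDS,
    ProfileModel,
    build_profile,
    calibrate,
    consensus_sequence,
    encode_protein,
    evalue,
    fit_gumbel,
    nt_to_protein,
    protein_to_nt,
    read_profiles,
    reverse_complement,
    score_local,
    search_genome,
    write_profiles,
)


def rec(i, seq):
    return SequenceRecord(id=f"r{i}", seq=seq)


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

class TestBuildProfile:
    def test_single_row_scores_observed_residue_positive(self):
        prof = build_profile([rec(1, "ACD")], "nrdA")
        assert prof.L == 3
        for j, aa in enumerate("ACD"):
            assert prof.S[j, AMINO_ACIDS.index(aa)] > 0

    def test_gap_rule_boundary_half_is_retained(self):
        # column 2 has gap fraction exactly 0.5, which is not > 0.5
        prof = build_profile([rec(1, "A-"), rec(2, "AC")], "nrdA")
        assert prof.L == 2

    def test_majority_gap_column_dropped(self):
        prof = build_profile([rec(1, "A-"), rec(2, "A-"), rec(3, "AC")], "nrdA")
        assert prof.L == 1

    def test_hand_computed_scores_match_formula(self):
        # 2 rows x 3 columns, uniform background 1/20, alpha = 1:
        # expected scores computed here directly from the definition.
        rows = ["ACD", "AVD"]
        prof = build_profile([rec(i, s) for i, s in enumerate(rows)], "nrdA")
        b = 0.05
        for j in range(3):
            counts = {aa: sum(1 for r in rows if r[j] == aa) for aa in set(r[j] for r in rows)}
            for a_i, aa in enumerate(AMINO_ACIDS):
                c = counts.get(aa, 0)
                expected = math.log2((c + 1 * b) / (2 + 1) / b)
                assert prof.S[j, a_i] == pytest.approx(expected, abs=1e-9)

    def test_ragged_alignment_error(self):
        with pytest.raises(ValueError, match="ragged"):
            build_profile([rec(1, "ACD"), rec(2, "AC")], "nrdA")

    def test_zero_retained_columns_error(self):
        with pytest.raises(ValueError, match="no match columns"):
            build_profile([rec(1, "--"), rec(2, "A-"), rec(3, "--")], "nrdA")


# ---------------------------------------------------------------------------
# Local alignment vs exhaustive oracle
# ---------------------------------------------------------------------------

from _oracles import oracle_best_local, random_tiny_profile  # noqa: E402


class TestLocalAlignment:
    def test_consensus_scores_column_max_sum_full_span(self, profiles_by_family):
        prof = profiles_by_family["nrdH"]
        hit = score_local(prof, consensus_sequence(prof))
        assert hit.score == pytest.approx(float(prof.S.max(axis=1).sum()), abs=1e-9)
        assert (hit.pf_from, hit.pf_to) == (1, prof.L)
        assert (hit.q_from, hit.q_to) == (0, prof.L)

    def test_nothing_positive_scores_zero_with_empty_span(self):
        S = np.full((4, 20), -1.0)
        prof = ProfileModel(family="nrdA", S=S)
        hit = score_local(prof, "ACDEFG")
        assert hit.score == 0.0 and hit.q_from == hit.q_to

    def test_empty_sequence_error(self, profiles_by_family):
        with pytest.raises(ValueError):
            score_local(profiles_by_family["nrdA"], "")

    def test_dp_equals_exhaustive_oracle_100_instances(self):
        """Seeded sweep: DP == enumeration oracle on L <= 5, |seq| <= 8."""
        rng = np.random.default_rng(1234)
        for _ in range(100):
            L = int(rng.integers(1, 6))
            n = int(rng.integers(1, 9))
            prof = random_tiny_profile(rng, L)
            seq_idx = rng.integers(0, 20, size=n)
            seq = "".join(AMINO_ACIDS[i] for i in seq_idx)
            expected = oracle_best_local(prof.S, seq_idx, prof.gap_open, prof.gap_extend)
            got = score_local(prof, seq).score
            assert got == pytest.approx(expected, abs=1e-9)

    def test_ambiguity_codes_score_as_mismatch(self, profiles_by_family):
        prof = profiles_by_family["nrdH"]
        cons = consensus_sequence(prof)
        with_x = "X" * 5 + cons + "X" * 5
        assert score_local(prof, with_x).score <= score_local(prof, cons).score + 1e-9


# ---------------------------------------------------------------------------
# Calibration and E-values
# ---------------------------------------------------------------------------

class TestCalibration:
    def test_zero_variance_error(self):
        prof = ProfileModel(family="nrdA", S=np.full((3, 20), -1.0))
        with pytest.raises(ValueError, match="zero decoy score variance"):
            calibrate(prof, n_decoys=50, decoy_len=50, seed=0)

    def test_too_few_decoys_error(self, profiles_by_family):
        with pytest.raises(ValueError):
            calibrate(profiles_by_family["nrdA"], n_decoys=10)

    def test_gumbel_parameter_recovery(self):
        rng = np.random.default_rng(77)
        sample = rng.gumbel(loc=10.0, scale=2.0, size=2000)
        mu, beta = fit_gumbel(sample)
        assert mu == pytest.approx(10.0, abs=0.3)
        assert beta == pytest.approx(2.0, abs=0.3)

    def test_determinism_same_seed(self, profiles_by_family):
        prof = ProfileModel(family="nrdH", S=profiles_by_family["nrdH"].S)
        c1 = calibrate(prof, n_decoys=60, decoy_len=100, seed=5)
        c2 = calibrate(prof, n_decoys=60, decoy_len=100, seed=5)
        assert c1.calib == c2.calib

    def test_evalue_at_location(self, profiles_by_family):
        prof = profiles_by_family["nrdA"]
        mu, _ = prof.calib
        assert evalue(prof, mu, 1) == pytest.approx(1 - math.exp(-1), abs=1e-9)

    def test_evalue_limit_and_monotonicity(self, profiles_by_family):
        prof = profiles_by_family["nrdA"]
        assert evalue(prof, 1e6, 1) == pytest.approx(0.0, abs=1e-12)
        mu, beta = prof.calib
        # strictly decreasing wherever the tail probability is representable
        for s in (mu, mu + 2, mu + 10, mu + 50):
            assert evalue(prof, s + beta, 10) < evalue(prof, s, 10)

    def test_missing_calib_error(self):
        prof = ProfileModel(family="nrdA", S=np.zeros((3, 20)))
        with pytest.raises(ValueError, match="not calibrated"):
            evalue(prof, 10.0, 1)


# ---------------------------------------------------------------------------
# Genome search
# ---------------------------------------------------------------------------

def _flip_genome(genome: GenomeRecord) -> GenomeRecord:
    n = len(genome.seq)
    feats = [
        GeneFeature(
            gene_id=f.gene_id, start=n - f.end, end=n - f.start,
            strand="-" if f.strand == "+" else "+",
            product=f.product, translation=f.translation,
        )
        for f in genome.features
    ]
    return GenomeRecord(id=genome.id, seq=reverse_complement(genome.seq), features=feats)


class TestGenomeSearch:
    def test_planted_gene_recovered(self, profiles, ancestors, scenario_config):
        from dataclasses import replace

        from rnrscape.synthetic_data import gen_genome

        cfg = replace(scenario_config, divergence=0.2)
        genome, truth = gen_genome(cfg, ancestors, "J", seed=21, genome_id="g1")
        hits = [h for h in search_genome(profiles, genome) if h.evalue <= 1e-4]
        assert len(hits) == 1 and hits[0].family == "nrdJ"
        planted = truth.calls[0]
        assert hits[0].q_from < planted.end and hits[0].q_to > planted.start

    def test_strand_symmetry(self, profiles, ancestors, scenario_config):
        from rnrscape.synthetic_data import gen_genome

        genome, _ = gen_genome(scenario_config, ancestors, "J", seed=22, genome_id="g2")
        flipped = _flip_genome(genome)
        fwd = [h for h in search_genome(profiles, genome) if h.evalue <= 1e-4]
        rev = [h for h in search_genome(profiles, flipped) if h.evalue <= 1e-4]
        n = len(genome.seq)
        assert {(h.family, h.q_from, h.q_to, h.strand) for h in rev} == {
            (h.family, n - h.q_to, n - h.q_from, "-" if h.strand == "+" else "+") for h in fwd
        }

    def test_six_frame_search_finds_unannotated_gene(self, profiles, ancestors, scenario_config):
        from rnrscape.synthetic_data import gen_genome

        genome, truth = gen_genome(scenario_config, ancestors, "J", seed=23, genome_id="g3")
        bare = GenomeRecord(id="g3", seq=genome.seq, features=[])
        hits = [h for h in search_genome(profiles, bare, use_features=False) if h.evalue <= 1e-4]
        fams = {h.family for h in hits}
        assert "nrdJ" in fams
        planted = truth.calls[0]
        best = min((h for h in hits if h.family == "nrdJ"), key=lambda h: h.evalue)
        assert best.q_from < planted.end and best.q_to > planted.start

    def test_no_features_warns_empty(self, profiles):
        genome = GenomeRecord(id="empty", seq="ACGT" * 100, features=[])
        assert search_genome(profiles, genome, use_features=True) == []

    def test_coordinate_round_trip(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            start = int(rng.integers(0, 1000)) * 3
            length = int(rng.integers(10, 200))
            end = start + 3 * length
            a = int(rng.integers(0, length))
            b = int(rng.integers(a + 1, length + 1))
            for strand in "+-":
                nt = protein_to_nt(a, b, start, end, strand)
                assert nt_to_protein(*nt, start, end, strand) == (a, b)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def test_profile_tsv_round_trip(tmp_path, profiles):
    path = tmp_path / "profiles.tsv"
    write_profiles(profiles, path)
    back = read_profiles(path)
    assert [p.family for p in back] == [p.family for p in profiles]
    for a, b in zip(profiles, back):
        assert a.L == b.L
        assert a.calib == pytest.approx(b.calib)
        np.testing.assert_allclose(a.S, b.S, atol=1e-9)
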