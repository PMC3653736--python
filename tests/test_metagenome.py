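"""Metagenome branch: de-replication, read ORFs, counting, normalization."""

import numpy as np
import pandas as pd
import pytest

from rnrscape.formats_io import SequenceRecord
from rnrscape.metagenome import (
    AbundanceMatrix,
    call_read_orfs,
    count_hits,
    dereplicate,
    exclude_sparse,
    heatmap_matrix,
    normalize,
    read_heatmap_tsv,
)
from rnrscape.profile_engine import reverse_complement
from rnrscape.synthetic_data import _random_protein, _reverse_translate


def reads(*seqs):
    return [SequenceRecord(id=f"r{i}", seq=s) for i, s in enumerate(seqs)]


class TestDereplicate:
    def test_exact_duplicates_removed_first_kept(self):
        m = dereplicate(reads("ACGT", "ACGT", "TTTT"))
        assert [r.seq for r in m.reads] == ["ACGT", "TTTT"]
        assert m.size_nt == 8

    def test_case_insensitive(self):
        m = dereplicate(reads("ACGT", "acgt".upper()))
        assert len(m.reads) == 1

    def test_no_duplicates_identity(self):
        m = dereplicate(reads("ACGT", "TTTT"))
        assert len(m.reads) == 2

    def test_idempotence(self):
        m1 = dereplicate(reads("ACGT", "ACGT", "TTTT", "GG" * 40))
        m2 = dereplicate(m1.reads, metagenome_id=m1.id)
        assert [r.seq for r in m2.reads] == [r.seq for r in m1.reads]

    def test_prefix_duplicates_flag(self):
        m = dereplicate(reads("ACGTACGTAA", "ACGTACGT"), prefix_duplicates=True)
        assert [r.seq for r in m.reads] == ["ACGTACGTAA"]


class TestReadOrfs:
    def test_stop_free_120nt_read_gives_40aa_fragment(self):
        rng = np.random.default_rng(2)
        nt = _reverse_translate(_random_protein(rng, 40), rng)
        frags = call_read_orfs(SequenceRecord(id="r", seq=nt))
        assert any(len(f.seq) == 40 for f in frags)

    def test_stop_dense_read_empty(self):
        from rnrscape.synthetic_data import _STOP_CASSETTE

        # cassette puts a stop in every frame on both strands every ~7 codons
        assert call_read_orfs(SequenceRecord(id="r", seq=_STOP_CASSETTE * 6)) == []

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(4)
        nt = "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))
        fwd = sorted(f.seq for f in call_read_orfs(SequenceRecord(id="a", seq=nt)))
        rev = sorted(
            f.seq for f in call_read_orfs(SequenceRecord(id="b", seq=reverse_complement(nt)))
        )
        assert fwd == rev

    def test_min_length_respected(self):
        rng = np.random.default_rng(6)
        nt = _reverse_translate(_random_protein(rng, 20), rng)
        frags = call_read_orfs(SequenceRecord(id="r", seq=nt), min_aa=30)
        assert all(len(f.seq) >= 30 for f in frags)


class TestCountHits:
    def test_empty_metagenome_all_zero(self, profiles):
        m = dereplicate([], metagenome_id="empty")
        counts = count_hits(m, profiles)
        assert set(counts.values()) == {0}

    def test_planted_gene_counts_concentrate(self, profiles, ancestors, scenario_config):
        from rnrscape.synthetic_data import gen_genome, gen_metagenome

        genome, _ = gen_genome(scenario_config, ancestors, "J", seed=31, genome_id="p1")
        rds, _ = gen_metagenome([genome], [1.0], n_reads=120, err=0.01, seed=32)
        counts = count_hits(dereplicate(rds, "m1"), profiles)
        assert counts["nrdJ"] > 0
        others = {f: n for f, n in counts.items() if f != "nrdJ"}
        assert sum(others.values()) == 0

    def test_total_count_conservation(self, profiles, ancestors, scenario_config):
        """Sum over families == number of ORFs whose best hit passes the cutoff."""
        from rnrscape.metagenome import call_read_orfs as orfs_of
        from rnrscape.profile_engine import _score_local_all, encode_protein, evalue
        from rnrscape.synthetic_data import gen_genome, gen_metagenome

        genome, _ = gen_genome(scenario_config, ancestors, "AB", seed=33, genome_id="p2")
        rds, _ = gen_metagenome([genome], [1.0], n_reads=60, err=0.01, seed=34)
        m = dereplicate(rds, "m2")
        counts = count_hits(m, profiles)
        all_orfs = [o for r in m.reads for o in orfs_of(r)]
        n_comp = len(all_orfs) * len(profiles)
        n_passing = 0
        for orf in all_orfs:
            best = None
            for p in profiles:
                hits = _score_local_all(p, encode_protein(orf.seq), max_hits=1)
                if hits:
                    ev = evalue(p, hits[0][0], n_comp)
                    if best is None or ev < best:
                        best = ev
            if best is not None and best <= 1e-4:
                n_passing += 1
        assert sum(counts.values()) == n_passing


class TestNormalize:
    def _raw(self, **cols):
        fams = ["nrdA", "nrdB", "nrdD", "nrdE", "nrdF", "nrdG", "nrdH", "nrdI", "nrdJ"]
        base = {f: [0] for f in fams}
        base.update({k: [v] for k, v in cols.items()})
        return pd.DataFrame(base, index=["m1"])

    def test_formula_arithmetic(self):
        raw = self._raw(nrdJ=2)
        lengths = {f: 500 for f in raw.columns}
        mat = normalize(raw, pd.Series([1_000_000], index=["m1"]), lengths)
        assert mat.values.loc["m1", "nrdJ"] == pytest.approx(4.0)

    def test_doubling_size_halves_abundance(self):
        raw = self._raw(nrdA=6, nrdJ=3)
        lengths = {f: 300 for f in raw.columns}
        a1 = normalize(raw, pd.Series([1e6], index=["m1"]), lengths).values
        a2 = normalize(raw, pd.Series([2e6], index=["m1"]), lengths).values
        pd.testing.assert_frame_equal(a2 * 2, a1)

    def test_class_aggregates_exact_sums(self):
        raw = self._raw(nrdA=3, nrdB=2, nrdE=1, nrdF=4, nrdH=1, nrdI=2, nrdJ=5, nrdD=1, nrdG=1)
        lengths = {f: 100 + 10 * i for i, f in enumerate(raw.columns)}
        v = normalize(raw, pd.Series([5e5], index=["m1"]), lengths).values
        assert v.loc["m1", "class_Ia"] == v.loc["m1", ["nrdA", "nrdB"]].sum()
        assert v.loc["m1", "class_Ib"] == v.loc["m1", ["nrdE", "nrdF", "nrdH", "nrdI"]].sum()
        assert v.loc["m1", "class_II"] == v.loc["m1", "nrdJ"]
        assert v.loc["m1", "class_III"] == v.loc["m1", ["nrdD", "nrdG"]].sum()

    def test_nonpositive_size_error(self):
        raw = self._raw(nrdA=1)
        with pytest.raises(ValueError):
            normalize(raw, pd.Series([0], index=["m1"]), {f: 100 for f in raw.columns})


class TestSparseExclusion:
    def _matrix(self, totals):
        fams = ["nrdA", "nrdB", "nrdD", "nrdE", "nrdF", "nrdG", "nrdH", "nrdI", "nrdJ"]
        raw = pd.DataFrame(
            {f: [t if f == "nrdA" else 0 for t in totals] for f in fams},
            index=[f"m{i}" for i in range(len(totals))],
        )
        sizes = pd.Series([1e6] * len(totals), index=raw.index)
        return normalize(raw, sizes, {f: 100 for f in fams})

    def test_boundaries(self):
        mat = exclude_sparse(self._matrix([5, 6, 0]))
        assert mat.excluded.tolist() == [True, False, True]

    def test_values_retained_for_excluded_rows(self):
        mat = exclude_sparse(self._matrix([5]))
        assert mat.values.loc["m0", "nrdA"] > 0


class TestHeatmap:
    def test_tsv_round_trip_and_exclusion(self, tmp_path):
        fams = ["nrdA", "nrdB", "nrdD", "nrdE", "nrdF", "nrdG", "nrdH", "nrdI", "nrdJ"]
        raw = pd.DataFrame(
            {f: [7 if f == "nrdA" else 1, 0, 0] if True else None for f in fams},
            index=["keep1", "drop1", "drop2"],
        )
        raw.loc["drop1"] = 0
        raw.loc["drop2"] = [1, 0, 0, 0, 0, 0, 0, 0, 0]
        mat = exclude_sparse(
            normalize(raw, pd.Series([1e6, 1e6, 2e6], index=raw.index), {f: 150 for f in fams})
        )
        out = tmp_path / "heatmap.tsv"
        table = heatmap_matrix(mat, path=out)
        assert list(table.index) == ["keep1"]
        back = read_heatmap_tsv(out)
        pd.testing.assert_frame_equal(back, table, atol=1e-12, check_exact=False)
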