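import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mndkit import (
    MISSING,
    DeltaMnd,
    GlobalAncestry,
    PairRecord,
    PipelineError,
    ValidationError,
    classify,
    compute_delta_table,
    compute_mnd_table,
    gene_wise_mnd,
    global_ancestry,
    global_mnd,
    sample_mnd,
)
from mndkit.ancestry_io import Gene, GeneIndex, build_site_map, read_gene_index
from mndkit.mnd_core import delta_mnd

from conftest import make_matrix

NAT, EUR, AFR = 0, 1, 2


def index_for(matrix, genes, sets=None):
    gene_ids = tuple(g.gene_id for g in genes)
    sets = sets or {"all_mitonuclear": gene_ids, "oxphos": (),
                    "high_mt": (), "low_mt": ()}
    site_map = build_site_map(genes, matrix)
    zero = tuple(g.gene_id for g in genes if site_map[g.gene_id].size == 0)
    return GeneIndex(genes=genes, sets=sets, site_map=site_map,
                     zero_snp_genes=zero)


class TestGeneWiseMnd:
    def test_perfect_concordance(self):
        m = make_matrix(np.full((1, 4, 2), NAT))
        gi = index_for(m, [Gene("G1", "chr1", 0, 1000)])
        assert gene_wise_mnd(m, "S1", "G1", gi, "NAT") == 0.0

    def test_full_discordance(self):
        m = make_matrix(np.full((1, 4, 2), EUR))
        gi = index_for(m, [Gene("G1", "chr1", 0, 1000)])
        assert gene_wise_mnd(m, "S1", "G1", gi, "NAT") == 1.0

    def test_heterozygous_sites_give_half(self):
        m = make_matrix(np.tile([[NAT, EUR]], (1, 4, 1)))
        gi = index_for(m, [Gene("G1", "chr1", 0, 1000)])
        assert gene_wise_mnd(m, "S1", "G1", gi, "NAT") == 0.5

    def test_missing_calls_excluded_from_both_counts(self):
        calls = np.array([[[EUR, MISSING], [NAT, NAT]]])
        m = make_matrix(calls)
        gi = index_for(m, [Gene("G1", "chr1", 0, 1000)])
        assert gene_wise_mnd(m, "S1", "G1", gi, "NAT") == pytest.approx(1 / 3)

    def test_all_missing_returns_none(self):
        m = make_matrix(np.full((1, 2, 2), MISSING))
        gi = index_for(m, [Gene("G1", "chr1", 0, 1000)])
        assert gene_wise_mnd(m, "S1", "G1", gi, "NAT") is None

    def test_per_snp_mode_equals_per_call_for_diploid(self, small_cohort, cohort_dir):
        m = small_cohort.matrix
        gi = read_gene_index(cohort_dir / "genes.bed",
                             cohort_dir / "gene_sets.tsv", m)
        for gid in list(gi.site_map)[:10]:
            a = gene_wise_mnd(m, m.samples[0], gid, gi, "NAT", mode="per_call")
            b = gene_wise_mnd(m, m.samples[0], gid, gi, "NAT", mode="per_snp")
            assert a == pytest.approx(b)

    @given(
        hnp.arrays(np.int16, (1, 30, 2), elements=st.integers(-1, 2)),
        st.sampled_from(["NAT", "EUR", "AFR"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_permutation_invariant(self, calls, mt):
        m = make_matrix(calls)
        gi = index_for(m, [Gene("G1", "chr1", 0, 100000)])
        v = gene_wise_mnd(m, "S1", "G1", gi, mt)
        if v is not None:
            assert 0.0 <= v <= 1.0
        # shuffling call order within the gene leaves the value unchanged
        rng = np.random.default_rng(0)
        shuffled = calls[:, rng.permutation(calls.shape[1]), :]
        m2 = make_matrix(shuffled)
        gi2 = index_for(m2, [Gene("G1", "chr1", 0, 100000)])
        assert gene_wise_mnd(m2, "S1", "G1", gi2, mt) == v


class TestSampleMnd:
    def test_mean_of_two_genes(self):
        calls = np.zeros((1, 10, 2), dtype=np.int16)  # all NAT
        calls[0, 0] = [EUR, EUR]  # G1 (sites 0-4): 2 of 10 calls -> 0.2
        calls[0, 5] = [EUR, EUR]  # G2 (sites 5-9): 4 of 10 calls -> 0.4
        calls[0, 6] = [EUR, EUR]
        m = make_matrix(calls)
        genes = [Gene("G1", "chr1", 0, 500), Gene("G2", "chr1", 500, 2000)]
        gi = index_for(m, genes)
        res = sample_mnd(m, "S1", ("G1", "G2"), gi, "NAT")
        assert res == (pytest.approx(0.3), 2)

    def test_gene_without_calls_dropped_from_mean(self):
        calls = np.full((1, 10, 2), EUR, dtype=np.int16)
        calls[0, 0] = [NAT, NAT]  # G1: 7 EUR of 10 calls -> 0.7
        calls[0, 1] = [NAT, EUR]
        calls[0, 5:] = MISSING  # G2 has zero usable calls
        m = make_matrix(calls)
        genes = [Gene("G1", "chr1", 0, 500), Gene("G2", "chr1", 500, 2000)]
        gi = index_for(m, genes)
        res = sample_mnd(m, "S1", ("G1", "G2"), gi, "NAT")
        assert res == (pytest.approx(0.7), 1)

    def test_no_usable_gene_returns_none(self):
        m = make_matrix(np.full((1, 4, 2), MISSING))
        gi = index_for(m, [Gene("G1", "chr1", 0, 1000)])
        assert sample_mnd(m, "S1", ("G1",), gi, "NAT") is None

    def test_empty_gene_set_rejected(self):
        m = make_matrix(np.zeros((1, 1, 2)))
        gi = index_for(m, [Gene("G1", "chr1", 0, 1000)])
        with pytest.raises(ValidationError, match="empty gene set"):
            sample_mnd(m, "S1", (), gi, "NAT")


class TestVectorizedTable:
    def test_matches_per_gene_loop_oracle(self, small_cohort, cohort_dir):
        m = small_cohort.matrix
        gi = read_gene_index(cohort_dir / "genes.bed",
                             cohort_dir / "gene_sets.tsv", m)
        assignments = classify(small_cohort.haplogroups, panel=m.panel)
        table, _, _ = compute_mnd_table(m, gi, assignments)
        by_sample = {a.sample_id: a for a in assignments}
        for row in table.itertuples():
            expected = sample_mnd(
                m, row.sample_id, gi.sets[row.gene_set], gi,
                by_sample[row.sample_id].mt_ancestry,
            )
            assert row.mean_mnd == pytest.approx(expected[0], abs=1e-12)
            assert row.n_genes_used == expected[1]

    def test_unmapped_samples_excluded(self, small_cohort, cohort_dir):
        m = small_cohort.matrix
        gi = read_gene_index(cohort_dir / "genes.bed",
                             cohort_dir / "gene_sets.tsv", m)
        records = [(sid, "Z9") if sid == m.samples[0] else (sid, hg)
                   for sid, hg in small_cohort.haplogroups]
        assignments = classify(records, panel=m.panel)
        table, _, exclusions = compute_mnd_table(m, gi, assignments)
        assert m.samples[0] not in set(table["sample_id"])
        assert any(sid == m.samples[0] and "unmapped" in reason
                   for sid, reason in exclusions)

    def test_all_values_in_unit_interval(self, small_cohort, cohort_dir):
        m = small_cohort.matrix
        gi = read_gene_index(cohort_dir / "genes.bed",
                             cohort_dir / "gene_sets.tsv", m)
        assignments = classify(small_cohort.haplogroups, panel=m.panel)
        table, detail, _ = compute_mnd_table(
            m, gi, assignments, with_detail=True
        )
        assert table["mean_mnd"].between(0, 1).all()
        assert detail["gene_mnd"].between(0, 1).all()
        assert (table["n_genes_used"]
                <= table["gene_set"].map(lambda s: len(gi.sets[s]))).all()


class TestGlobalAncestry:
    def test_all_one_ancestry(self):
        m = make_matrix(np.full((1, 5, 2), EUR))
        ga = global_ancestry(m, "S1")
        assert ga.proportions == {"NAT": 0.0, "EUR": 1.0, "AFR": 0.0}

    def test_half_and_half(self):
        calls = np.tile([[NAT, EUR]], (1, 6, 1))
        ga = global_ancestry(make_matrix(calls), "S1")
        assert ga.proportions["NAT"] == pytest.approx(0.5)
        assert ga.proportions["EUR"] == pytest.approx(0.5)

    def test_matches_counting_oracle(self, small_cohort):
        m = small_cohort.matrix
        for sid in m.samples[:5]:
            ga = global_ancestry(m, sid)
            calls = m.calls[m.samples.index(sid)]
            usable = calls[calls != MISSING]
            for code, name in enumerate(m.panel.names):
                assert ga.proportions[name] == pytest.approx(
                    (usable == code).sum() / usable.size
                )

    def test_all_missing_errors(self):
        m = make_matrix(np.full((1, 3, 2), MISSING))
        with pytest.raises(PipelineError, match="missing"):
            global_ancestry(m, "S1")

    def test_proportions_sum_to_one(self, small_cohort):
        m = small_cohort.matrix
        for sid in m.samples:
            assert sum(global_ancestry(m, sid).proportions.values()) == pytest.approx(1)


class TestGlobalMnd:
    def test_worked_example(self):
        ga = GlobalAncestry("X", {"EUR": 0.55, "NAT": 0.40, "AFR": 0.05})
        assert global_mnd(ga, "NAT") == pytest.approx(0.60)

    def test_pure_concordant(self):
        ga = GlobalAncestry("X", {"NAT": 1.0, "EUR": 0.0, "AFR": 0.0})
        assert global_mnd(ga, "NAT") == 0.0

    def test_pure_discordant(self):
        ga = GlobalAncestry("X", {"NAT": 0.0, "EUR": 0.0, "AFR": 1.0})
        assert global_mnd(ga, "NAT") == 1.0

    def test_unknown_ancestry_rejected(self):
        ga = GlobalAncestry("X", {"NAT": 1.0})
        with pytest.raises(ValidationError):
            global_mnd(ga, "EAS")

    def test_single_ancestry_individual_sample_equals_global(self):
        # degenerate case: one ancestry everywhere -> gene mean == global MND
        m = make_matrix(np.full((1, 10, 2), EUR))
        genes = [Gene("G1", "chr1", 0, 500), Gene("G2", "chr1", 500, 2000)]
        gi = index_for(m, genes)
        mean, _ = sample_mnd(m, "S1", ("G1", "G2"), gi, "NAT")
        assert mean == global_mnd(global_ancestry(m, "S1"), "NAT") == 1.0


def _mnd_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "gene_set", "mean_mnd", "n_genes_used",
                       "mt_ancestry"]
    )


class TestDeltaMnd:
    @pytest.mark.parametrize(
        "mother,offspring,expected",
        [(0.5, 0.5, 0.0), (0.4, 0.6, 0.5), (0.6, 0.3, -0.5)],
    )
    def test_examples(self, mother, offspring, expected):
        table = _mnd_frame([
            ("M1", "all_mitonuclear", mother, 10, "NAT"),
            ("O1", "all_mitonuclear", offspring, 10, "NAT"),
        ])
        d = delta_mnd(PairRecord("M1", "O1"), table, "all_mitonuclear")
        assert d.delta == pytest.approx(expected)

    @given(st.floats(min_value=1e-6, max_value=1.0))
    def test_identity_is_exactly_zero(self, value):
        assert DeltaMnd(PairRecord("M", "O"), "s", value, value).delta == 0.0

    def test_zero_mother_dropped(self):
        table = _mnd_frame([
            ("M1", "all_mitonuclear", 0.0, 10, "NAT"),
            ("O1", "all_mitonuclear", 0.5, 10, "NAT"),
        ])
        assert delta_mnd(PairRecord("M1", "O1"), table, "all_mitonuclear") is None
        df, exclusions = compute_delta_table(
            [PairRecord("M1", "O1")], table, ["all_mitonuclear"]
        )
        assert df.empty
        assert exclusions[0][2] == "mother MND is 0"

    def test_missing_member_logged(self):
        table = _mnd_frame([("M1", "all_mitonuclear", 0.4, 10, "NAT")])
        df, exclusions = compute_delta_table(
            [PairRecord("M1", "O1")], table, ["all_mitonuclear"]
        )
        assert df.empty and "offspring" in exclusions[0][2]

    def test_table_rows(self):
        table = _mnd_frame([
            ("M1", "oxphos", 0.4, 5, "NAT"),
            ("O1", "oxphos", 0.6, 5, "NAT"),
        ])
        df, exclusions = compute_delta_table(
            [PairRecord("M1", "O1", "c")], table, ["oxphos"]
        )
        assert not exclusions
        assert df.iloc[0]["delta"] == pytest.approx(0.5)
        assert df.iloc[0]["cohort"] == "c"
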