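"""Clonotype tables, diversity indices, and their ordering invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repdiv.annotate import AnnotatedSequence
from repdiv.diversity import (
    build_clonotypes,
    cdr3_length_summary,
    count_large_clones,
    count_vj100,
    gene_usage,
    inverse_simpson,
    shannon_index,
    subsample_molecules,
    summarize_sample,
)
from repdiv.simulate import SimulationConfig, simulate_repertoire


def _ann(seq="ACGT", v="V1", j="J1", cdr3_aa="ARDY", v_id=1.0, j_id=1.0, dup=1):
    return AnnotatedSequence(
        sequence_id=seq,
        seq_nt=seq,
        v_call=v,
        j_call=j,
        v_identity=v_id,
        j_identity=j_id,
        n_v_mutations=0 if v_id == 1.0 else 1,
        cdr3_nt="",
        cdr3_aa=cdr3_aa,
        productive=True,
        duplicate_count=dup,
    )


class TestClonotypes:
    def test_cdr3_definition_groups_by_amino_acid(self):
        seqs = [
            _ann(seq="A1", cdr3_aa="ARDY"),
            _ann(seq="A2", cdr3_aa="ARDY", dup=2),
            _ann(seq="A3", cdr3_aa="ARDF", dup=2),
        ]
        table = build_clonotypes(seqs, "CDR3")
        assert table.richness == 2
        assert sorted(table.counts.values()) == [2, 3]

    def test_vj_context_splits_shared_cdr3(self):
        seqs = [
            _ann(seq="A1", v="V1", cdr3_aa="ARDY", dup=2),
            _ann(seq="A2", v="V2", cdr3_aa="ARDY"),
        ]
        assert build_clonotypes(seqs, "CDR3").richness == 1
        table = build_clonotypes(seqs, "CDR3VJ")
        assert table.richness == 2
        assert sorted(table.counts.values()) == [1, 2]

    def test_empty_input_gives_empty_table(self):
        table = build_clonotypes([], "CDR3")
        assert table.richness == 0
        assert table.total_molecules == 0

    def test_partition_refinement_on_simulated_samples(self, germline):
        """n_cdr3 <= n_cdr3vj <= distinct nt sequences, on every sample."""
        for seed in range(20):
            config = SimulationConfig(
                n_naive_clones=15, n_molecules=60, shm_rate=0.01, seed=seed
            )
            rep = simulate_repertoire(germline, config)
            seqs = [
                _ann(seq=m.seq_nt, v=m.v_name, j=m.j_name, cdr3_aa=m.cdr3_nt)
                for m in rep.molecules
            ]
            n_cdr3 = build_clonotypes(seqs, "CDR3").richness
            n_cdr3vj = build_clonotypes(seqs, "CDR3VJ").richness
            n_nt = build_clonotypes(seqs, "NT").richness
            assert n_cdr3 <= n_cdr3vj <= n_nt


class TestLargeClones:
    def test_strict_boundary_hand_enumeration(self):
        # 1000 molecules: 10 (1.0%) and 6 (0.6%) exceed 0.5%; 5 (exactly
        # 0.5%) does not; the 979 singletons do not.
        seqs = (
            [_ann(seq="C1", dup=10), _ann(seq="C2", dup=6), _ann(seq="C3", dup=5)]
            + [_ann(seq=f"S{i}") for i in range(979)]
        )
        table = build_clonotypes(seqs, "NT")
        assert table.total_molecules == 1000
        assert count_large_clones(table) == 2

    def test_all_singletons_at_shallow_depth_all_large(self):
        # 150 singletons: each is 0.67% > 0.5% — the statistic is
        # depth-dependent by design.
        table = build_clonotypes([_ann(seq=f"S{i}") for i in range(150)], "NT")
        assert count_large_clones(table) == 150

    def test_single_clone_holding_everything(self):
        table = build_clonotypes([_ann(seq="C", dup=500)], "NT")
        assert count_large_clones(table) == 1

    def test_invariant_under_clone_permutation(self):
        seqs = [_ann(seq=f"C{i}", dup=d) for i, d in enumerate([10, 6, 5, 400])]
        a = count_large_clones(build_clonotypes(seqs, "NT"))
        b = count_large_clones(build_clonotypes(list(reversed(seqs)), "NT"))
        assert a == b

    def test_threshold_validated(self):
        table = build_clonotypes([_ann()], "NT")
        with pytest.raises(ValueError):
            count_large_clones(table, threshold=0.0)
        with pytest.raises(ValueError):
            count_large_clones(table, threshold=1.0)
        with pytest.raises(ValueError):
            count_large_clones(build_clonotypes([_ann()], "CDR3"))


class TestVj100:
    def test_mutated_sequences_excluded(self):
        seqs = [
            _ann(seq="A1", v_id=1.0, j_id=1.0),
            _ann(seq="A2", v_id=0.99, j_id=1.0),  # one V mismatch
            _ann(seq="A3", v_id=1.0, j_id=0.98),
        ]
        assert count_vj100(seqs) == 1

    def test_counts_distinct_nucleotide_sequences(self):
        seqs = [
            _ann(seq="A1", v_id=1.0, j_id=1.0, dup=5),
            _ann(seq="A2", v_id=1.0, j_id=1.0),
        ]
        assert count_vj100(seqs) == 2

    def test_no_shm_every_distinct_sequence_is_vj100(self, germline, clean_repertoire):
        from repdiv.annotate import annotate_all

        records = [(f"m{m.molecule_id}", m.seq_nt) for m in clean_repertoire.molecules]
        annots, _ = annotate_all(records, germline)
        assert count_vj100(annots) == len({m.seq_nt for m in clean_repertoire.molecules})


class TestIndices:
    def test_uniform_closed_forms(self):
        assert shannon_index([0.25] * 4) == pytest.approx(math.log(4), abs=1e-12)
        assert inverse_simpson([0.2] * 5) == pytest.approx(5.0, abs=1e-12)

    def test_single_category_degenerate(self):
        assert shannon_index([1.0]) == 0.0
        assert inverse_simpson([1.0]) == pytest.approx(1.0)

    def test_fixed_point_evaluations(self):
        # -0.5 ln 0.5 - 2 * 0.25 ln 0.25 = 1.5 ln 2
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.0397207708399179)
        assert inverse_simpson([0.6, 0.4]) == pytest.approx(1 / 0.52)

    def test_zero_entries_contribute_nothing(self):
        assert shannon_index([0.5, 0.5, 0.0]) == pytest.approx(math.log(2))

    def test_invalid_vectors_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0.7, -0.1, 0.4])
        with pytest.raises(ValueError):
            inverse_simpson([0.5, 0.4])  # sums to 0.9
        with pytest.raises(ValueError):
            shannon_index([])

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30)
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_hill_number_ordering(self, weights):
        """inv_simpson <= exp(shannon) <= richness, equality iff uniform."""
        p = np.asarray(weights) / np.sum(weights)
        d2 = inverse_simpson(p)
        d1 = math.exp(shannon_index(p))
        d0 = len(p)
        assert d2 <= d1 * (1 + 1e-9)
        assert d1 <= d0 * (1 + 1e-9)

    def test_hill_equality_iff_uniform(self):
        p = [0.25] * 4
        assert inverse_simpson(p) == pytest.approx(math.exp(shannon_index(p))) == pytest.approx(4.0)
        q = [0.7, 0.1, 0.1, 0.1]
        assert inverse_simpson(q) < math.exp(shannon_index(q)) < 4.0


class TestCdr3LengthSummary:
    def test_degenerate_all_equal_not_applicable(self):
        seqs = [_ann(seq=f"A{i}", cdr3_aa="ARDY") for i in range(10)]
        summary = cdr3_length_summary(seqs)
        assert not summary.applicable
        assert summary.pvalue is None

    def test_histogram_conserves_molecules(self):
        seqs = [
            _ann(seq="A1", cdr3_aa="ARDY", dup=3),
            _ann(seq="A2", cdr3_aa="ARDYF", dup=2),
        ]
        summary = cdr3_length_summary(seqs)
        assert summary.total == 5
        assert summary.histogram == {4: 3, 5: 2}

    def test_normalish_lengths_pass_dagostino(self):
        """Normal-shaped integer length samples are not rejected (the
        D'Agostino variant; Shapiro-Wilk is oversensitive to the integer
        discreteness of length data at depth — see the small-n test)."""
        rng = np.random.default_rng(1)
        passed = 0
        for _ in range(20):
            lengths = np.clip(np.rint(rng.normal(12, 2, size=500)), 5, 25).astype(int)
            seqs = [_ann(seq=f"A{i}", cdr3_aa="A" * l) for i, l in enumerate(lengths)]
            summary = cdr3_length_summary(seqs, test="normaltest")
            assert summary.applicable
            passed += summary.pvalue > 0.01
        assert passed >= 18

    def test_shapiro_reasonable_at_small_depth(self):
        rng = np.random.default_rng(2)
        lengths = np.clip(np.rint(rng.normal(12, 2, size=60)), 5, 25).astype(int)
        seqs = [_ann(seq=f"A{i}", cdr3_aa="A" * l) for i, l in enumerate(lengths)]
        summary = cdr3_length_summary(seqs)
        assert summary.applicable
        assert summary.test_name == "shapiro"
        assert 0.0 <= summary.pvalue <= 1.0


class TestGeneUsage:
    def test_single_gene_fraction_one(self):
        v, j = gene_usage([_ann(v="V1"), _ann(v="V1", seq="B")])
        assert v["V1"] == 1.0
        assert j.sum() == pytest.approx(1.0)

    def test_multinomial_fractions_recovered(self, germline):
        config = SimulationConfig(n_naive_clones=400, n_molecules=1000, shm_rate=0.0, seed=17)
        rep = simulate_repertoire(germline, config)
        seqs = [
            _ann(seq=f"m{m.molecule_id}", v=m.v_name, j=m.j_name)
            for m in rep.molecules
        ]
        v_frac, j_frac = gene_usage(seqs)
        assert v_frac.sum() == pytest.approx(1.0)
        assert j_frac.sum() == pytest.approx(1.0)
        n_v = sum(1 for s in germline if s.kind == "V")
        for frac in v_frac:
            se = math.sqrt((1 / n_v) * (1 - 1 / n_v) / 400)
            assert abs(frac - 1 / n_v) <= 4 * se


def test_subsampling_never_increases_richness(germline, mutated_repertoire):
    seqs = [
        _ann(seq=m.seq_nt, v=m.v_name, j=m.j_name, cdr3_aa=m.cdr3_nt)
        for m in mutated_repertoire.molecules
    ]
    table = build_clonotypes(seqs, "NT")
    rng = np.random.default_rng(3)
    smaller = subsample_molecules(table, 100, rng)
    even_smaller = subsample_molecules(smaller, 40, rng)
    assert even_smaller.richness <= smaller.richness <= table.richness


def test_summarize_sample_consistency(germline, mutated_repertoire):
    from repdiv.annotate import annotate_all

    records = [(f"m{m.molecule_id}", m.seq_nt) for m in mutated_repertoire.molecules]
    annots, _ = annotate_all(records, germline)
    report = summarize_sample(annots, sample_id="s1")
    assert report.n_cdr3 <= report.n_cdr3vj <= report.n_distinct_nt
    assert 1.0 <= report.inv_simpson <= report.n_distinct_nt + 1e-9
    assert 0.0 <= report.shannon <= math.log(report.n_distinct_nt) + 1e-9
    assert report.inv_simpson <= math.exp(report.shannon) + 1e-9
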