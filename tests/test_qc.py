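"""Genotype QC: filters, corrections, LD and imputation on toy tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dfemix as dx
from dfemix.qc import (
    GenotypeTable,
    correct_single_primer,
    drop_invariant_mutations,
    drop_marker_linked_mutations,
    filter_lines,
    impute,
    ld_r_squared,
    run_qc,
    set_het_missing,
)


def make_table(calls: dict, markers=(), chrom=None, pos=None, lines=None):
    """Toy GenotypeTable from a {site: list-of-calls} dict."""
    df = pd.DataFrame(calls, index=[f"L{i}" for i in range(len(next(iter(calls.values()))))])
    ids = list(calls)
    sites = pd.DataFrame(
        {
            "chrom": chrom or ["chr1"] * len(ids),
            "pos": pos or list(range(1, len(ids) + 1)),
            "is_marker": [s in markers for s in ids],
        },
        index=ids,
    )
    line_df = None
    if lines is not None:
        line_df = pd.DataFrame(lines, index=df.index)
    return GenotypeTable(df, sites, line_df)


class TestInvariantDrop:
    def test_all_derived_column_removed(self):
        t = make_table({"m1": list("DDDDD"), "m2": list("ADADA")})
        out, removed = drop_invariant_mutations(t)
        assert removed == ["m1"] and out.mutation_ids == ["m2"]

    def test_single_discordant_call_retains(self):
        t = make_table({"m1": list("ADDDD")})
        out, removed = drop_invariant_mutations(t)
        assert removed == []

    def test_toy_five_by_four(self):
        t = make_table(
            {
                "m1": list("ADADA"),
                "m2": list("DDDDD"),  # invariant
                "m3": list("AADDD"),
                "m4": list("DADAD"),
            }
        )
        out, removed = drop_invariant_mutations(t)
        assert len(out.mutation_ids) == 3 and removed == ["m2"]

    def test_missing_calls_ignored_in_invariance(self):
        t = make_table({"m1": list("DDNND")})
        _, removed = drop_invariant_mutations(t)
        assert removed == ["m1"]


class TestMarkerLinkage:
    def test_identical_to_mating_type_marker_removed(self):
        t = make_table(
            {"m1": list("ADADAD"), "mt": list("ADADAD")}, markers=("mt",)
        )
        _, removed = drop_marker_linked_mutations(t)
        assert removed == ["m1"]

    def test_anti_concordant_pair_removed(self):
        t = make_table(
            {"m1": list("ADADAD"), "mk": list("DADADA")}, markers=("mk",)
        )
        _, removed = drop_marker_linked_mutations(t)
        assert removed == ["m1"]

    def test_one_discordant_line_retained(self):
        t = make_table(
            {"m1": list("ADADAA"), "mt": list("ADADAD")}, markers=("mt",)
        )
        _, removed = drop_marker_linked_mutations(t)
        assert removed == []

    def test_no_complete_cases_retained(self):
        t = make_table(
            {"m1": list("ADNN"), "mk": list("NNAD")}, markers=("mk",)
        )
        _, removed = drop_marker_linked_mutations(t)
        assert removed == []


class TestSinglePrimer:
    def test_missing_set_to_nonamplified_allele(self):
        t = make_table({"m1": list("DNDNN"), "m2": list("ANAAA")})
        out, n = correct_single_primer(t, {"m1": "A"})
        assert n == 3
        assert list(out.calls["m1"]) == list("DADAA")
        assert list(out.calls["m2"]) == list("ANAAA")  # unlisted unchanged

    def test_empty_list_is_noop(self):
        t = make_table({"m1": list("DND")})
        out, n = correct_single_primer(t, {})
        assert n == 0 and (out.calls == t.calls).all().all()

    def test_absent_mutation_raises(self):
        t = make_table({"m1": list("DND")})
        with pytest.raises(KeyError):
            correct_single_primer(t, {"nope": "A"})


class TestLineFilter:
    def test_strict_boundaries(self):
        """A line at exactly 10% missing and 5% het is retained; lines just
        above either threshold are removed."""
        calls = {}
        # 20 mutation sites; L0: 2 missing (10%) + 1 het (5%) -> retained
        # L1: 3 missing (15%) -> removed; L2: 2 het (10%) -> removed
        for j in range(20):
            col = ["D", "D", "D", "D"]
            if j < 2:
                col[0] = "N"
            if j == 2:
                col[0] = "H"
            if j < 3:
                col[1] = "N"
            if j < 2:
                col[2] = "H"
            col[3] = "A" if j % 2 else "D"
            calls[f"m{j}"] = col
        t = make_table(calls)
        out, rep = filter_lines(t)
        assert list(out.calls.index) == ["L0", "L3"]
        assert rep["removed_missing"] == 1 and rep["removed_het"] == 1

    def test_fully_called_line_retained(self):
        t = make_table({"m1": list("AD"), "m2": list("DA")})
        out, rep = filter_lines(t)
        assert len(out.calls) == 2


class TestLdRSquared:
    def test_identical_columns(self):
        a = np.array([0, 1, 0, 1, 1], dtype=float)
        assert ld_r_squared(a, a) == pytest.approx(1.0)

    def test_independent_balanced_haplotypes(self):
        a = np.array([0, 0, 1, 1], dtype=float)
        b = np.array([0, 1, 0, 1], dtype=float)
        assert ld_r_squared(a, b) == pytest.approx(0.0)

    def test_two_by_two_counts_formula(self):
        """Counts (AB=40, Ab=10, aB=10, ab=40) give r^2 = 0.36."""
        a = np.concatenate([np.ones(50), np.zeros(50)])
        b = np.concatenate([np.ones(40), np.zeros(10), np.ones(10), np.zeros(40)])
        assert ld_r_squared(a, b) == pytest.approx(0.36)

    def test_monomorphic_is_nan(self):
        assert np.isnan(ld_r_squared(np.ones(5), np.array([0, 1, 0, 1, 1.0])))

    @given(seed=st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_label_swap_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, 30).astype(float)
        b = rng.integers(0, 2, 30).astype(float)
        r = ld_r_squared(a, b)
        if np.isnan(r):
            return
        assert r == pytest.approx(ld_r_squared(b, a))
        assert r == pytest.approx(ld_r_squared(1 - a, b))


class TestImpute:
    def test_no_missing_unchanged(self):
        t = make_table({"m1": list("ADAD"), "m2": list("DADA")})
        out, rep = impute(t)
        assert rep == {"imputed_mating_reaction": 0, "imputed_ld": 0}
        assert (out.calls == t.calls).all().all()

    def test_mating_reaction_fill(self):
        """A missing call is copied from an identical-haplotype line of the
        same mating reaction."""
        t = make_table(
            {"m1": list("AAD"), "m2": list("DND"), "m3": list("AAD")},
            lines={"mating_reaction": ["r1", "r1", "r2"]},
        )
        out, rep = impute(t)
        assert rep["imputed_mating_reaction"] == 1
        assert out.calls.at["L1", "m2"] == "D"

    def test_perfect_ld_neighbor_positive_phase(self):
        """r^2 = 1 with positive D copies the neighbour's call."""
        t = make_table({"m1": list("ADADN"), "m2": list("ADADA")})
        out, rep = impute(t)
        assert rep["imputed_ld"] == 1
        assert out.calls.at["L4", "m1"] == "A"

    def test_perfect_ld_neighbor_negative_phase(self):
        """r^2 = 1 with negative D copies the flipped call."""
        t = make_table({"m1": list("ADADN"), "m2": list("DADAD")})
        out, rep = impute(t)
        assert out.calls.at["L4", "m1"] == "A"

    def test_r2_exactly_at_threshold_not_used(self):
        """Imputation requires r^2 strictly above the threshold."""
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0, 1, 0], dtype=float)
        b = np.array([1, 1, 1, 0, 0, 0, 0, 1, 1, 0], dtype=float)
        r2 = ld_r_squared(a, b)
        calls = {
            "m1": ["D" if x else "A" for x in a] + ["N"],
            "m2": ["D" if x else "A" for x in b] + ["D"],
        }
        t = make_table(calls)
        out, rep = impute(t, r2_threshold=r2)  # equal, not above
        assert rep["imputed_ld"] == 0
        out2, rep2 = impute(t, r2_threshold=r2 - 1e-9)
        assert rep2["imputed_ld"] == 1

    def test_never_imputes_across_chromosomes(self):
        t = make_table(
            {"m1": list("ADADN"), "m2": list("ADADA")},
            chrom=["chr1", "chr2"],
        )
        _, rep = impute(t)
        assert rep["imputed_ld"] == 0

    def test_imputation_never_alters_called_genotypes(self):
        t = make_table(
            {"m1": list("ADADN"), "m2": list("ADADA")},
            lines={"mating_reaction": ["r"] * 5},
        )
        out, _ = impute(t)
        called = t.calls != "N"
        assert ((out.calls == t.calls) | ~called).all().all()


class TestHaplotypes:
    def test_all_identical_is_one_haplotype(self):
        t = make_table({"m1": list("DDD"), "m2": list("AAA")})
        s = dx.haplotype_summary(t)
        assert s["n_haplotypes"] == 1

    def test_two_identical_of_three(self):
        t = make_table({"m1": list("DDA"), "m2": list("AAD")})
        s = dx.haplotype_summary(t)
        assert s["n_haplotypes"] == 2
        assert sorted(s["multiplicity"].tolist(), reverse=True) == [2, 1]

    def test_mean_derived_proportion(self):
        t = make_table({"m1": list("DA"), "m2": list("DA"), "m3": list("DD"), "m4": list("AA")})
        s = dx.haplotype_summary(t)
        # haplotypes DDDA (3/4 derived) and AADA (1/4 derived)
        assert s["mean_derived_proportion"] == pytest.approx(0.5)


class TestPipeline:
    def test_report_reconciles(self):
        t = make_table(
            {
                "m1": list("DDDDDD"),            # invariant -> dropped
                "m2": list("ADADAA"),
                "m3": list("ADADAD"),            # linked to marker -> dropped
                "m4": list("ANDDAD"),            # L1 33% missing -> line dropped
                "m5": list("ADHDAA"),            # L2 33% het -> line dropped
                "mt": list("ADADAD"),
            },
            markers=("mt",),
            lines={"mating_reaction": ["r1"] * 3 + ["r2"] * 3},
        )
        out, rep = run_qc(t)
        assert rep.mutations_in == 5
        assert rep.mutations_invariant == 1
        assert rep.mutations_marker_linked == 1
        assert rep.lines_in == 6
        assert rep.lines_removed_missing == 1 and rep.lines_removed_het == 1
        assert rep.cells_missing_final <= rep.cells_missing_initial
        assert (
            rep.cells_missing_initial
            - rep.imputed_mating_reaction
            - rep.imputed_ld
            == rep.cells_missing_final
        )

    def test_het_recoded_missing(self):
        t = make_table({"m1": list("ADH")})
        out, n = set_het_missing(t)
        assert n == 1 and out.calls.at["L2", "m1"] == "N"
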