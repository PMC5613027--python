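import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methylseed import (
    Compartment,
    GeneModel,
    composition_of_methylcytosines,
    compartment_summary,
    conversion_rate,
    genome_window_scan,
    replicate_concordance,
    stage_cv,
    stage_difference_test,
    weighted_level,
    window_starts,
)
from methylseed.simulate import simulate_uniform_sites

from conftest import make_records


class TestWeightedLevel:
    def test_hand_summed_counts(self):
        rec = make_records(
            [("Chr1", 10, "+", 3, 1, "CG"), ("Chr1", 20, "-", 0, 4, "CG")]
        )
        level = weighted_level(rec, "CG")
        assert level.percent == pytest.approx(3 / 8 * 100)
        assert (level.meth_calls, level.total_calls) == (3, 8)

    def test_all_unmethylated_is_zero_percent(self):
        rec = make_records([("Chr1", 10, "+", 0, 5, "CHH")])
        assert weighted_level(rec, "CHH").percent == 0.0

    def test_no_calls_is_undefined_not_zero(self):
        rec = make_records([("Chr1", 10, "+", 3, 1, "CHG")])
        level = weighted_level(rec, "CG")
        assert not level.defined
        assert level.percent is None

    def test_region_restriction(self):
        rec = make_records(
            [("Chr1", 10, "+", 4, 0, "CG"), ("Chr1", 50, "+", 0, 4, "CG")]
        )
        assert weighted_level(rec, "CG", ("Chr1", 0, 20)).percent == 100.0
        assert weighted_level(rec, "CG", ("Chr1", 20, 60)).percent == 0.0

    @given(
        st.lists(
            st.tuples(st.integers(0, 20), st.integers(0, 20)), min_size=1, max_size=20
        ),
        st.integers(1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_pooling_equals_count_weighted_combination(self, counts, split):
        """The level of a union of record sets is the count-weighted pool."""
        rows = [
            ("Chr1", 10 * i, "+", m, u, "CG") for i, (m, u) in enumerate(counts)
        ]
        whole = weighted_level(make_records(rows), "CG")
        cut = min(split, len(rows))
        a = weighted_level(make_records(rows[:cut]) if cut else make_records([]), "CG")
        b = weighted_level(make_records(rows[cut:]) if cut < len(rows) else make_records([]), "CG")
        pooled = (a.meth_calls + b.meth_calls, a.total_calls + b.total_calls)
        assert pooled == (whole.meth_calls, whole.total_calls)
        if whole.defined:
            assert 0.0 <= whole.percent <= 100.0

    def test_invariant_to_record_order(self, rng):
        rows = [
            ("Chr1", int(p), "+", int(m), int(u), "CHH")
            for p, m, u in zip(
                rng.choice(1000, 50, replace=False),
                rng.integers(0, 5, 50),
                rng.integers(0, 5, 50),
            )
        ]
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        assert (
            weighted_level(make_records(rows), "CHH").percent
            == weighted_level(make_records(shuffled), "CHH").percent
        )


class TestComposition:
    def test_direct_normalisation(self):
        rec = make_records(
            [
                ("Chr1", 1, "+", 32, 0, "CG"),
                ("Chr1", 2, "+", 27, 5, "CHG"),
                ("Chr1", 3, "+", 41, 9, "CHH"),
            ]
        )
        frac = composition_of_methylcytosines(rec)
        assert frac == pytest.approx({"CG": 0.32, "CHG": 0.27, "CHH": 0.41})
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_context(self):
        rec = make_records([("Chr1", 1, "+", 5, 0, "CG")])
        assert composition_of_methylcytosines(rec) == {"CG": 1.0, "CHG": 0.0, "CHH": 0.0}

    def test_no_methylated_calls_errors(self):
        rec = make_records([("Chr1", 1, "+", 0, 5, "CG")])
        with pytest.raises(ValueError, match="no methylated"):
            composition_of_methylcytosines(rec)


class TestWindowScan:
    def test_two_megabase_chromosome_has_eleven_windows(self):
        assert window_starts(2_000_000, 1_000_000, 100_000) == list(
            range(0, 1_000_001, 100_000)
        )

    def test_short_chromosome_single_truncated_window(self):
        rec = make_records([("Chr1", 10, "+", 1, 1, "CG")])
        scan = genome_window_scan(rec, {"Chr1": 500_000})
        cg = scan[scan.context == "CG"]
        assert len(cg) == 1
        assert (cg.iloc[0].start, cg.iloc[0].end) == (0, 500_000)

    def test_terminal_truncated_window_reaches_chromosome_end(self):
        starts = window_starts(2_050_000, 1_000_000, 100_000)
        assert starts[-1] == 1_100_000  # truncated window covering the tail

    @pytest.mark.parametrize("window,step", [(1000, 0), (100, 500)])
    def test_bad_parameters(self, window, step):
        rec = make_records([("Chr1", 10, "+", 1, 1, "CG")])
        with pytest.raises(ValueError):
            genome_window_scan(rec, {"Chr1": 10_000}, window, step)

    def test_uniform_simulation_recovers_flat_profile(self):
        rec = simulate_uniform_sites(
            0.10, 40_000, "CHH", coverage=10, conversion_rate=1.0, seed=5,
            chrom="Chr1",
        )
        rec["pos"] = (rec["pos"] * 25) % 2_000_000  # spread over the chromosome
        rec = rec.sort_values("pos").reset_index(drop=True)
        scan = genome_window_scan(rec, {"Chr1": 2_000_000})
        chh = scan[scan.context == "CHH"]
        # each 1-Mb window holds ~20k sites (200k calls): binomial SE ~0.07pt
        assert np.all(np.abs(chh.percent - 10.0) < 0.5)


class TestConversionRate:
    def test_arithmetic(self):
        rec = make_records([("lambda", 1, "+", 5, 995, "CHH")])
        assert conversion_rate(rec) == pytest.approx(99.5)

    def test_fully_converted(self):
        rec = make_records([("lambda", 1, "+", 0, 10, "CG")])
        assert conversion_rate(rec) == 100.0

    def test_no_calls_errors(self):
        rec = make_records([("lambda", 1, "+", 0, 0, "CG")])
        with pytest.raises(ValueError, match="no calls"):
            conversion_rate(rec)


class TestStageCv:
    def test_hand_value(self):
        # sample SD sqrt(7) over mean 9
        assert stage_cv([6, 10, 11]) == pytest.approx(100 * np.sqrt(7) / 9, abs=1e-9)

    def test_constant_levels(self):
        assert stage_cv([5, 5, 5]) == 0.0

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError, match="zero mean"):
            stage_cv([0, 0, 0])


class TestReplicateConcordance:
    def test_identical_vectors(self):
        assert replicate_concordance([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = np.array([10.0, 40.0, 90.0])
        assert replicate_concordance(a, 100 - a) == pytest.approx(1.0)

    def test_matches_brute_force_pcc(self, rng):
        a = rng.uniform(0, 100, 200)
        b = 0.8 * a + rng.normal(0, 5, 200)
        # independent textbook formula
        r = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert replicate_concordance(a, b) == pytest.approx(r * r, abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            replicate_concordance([1, 2], [1, 2])

    def test_zero_variance_flagged(self):
        assert np.isnan(replicate_concordance([5, 5, 5, 5], [1, 2, 3, 4]))


class TestCompartmentSummary:
    def test_no_genes_zero_density(self):
        rec = make_records([("Chr1", 10, "+", 1, 1, "CG")])
        comps = [Compartment("Chr1", 0, 1_000_000, "pericentromeric")]
        table = compartment_summary(rec, comps, genes=[])
        assert table.loc["pericentromeric", "genes_per_mb"] == 0.0

    def test_single_compartment_equals_genome_summary(self):
        rec = make_records(
            [("Chr1", 10, "+", 3, 1, "CG"), ("Chr1", 500, "-", 1, 3, "CG")]
        )
        comps = [Compartment("Chr1", 0, 1000, "non_pericentromeric")]
        table = compartment_summary(rec, comps, genes=[])
        assert table.loc["non_pericentromeric", "CG_percent"] == pytest.approx(
            weighted_level(rec, "CG").percent
        )

    def test_overlapping_compartments_rejected(self):
        rec = make_records([("Chr1", 10, "+", 1, 1, "CG")])
        comps = [
            Compartment("Chr1", 0, 1000, "pericentromeric"),
            Compartment("Chr1", 500, 2000, "non_pericentromeric"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            compartment_summary(rec, comps, genes=[])

    def test_gene_assigned_by_tss(self):
        rec = make_records([("Chr1", 10, "+", 1, 1, "CG")])
        comps = [
            Compartment("Chr1", 0, 1000, "non_pericentromeric"),
            Compartment("Chr1", 1000, 2000, "pericentromeric"),
        ]
        # body straddles the boundary; TSS (minus strand -> right end) decides
        gene = GeneModel("G1", "Chr1", "-", 800, 1500)
        table = compartment_summary(rec, comps, genes=[gene])
        assert table.loc["pericentromeric", "genes_per_mb"] > 0
        assert table.loc["non_pericentromeric", "genes_per_mb"] == 0


class TestStageDifference:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert stage_difference_test(a, a) > 0.99

    def test_separated_samples(self):
        assert stage_difference_test(range(1, 21), range(31, 51)) < 0.001

    def test_tiny_samples_error(self):
        with pytest.raises(ValueError):
            stage_difference_test([1.0], [2.0])

    def test_all_tied(self):
        assert stage_difference_test([5, 5, 5], [5, 5, 5]) == pytest.approx(1.0)
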