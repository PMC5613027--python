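import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methylseed import (
    GeneModel,
    call_dmrs,
    dmr_expression_enrichment,
    leaf_fallback_dmrs,
    map_dmr_genes,
    promoter_window_table,
    promoter_windows,
    window_levels,
)
from methylseed.core import CytosineIndex

from conftest import make_records


class TestPromoterWindows:
    def test_plus_strand_enumeration(self):
        gene = GeneModel("G1", "Chr1", "+", 5000, 6000)
        wins = promoter_windows(gene, 100_000)
        assert len(wins) == 40
        assert wins[0] == (0, 4900, 5000)  # TSS-proximal
        assert wins[-1] == (39, 1000, 1100)
        starts = sorted(s for _, s, _ in wins)
        assert starts == list(range(1000, 5000, 100))

    def test_minus_strand_enumeration(self):
        gene = GeneModel("G1", "Chr1", "-", 4000, 5000)
        wins = promoter_windows(gene, 100_000)
        assert wins[0] == (0, 5000, 5100)
        assert wins[-1] == (39, 8900, 9000)

    def test_truncation_at_chromosome_start(self):
        gene = GeneModel("G1", "Chr1", "+", 150, 1000)
        wins = promoter_windows(gene, 100_000)
        assert len(wins) == 2
        assert wins[0] == (0, 50, 150)  # full window
        assert wins[1] == (1, 0, 50)  # truncated to 50 bp

    def test_tss_at_chromosome_start_yields_no_windows(self):
        gene = GeneModel("G1", "Chr1", "+", 0, 1000)
        assert promoter_windows(gene, 100_000) == []

    def test_windows_are_adjacent_and_non_overlapping(self):
        gene = GeneModel("G1", "Chr1", "-", 1000, 2000)
        wins = promoter_windows(gene, 100_000)
        for (_, s1, e1), (_, s2, e2) in zip(wins, wins[1:]):
            assert s2 == e1  # adjacent tiles walking outward


class TestWindowLevels:
    def _windows(self):
        return pd.DataFrame(
            {
                "gene_id": ["G1"],
                "chrom": ["Chr1"],
                "start": [100],
                "end": [200],
                "window_index": [0],
            }
        )

    def test_replicates_average_percents(self):
        rep1 = make_records([("Chr1", 150, "+", 2, 8, "CHH")])  # 20%
        rep2 = make_records([("Chr1", 150, "+", 4, 6, "CHH")])  # 40%
        levels = window_levels([rep1, rep2], self._windows(), "CHH")
        assert levels[0] == pytest.approx(30.0)

    def test_undefined_replicate_dropped(self):
        rep1 = make_records([("Chr1", 999, "+", 5, 5, "CHH")])  # outside window
        rep2 = make_records([("Chr1", 150, "+", 4, 6, "CHH")])
        levels = window_levels([rep1, rep2], self._windows(), "CHH")
        assert levels[0] == pytest.approx(40.0)

    def test_single_library_stage(self):
        rep = make_records([("Chr1", 150, "+", 1, 3, "CHH")])
        assert window_levels([rep], self._windows(), "CHH")[0] == pytest.approx(25.0)

    def test_all_undefined_is_nan(self):
        rep = make_records([("Chr1", 999, "+", 1, 3, "CHH")])
        assert np.isnan(window_levels([rep], self._windows(), "CHH")[0])


def _window_table(n):
    return pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(n)],
            "chrom": "Chr1",
            "start": np.arange(n) * 100,
            "end": np.arange(n) * 100 + 100,
            "window_index": 0,
        }
    )


class TestCallDmrs:
    def test_strictly_more_than_threshold(self):
        wins = _window_table(2)
        out = call_dmrs(wins, [10.0, 10.0], [45.0, 40.0], "CHH", "S2", "S6")
        assert list(out["gene_id"]) == ["G0"]  # delta 35 yes, delta exactly 30 no
        assert out.iloc[0]["delta"] == pytest.approx(35.0)

    def test_undefined_windows_are_uncallable(self):
        wins = _window_table(1)
        out = call_dmrs(wins, [np.nan], [80.0], "CHH", "S2", "S6")
        assert len(out) == 0

    def test_mismatched_vectors_error(self):
        with pytest.raises(ValueError, match="match"):
            call_dmrs(_window_table(2), [1.0], [2.0, 3.0], "CHH", "S2", "S6")

    def test_symmetric_under_stage_swap(self, rng):
        wins = _window_table(50)
        a = rng.uniform(0, 100, 50)
        b = rng.uniform(0, 100, 50)
        fwd = call_dmrs(wins, a, b, "CHH", "S2", "S6")
        rev = call_dmrs(wins, b, a, "CHH", "S6", "S2")
        assert list(fwd["gene_id"]) == list(rev["gene_id"])
        assert np.allclose(fwd["delta"].to_numpy(), -rev["delta"].to_numpy())

    @given(st.integers(0, 2**31 - 1), st.floats(0, 60), st.floats(0, 60))
    @settings(max_examples=30, deadline=None)
    def test_raising_threshold_never_adds_dmrs(self, seed, t1, t2):
        lo, hi = sorted((t1, t2))
        r = np.random.default_rng(seed)
        wins = _window_table(30)
        a, b = r.uniform(0, 100, 30), r.uniform(0, 100, 30)
        loose = set(call_dmrs(wins, a, b, "CHH", "A", "B", lo)["gene_id"])
        strict = set(call_dmrs(wins, a, b, "CHH", "A", "B", hi)["gene_id"])
        assert strict <= loose


class TestLeafFallback:
    def test_leaf_dmr_called_when_stages_agree(self):
        wins = _window_table(1)
        stages = {"S2": [10.0], "S6": [12.0], "S8": [11.0]}
        out = leaf_fallback_dmrs(wins, stages, [60.0], "CHH")
        assert len(out) == 3  # every stage differs from leaf by > 30
        assert set(out["stage_b"]) == {"leaf"}

    def test_stage_dmr_takes_precedence(self):
        wins = _window_table(1)
        stages = {"S2": [10.0], "S6": [45.0], "S8": [11.0]}
        out = leaf_fallback_dmrs(wins, stages, [60.0], "CHH")
        assert len(out) == 0  # S2->S6 already a stage DMR: excluded from leaf

    def test_no_call_within_threshold(self):
        wins = _window_table(1)
        stages = {"S2": [40.0], "S6": [45.0], "S8": [50.0]}
        out = leaf_fallback_dmrs(wins, stages, [60.0], "CHH")
        assert len(out) == 0


class TestDmrGenes:
    def test_many_windows_collapse_to_one_gene(self):
        dmrs = pd.DataFrame({"gene_id": ["G1", "G1", "G1"]})
        assert map_dmr_genes(dmrs) == {"G1"}

    def test_empty(self):
        assert map_dmr_genes(pd.DataFrame(columns=["gene_id"])) == set()


class TestExpressionEnrichment:
    def test_all_genes_have_dmrs(self):
        genes = {f"G{i}" for i in range(10)}
        expressed = {f"G{i}" for i in range(6)}
        out = dmr_expression_enrichment(genes, expressed, genes)
        assert out["pct_expressed_with_dmr"] == 100.0
        assert out["pct_non_expressed_with_dmr"] == 100.0

    def test_empty_partition_errors(self):
        genes = {"G1", "G2"}
        with pytest.raises(ValueError):
            dmr_expression_enrichment(genes, genes, genes)

    def test_subset_violation_errors(self):
        with pytest.raises(ValueError, match="subset"):
            dmr_expression_enrichment(set(), {"GX"}, {"G1"})


class TestScanMatchesNaiveOracle:
    """The vectorised window-level scan must agree exactly with a naive
    per-window recomputation that filters raw records for every window."""

    def _naive_levels(self, replicate_frames, windows, context):
        out = np.full(len(windows), np.nan)
        for i, w in windows.iterrows():
            per_rep = []
            for df in replicate_frames:
                sub = df[
                    (df["chrom"] == w["chrom"])
                    & (df["context"] == context)
                    & (df["pos"] >= w["start"])
                    & (df["pos"] < w["end"])
                ]
                total = int(sub["meth"].sum() + sub["unmeth"].sum())
                if total > 0:
                    per_rep.append(100.0 * sub["meth"].sum() / total)
            if per_rep:
                out[i] = float(np.mean(per_rep))
        return out

    def test_equivalence_on_small_genome(self, rng):
        chrom_len = 120_000
        genes = [
            GeneModel(f"G{i}", "Chr1", "+" if i % 2 else "-", int(s), int(s) + 1200)
            for i, s in enumerate(rng.integers(4500, chrom_len - 6000, size=60))
        ]
        windows = promoter_window_table(genes, {"Chr1": chrom_len})
        reps = []
        for seed in (1, 2):
            r = np.random.default_rng(seed)
            pos = np.sort(r.choice(chrom_len, 6000, replace=False))
            depth = r.poisson(6, len(pos))
            meth = r.binomial(depth, 0.3)
            reps.append(
                pd.DataFrame(
                    {
                        "chrom": "Chr1",
                        "pos": pos,
                        "strand": "+",
                        "meth": meth,
                        "unmeth": depth - meth,
                        "context": "CHH",
                        "tricontext": "CAT",
                    }
                )
            )
        fast = window_levels([CytosineIndex(r) for r in reps], windows, "CHH")
        naive = self._naive_levels(reps, windows, "CHH")
        assert np.array_equal(np.isnan(fast), np.isnan(naive))
        assert np.allclose(fast[~np.isnan(fast)], naive[~np.isnan(naive)])

    def test_null_simulation_dmr_rate_matches_monte_carlo(self):
        """Under identical truth in both stages the observed DMR rate equals
        an independently simulated prediction of the same sampling model."""
        n_windows, sites, cov, p = 3000, 2, 8.0, 0.30
        r = np.random.default_rng(99)

        def draw_window_percent(k):
            depth = r.poisson(cov, size=k)
            meth = r.binomial(depth, p)
            tot = depth.sum()
            return 100.0 * meth.sum() / tot if tot else np.nan

        # pipeline-path levels via call_dmrs on simulated window levels
        a = np.array([draw_window_percent(sites) for _ in range(n_windows)])
        b = np.array([draw_window_percent(sites) for _ in range(n_windows)])
        wins = pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(n_windows)],
                "chrom": "Chr1",
                "start": np.arange(n_windows) * 100,
                "end": np.arange(n_windows) * 100 + 100,
                "window_index": 0,
            }
        )
        dmrs = call_dmrs(wins, a, b, "CHH", "A", "B")
        callable_ = (~np.isnan(a) & ~np.isnan(b)).sum()
        rate = len(dmrs) / callable_

        # independent Monte-Carlo of the identical sampling model
        mc = 20_000
        xa = np.array([draw_window_percent(sites) for _ in range(mc)])
        xb = np.array([draw_window_percent(sites) for _ in range(mc)])
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        predicted = float((np.abs(xa[ok] - xb[ok]) > 30).mean())
        se = np.sqrt(predicted * (1 - predicted) / callable_ + 1e-12)
        se_mc = np.sqrt(predicted * (1 - predicted) / ok.sum() + 1e-12)
        assert abs(rate - predicted) <= 2 * (se + se_mc) + 1e-9
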