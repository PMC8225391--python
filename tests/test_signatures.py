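"""Battery enrichment/rank tests, BH correction and signature calls."""

import math

import numpy as np
import pandas as pd
import pytest

import phylofoot as pf
from phylofoot.signatures import MotifGenomeData, SignatureError


class TestSimilarityFilter:
    def frame(self, rows):
        return pd.DataFrame(
            rows, columns=["motif_id", "best_cross_TF_similarity", "exclusion_rule"]
        )

    def test_boundary_inclusive(self):
        kept = pf.filter_motifs_by_similarity(
            self.frame([("mA", 0.807, None)]), sr_cutoff=0.807
        )
        assert kept == ["mA"]

    def test_above_cutoff_excluded(self):
        kept = pf.filter_motifs_by_similarity(self.frame([("mB", 0.95, None)]))
        assert kept == []

    def test_explicit_exclusion_rule(self):
        kept = pf.filter_motifs_by_similarity(
            self.frame([("mC", 0.1, "duplicate"), ("mD", 0.1, None)])
        )
        assert kept == ["mD"]

    def test_empty_table(self):
        assert pf.filter_motifs_by_similarity(self.frame([])) == []

    def test_missing_columns_raise(self):
        with pytest.raises(SignatureError, match="missing columns"):
            pf.filter_motifs_by_similarity(pd.DataFrame({"motif_id": ["x"]}))


class TestEnrichmentTest:
    def battery(self, genes):
        return pf.GeneBattery("b", frozenset(genes))

    def test_closed_form_all_hits(self):
        """Genome 20, 10 candidates, battery of 5 all with motif:
        p = C(10,5)/C(20,5) = 252/15504."""
        candidates = {f"g{i}" for i in range(10)}
        n, p, _ = pf.enrichment_test(self.battery([f"g{i}" for i in range(5)]), candidates, 20)
        assert n == 5
        assert p == pytest.approx(252 / 15504, rel=1e-9)

    def test_at_expectation_heavy_tail(self):
        # N=20, K=10, draws 4, observed 2 (= the expectation) -> p >= 0.5
        candidates = {f"g{i}" for i in range(10)}
        batt = self.battery(["g0", "g1", "g90", "g91"])
        n, p, _ = pf.enrichment_test(batt, candidates, 20)
        assert n == 2 and p >= 0.5

    def test_zero_observed_p_one(self):
        candidates = {f"g{i}" for i in range(10)}
        n, p, _ = pf.enrichment_test(self.battery(["x1", "x2"]), candidates, 20)
        assert n == 0 and p == 1.0

    def test_universe_violation_raises(self):
        with pytest.raises(SignatureError, match="outside"):
            pf.enrichment_test(
                self.battery(["alien"]), {"g1"}, 10, genome_universe={"g1", "g2"}
            )

    def test_permissive_drops_offenders(self):
        n, p, used = pf.enrichment_test(
            self.battery(["g1", "alien"]),
            {"g1"},
            10,
            genome_universe={"g1", "g2"},
            permissive=True,
        )
        assert used.genes == frozenset({"g1"}) and n == 1


class TestRankTest:
    def test_top_ranked_small_battery(self):
        genome = np.linspace(1, 100, 200)
        p, ok, flags = pf.rank_test([98.0, 95.0, 91.0], genome)
        assert ok and not flags
        assert 1e-4 < p < 0.1  # marginal at n=3

    def test_closed_form_3v3(self):
        p, ok, _ = pf.rank_test([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(0.0495, abs=5e-4)
        assert ok

    def test_empty_battery_flagged(self):
        p, ok, flags = pf.rank_test([], np.linspace(1, 100, 50))
        assert p == 1.0 and not ok and flags == ["no_motif_bearing_battery_genes"]

    def test_null_uniformity(self):
        """Battery ranks drawn from the genome ranks give uniform p-values.

        The KS statistic of a single 1000-draw replicate is itself noisy, so
        the assertion is on the median KS p over three replicates.
        """
        from scipy.stats import kstest

        genome = np.linspace(1, 100, 2000)
        ks_ps = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            ps = [
                pf.rank_test(rng.choice(genome, size=40, replace=False), genome)[0]
                for _ in range(1000)
            ]
            ks_ps.append(kstest(ps, "uniform").pvalue)
            rate = np.mean(np.asarray(ps) < 0.05)
            assert 0.02 < rate < 0.08
        assert np.median(ks_ps) > 0.01


class TestClassifySignature:
    @pytest.mark.parametrize(
        "ep,rp,ok,expected",
        [
            (0.001, 0.001, True, "coordinated"),
            (0.30, 0.001, True, "piecemeal"),
            (0.001, 0.30, True, "other"),
            (0.30, 0.30, True, "other"),
            (0.001, 0.001, False, "other"),
        ],
    )
    def test_truth_table(self, ep, rp, ok, expected):
        category, _ = pf.classify_signature(ep, rp, ok)
        assert category == expected

    def test_subcases_distinguish_other(self):
        assert pf.classify_signature(0.001, 0.3, True)[1] == "enriched_not_ranked"
        assert pf.classify_signature(0.3, 0.3, True)[1] == "neither"


class TestBHAdjust:
    def test_hand_step_up(self):
        adj = pf.bh_adjust([0.01, 0.04, 0.03, 0.05])
        assert np.allclose(adj, [0.04, 0.05, 0.05, 0.05])

    def test_all_equal_unchanged(self):
        assert np.allclose(pf.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_single_p_unchanged(self):
        assert pf.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_out_of_range_raises(self):
        with pytest.raises(SignatureError):
            pf.bh_adjust([0.5, 1.5])

    def test_validity_properties(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        adj = pf.bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestRunSignatureAnalysis:
    def make_data(self, motif_id, candidates, seed=0):
        rng = np.random.default_rng(seed)
        ranks = pd.Series(
            rng.permutation(np.linspace(1, 100, len(candidates))),
            index=sorted(candidates),
        )
        return MotifGenomeData(motif_id, frozenset(candidates), ranks)

    def test_expression_gate_row_count(self):
        candidates = {f"g{i}" for i in range(50)}
        data = {"tf1": self.make_data("tf1", candidates)}
        batteries = [
            pf.GeneBattery(f"b{i}", frozenset([f"g{i}", f"g{i+1}"])) for i in range(5)
        ]
        expression = {("tf1", "b0"), ("tf1", "b2"), ("tf1", "b4")}
        results = pf.run_signature_analysis(data, batteries, expression, 200)
        assert len(results) == 3
        assert {r.battery_label for r in results} == {"b0", "b2", "b4"}

    def test_every_tested_pair_has_one_category(self):
        candidates = {f"g{i}" for i in range(60)}
        data = {
            "tfA": self.make_data("tfA", candidates, 1),
            "tfB": self.make_data("tfB", candidates, 2),
        }
        batteries = [
            pf.GeneBattery(f"b{i}", frozenset(f"g{j}" for j in range(i, i + 10)))
            for i in range(4)
        ]
        expression = {(m, b.label) for m in data for b in batteries}
        results = pf.run_signature_analysis(data, batteries, expression, 300)
        assert len(results) == 8
        assert all(r.category in pf.signatures.CATEGORIES for r in results)
        frame = pf.signature_frame(results)
        assert len(frame) == 8 and frame["category"].notna().all()
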