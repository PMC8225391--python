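"""Training sets, the ranking classifier and cross-validation."""

import numpy as np
import pandas as pd
import pytest

import phylofoot as pf
from phylofoot.ranking import TrainingSetError

from conftest import random_feature_table

SPECIES = [f"s{i}" for i in range(1, 9)]


def separable_table(n_targets=30, n_background=300, seed=0):
    """Targets: high conservation and scores; background: sparse, weak."""
    rng = np.random.default_rng(seed)
    cols = pf.feature_columns(SPECIES)
    rows = []
    ids = []
    for i in range(n_targets + n_background):
        target = i < n_targets
        row = {}
        for sp in SPECIES:
            present = rng.random() < (0.95 if target else 0.2)
            freq = rng.integers(1, 4) if present else 0
            score = rng.normal(20 if target else 13, 1) if present else 0.0
            row[f"f_{sp}_upFreq"] = freq
            row[f"f_{sp}_upMax"] = score
            row[f"f_{sp}_upAvg"] = score * 0.9
            row[f"f_{sp}_inFreq"] = 0
            row[f"f_{sp}_inMax"] = 0.0
            row[f"f_{sp}_inAvg"] = 0.0
        row["up_cons"] = sum(row[f"f_{sp}_upFreq"] > 0 for sp in SPECIES)
        row["in_cons"] = 0
        rows.append(row)
        ids.append(("t" if target else "b") + f"{i:04d}")
    table = pd.DataFrame(rows, index=pd.Index(ids, name="gene_id"))[cols]
    targets = [g for g in ids if g.startswith("t")]
    return table, targets


class TestBuildTrainingSet:
    def test_equal_label_counts(self):
        table = random_feature_table(5000, SPECIES)
        positives = list(table.index[:100])
        ts = pf.build_training_set(positives, table, seed=7)
        assert len(ts.labels) == 200
        assert (ts.labels == 1).sum() == 100 and (ts.labels == 0).sum() == 100

    def test_absent_positive_dropped_with_record(self):
        table = random_feature_table(50, SPECIES)
        ts = pf.build_training_set(
            ["g00001", "g00002", "ghost"], table, seed=1
        )
        assert ts.dropped == ["ghost"]
        assert (ts.labels == 1).sum() == 2

    def test_seed_reproducibility(self):
        table = random_feature_table(500, SPECIES)
        pos = list(table.index[:20])
        a = pf.build_training_set(pos, table, seed=9)
        b = pf.build_training_set(pos, table, seed=9)
        assert list(a.labels.index) == list(b.labels.index)

    def test_too_few_candidates_raises(self):
        table = random_feature_table(30, SPECIES)
        with pytest.raises(TrainingSetError, match="too few"):
            pf.build_training_set(list(table.index[:25]), table, seed=0)


class TestTrainClassifier:
    def test_separable_training_recall_one(self):
        table, targets = separable_table()
        ts = pf.build_training_set(targets, table, seed=2)
        model = pf.train_classifier(ts, seed=2)
        post = model.posterior(ts.features)
        assert (post[ts.labels.to_numpy() == 1] >= 0.5).mean() == 1.0

    def test_no_signal_posterior_half(self):
        cols = pf.feature_columns(SPECIES)
        rows = pd.DataFrame(
            np.ones((20, len(cols))), columns=cols,
            index=pd.Index([f"g{i}" for i in range(20)], name="gene_id"),
        )
        ts = pf.TrainingSet(
            features=rows, labels=pd.Series([1] * 10 + [0] * 10, index=rows.index), seed=0
        )
        model = pf.train_classifier(ts, seed=0)
        assert np.allclose(model.posterior(rows), 0.5, atol=0.05)

    def test_refit_determinism(self):
        table, targets = separable_table()
        ts = pf.build_training_set(targets, table, seed=4)
        p1 = pf.train_classifier(ts, seed=4).posterior(table)
        p2 = pf.train_classifier(ts, seed=4).posterior(table)
        assert np.allclose(p1, p2, atol=1e-8)

    def test_one_label_raises(self):
        table = random_feature_table(10, SPECIES)
        ts = pf.TrainingSet(
            features=table, labels=pd.Series(1, index=table.index), seed=0
        )
        with pytest.raises(TrainingSetError, match="degenerate"):
            pf.train_classifier(ts)

    @pytest.mark.parametrize("kind", ["logistic", "random_forest"])
    def test_alternative_kinds_fit(self, kind):
        table, targets = separable_table(20, 100)
        ts = pf.build_training_set(targets, table, seed=5)
        model = pf.train_classifier(ts, kind=kind, seed=5)
        assert model.posterior(table).shape == (len(table),)


class TestRankTargets:
    def make_model(self, posteriors):
        class Fake:
            def __init__(self, p):
                self._p = np.asarray(p, dtype=float)

            def posterior(self, table):
                return self._p

        return Fake(posteriors)

    def table(self, n):
        return random_feature_table(n, SPECIES)

    def test_linear_map_endpoints_and_midpoint(self):
        ranked = pf.rank_targets(self.make_model([0.9, 0.5, 0.1]), self.table(3))
        assert list(ranked["normalized_rank"]) == [100.0, 50.5, 1.0]

    def test_tie_rule(self):
        ranked = pf.rank_targets(self.make_model([0.8, 0.8, 0.1]), self.table(3))
        assert sorted(ranked["rank"]) == [1.5, 1.5, 3.0]
        assert ranked["normalized_rank"].iloc[0] == pytest.approx(75.25)

    def test_single_row_is_100(self):
        ranked = pf.rank_targets(self.make_model([0.42]), self.table(1))
        assert ranked["normalized_rank"].iloc[0] == 100.0

    def test_empty_table(self):
        model = self.make_model([])
        assert pf.rank_targets(model, self.table(0)).empty

    def test_probability_nonincreasing_with_rank(self):
        rng = np.random.default_rng(0)
        ranked = pf.rank_targets(self.make_model(rng.random(50)), self.table(50))
        assert (np.diff(ranked["probability"]) <= 1e-12).all()
        assert ranked["normalized_rank"].iloc[0] == 100.0
        assert ranked["normalized_rank"].iloc[-1] == 1.0

    def test_row_order_permutation_invariance(self):
        table, targets = separable_table(10, 60)
        ts = pf.build_training_set(targets, table, seed=3)
        model = pf.train_classifier(ts, seed=3)
        r1 = pf.rank_targets(model, table)
        shuffled = table.sample(frac=1.0, random_state=1)
        r2 = pf.rank_targets(model, shuffled)
        assert r1.sort_index().equals(r2.sort_index())


class TestRankSumsOracle:
    def test_closed_form_small_n(self):
        """Posteriors ranked {4,5,6} vs {1,2,3}: Z = 1.964, p ~ 0.0495."""
        from scipy.stats import ranksums

        stat = ranksums([0.4, 0.5, 0.6], [0.1, 0.2, 0.3])
        # closed form: W=15, mean=10.5, sd=sqrt(n1*n2*(n+1)/12)=sqrt(5.25)
        expect = (15 - 10.5) / np.sqrt(5.25)
        assert stat.statistic == pytest.approx(expect, abs=1e-12)
        assert stat.statistic == pytest.approx(1.964, abs=1e-3)
        assert stat.pvalue == pytest.approx(0.0495, abs=5e-4)


class TestCrossValidation:
    def test_fold_count(self):
        table, targets = separable_table(12, 80)
        reports = pf.run_cross_validation(
            targets, table, ("logistic",), repeats=3, seed=0
        )
        assert len(reports["logistic"].folds) == 6

    def test_separable_fixture_strong(self):
        table, targets = separable_table()
        reports = pf.run_cross_validation(
            targets, table, ("gaussian_process",), repeats=10, seed=1
        )
        r = reports["gaussian_process"]
        assert len(r.folds) == 20
        assert r.median_recall >= 0.9
        assert r.median_z > 3

    def test_null_positives_recall_near_base_rate(self):
        """With no signal, randomly chosen 'positives' should achieve a
        median recall near the 0.5 posterior-threshold base rate."""
        table = random_feature_table(400, SPECIES, seed=11)
        rng = np.random.default_rng(12)
        positives = list(rng.choice(table.index.to_numpy(), 40, replace=False))
        reports = pf.run_cross_validation(
            positives, table, ("logistic",), repeats=10, seed=2
        )
        assert 0.25 <= reports["logistic"].median_recall <= 0.75
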