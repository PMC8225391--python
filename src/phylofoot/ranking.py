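"""Supervised ranking of candidate TF target genes.

Training sets pair validated target genes with an equal-sized random draw
of candidate genes (genes that carry at least one scoring motif match —
some of which may be unknown true targets; the classifier only needs the
two samples to differ in their feature distributions).  A probabilistic
binary classifier (Gaussian process by default) is fit on standardized
features and every candidate gene is ranked by its posterior probability of
being a target.  Ranks are rescaled to a normalized rank in [1, 100] where
100 is the best-predicted target and 1 the worst.

Model assessment uses a repeated 2-fold scheme: per repeat the positives
plus a fresh random negative draw are shuffled, split in half, and each
half serves once as training and once as validation; per fold we record
recall of validation positives at a 0.5 posterior threshold and the
rank-sums Z statistic comparing validation-positive posteriors with
validation-negative posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ranksums
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

CLASSIFIER_KINDS = ("gaussian_process", "logistic", "random_forest")


class TrainingSetError(ValueError):
    """Raised when a valid training set cannot be built."""


@dataclass
class TrainingSet:
    """Balanced labeled feature rows: label 1 = validated target, 0 = random
    candidate gene.  ``dropped`` lists requested positives absent from the
    feature table."""

    features: pd.DataFrame
    labels: pd.Series
    seed: int
    positive_source: str = "user"
    dropped: list[str] = field(default_factory=list)

    def validate_balanced(self) -> None:
        counts = self.labels.value_counts()
        if set(counts.index) != {0, 1} or counts[0] != counts[1]:
            raise TrainingSetError("training set must have equal label counts")
        if self.features.index.duplicated().any():
            raise TrainingSetError("duplicate gene id in training set")


def build_training_set(
    positives: list[str],
    feature_table: pd.DataFrame,
    seed: int,
    positive_source: str = "user",
) -> TrainingSet:
    """Pair the validated positives with an equal-sized uniform draw (without
    replacement) of other candidate genes from the feature table."""
    present = [g for g in positives if g in feature_table.index]
    dropped = [g for g in positives if g not in feature_table.index]
    if len(present) < 2:
        raise TrainingSetError(
            f"too few positives present in the feature table ({len(present)})"
        )
    pool = feature_table.index.difference(present)
    if len(pool) < len(present):
        raise TrainingSetError(
            f"too few candidate genes ({len(pool)}) to draw {len(present)} negatives"
        )
    rng = np.random.default_rng(seed)
    negatives = list(rng.choice(np.asarray(pool, dtype=object), size=len(present), replace=False))
    rows = feature_table.loc[present + negatives]
    labels = pd.Series([1] * len(present) + [0] * len(negatives), index=rows.index)
    ts = TrainingSet(
        features=rows,
        labels=labels,
        seed=seed,
        positive_source=positive_source,
        dropped=dropped,
    )
    ts.validate_balanced()
    return ts


@dataclass
class TargetClassifier:
    """A fitted probabilistic classifier plus its feature-column contract."""

    pipeline: Pipeline
    columns: list[str]
    kind: str

    def posterior(self, feature_table: pd.DataFrame) -> np.ndarray:
        """Posterior probability of the target label per row."""
        X = feature_table[self.columns].to_numpy(dtype=float)
        proba = self.pipeline.predict_proba(X)
        target_col = list(self.pipeline.classes_).index(1)
        return proba[:, target_col]


def _make_estimator(kind: str, seed: int):
    if kind == "gaussian_process":
        kernel = ConstantKernel(1.0) * RBF(length_scale=1.0)
        return GaussianProcessClassifier(kernel=kernel, random_state=seed)
    if kind == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")


def train_classifier(
    ts: TrainingSet,
    kind: str = "gaussian_process",
    seed: int = 0,
    standardize: bool = True,
) -> TargetClassifier:
    """Fit a probabilistic binary classifier on the training set.

    Features are standardized with statistics from the training rows only
    (applied unchanged to any table scored later).
    """
    if ts.labels.nunique() < 2:
        raise TrainingSetError("degenerate training set: one label only")
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", _make_estimator(kind, seed)))
    pipe = Pipeline(steps)
    pipe.fit(ts.features.to_numpy(dtype=float), ts.labels.to_numpy())
    return TargetClassifier(pipeline=pipe, columns=list(ts.features.columns), kind=kind)


def normalized_rank(rank: np.ndarray, n_rows: int) -> np.ndarray:
    """Map rank 1..G onto [1, 100] with 100 = best; a single row maps to 100."""
    rank = np.asarray(rank, dtype=float)
    if n_rows <= 1:
        return np.full_like(rank, 100.0)
    return 1.0 + 99.0 * (n_rows - rank) / (n_rows - 1.0)


def rank_targets(
    model: TargetClassifier, feature_table: pd.DataFrame
) -> pd.DataFrame:
    """Rank every candidate gene by posterior probability.

    Returns a DataFrame (gene_id index) with ``probability``, ``rank``
    (1 = best; ties share the mean of their ranks) and ``normalized_rank``,
    sorted by probability descending.
    """
    if feature_table.empty:
        return pd.DataFrame(
            columns=["probability", "rank", "normalized_rank"],
            index=pd.Index([], name="gene_id"),
        )
    # round to absorb batch-order float noise so tie structure (and thus
    # ranks) is invariant to row order
    prob = np.round(model.posterior(feature_table), 10)
    rank = rankdata(-prob, method="average")
    out = pd.DataFrame(
        {
            "probability": prob,
            "rank": rank,
            "normalized_rank": normalized_rank(rank, len(prob)),
        },
        index=feature_table.index,
    )
    return out.sort_values(["probability", "rank"], ascending=[False, True], kind="mergesort")


@dataclass
class CVReport:
    """Per-(repeat, fold) recall and rank-sums Z for one classifier kind."""

    kind: str
    folds: pd.DataFrame  # columns: repeat, fold, recall, rank_sums_z

    @property
    def median_recall(self) -> float:
        return float(self.folds["recall"].median())

    @property
    def median_z(self) -> float:
        return float(self.folds["rank_sums_z"].median())


def run_cross_validation(
    positives: list[str],
    feature_table: pd.DataFrame,
    classifier_kinds: tuple[str, ...] = ("gaussian_process",),
    repeats: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> dict[str, CVReport]:
    """Repeated 2-fold cross-validation with a fresh negative draw per repeat.

    Each repeat shuffles the 2N labeled rows and splits them in half (an odd
    row count puts the extra row in the training half); each half is used
    once for training and once for validation.
    """
    reports = {kind: [] for kind in classifier_kinds}
    for r in range(repeats):
        sub_seed = (seed * 100003 + r) % (2**31)
        ts = build_training_set(positives, feature_table, seed=sub_seed)
        rng = np.random.default_rng(sub_seed + 1)
        order = rng.permutation(len(ts.labels))
        half = (len(order) + 1) // 2  # extra row to the training half
        idx_a, idx_b = order[:half], order[half:]
        for fold, (train_idx, val_idx) in enumerate(((idx_a, idx_b), (idx_b, idx_a)), 1):
            # fold halves need not be label-balanced; no balance check here
            train = TrainingSet(
                features=ts.features.iloc[train_idx],
                labels=ts.labels.iloc[train_idx],
                seed=sub_seed,
                positive_source=ts.positive_source,
            )
            val_feats = ts.features.iloc[val_idx]
            val_labels = ts.labels.iloc[val_idx].to_numpy()
            for kind in classifier_kinds:
                model = train_classifier(
                    train, kind=kind, seed=sub_seed, standardize=standardize
                )
                post = model.posterior(val_feats)
                pos_post = post[val_labels == 1]
                neg_post = post[val_labels == 0]
                recall = float((pos_post >= 0.5).mean()) if len(pos_post) else float("nan")
                z = (
                    float(ranksums(pos_post, neg_post).statistic)
                    if len(pos_post) and len(neg_post)
                    else float("nan")
                )
                reports[kind].append(
                    {"repeat": r + 1, "fold": fold, "recall": recall, "rank_sums_z": z}
                )
    return {
        kind: CVReport(kind=kind, folds=pd.DataFrame(rows))
        for kind, rows in reports.items()
    }
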