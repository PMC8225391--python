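"""Motif-signature statistics within gene batteries.

For a TF motif and a gene battery (the set of genes differentially
expressed by one cell class) two tests are run:

* an **enrichment test**: the hypergeometric upper-tail probability of
  drawing at least the observed number of motif-bearing battery genes when
  sampling the battery size from the genome, with the genome-wide set of
  motif-bearing candidate genes as successes;
* a **rank test**: a two-sample Wilcoxon rank-sums test comparing the
  normalized classifier ranks of motif-bearing battery genes against the
  ranks of all candidate genes genome-wide.  The reported p-value is
  two-sided; calling a battery significantly *well* ranked additionally
  requires its median normalized rank to exceed the genome median (the
  direction guard).

After Benjamini-Hochberg correction (enrichment and rank p-values corrected
as separate families across all (motif, battery) pairs in a run) each pair
is classified: ``coordinated`` (enriched and well ranked), ``piecemeal``
(not enriched, but motif-bearing battery genes well ranked) or ``other``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, ranksums
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05
SR_CUTOFF_DEFAULT = 0.807

CATEGORIES = ("coordinated", "piecemeal", "other")


class SignatureError(ValueError):
    """Raised for invalid battery / universe input."""


@dataclass(frozen=True)
class GeneBattery:
    """A labeled gene set (e.g. one neuron class's effector battery)."""

    label: str
    genes: frozenset[str]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.genes:
            raise SignatureError(f"battery {self.label!r} is empty")


@dataclass
class MotifGenomeData:
    """Genome-wide evidence for one motif: the candidate gene set (genes
    with >= 1 upstream/intronic match) and their normalized ranks."""

    motif_id: str
    candidates: frozenset[str]
    ranks: pd.Series  # index: candidate gene id -> normalized rank

    @property
    def genome_ranks(self) -> np.ndarray:
        return self.ranks.to_numpy(dtype=float)


@dataclass
class SignatureResult:
    motif_id: str
    battery_label: str
    n_battery: int
    n_with_motif: int
    prop_with_motif: float
    genome_prop: float
    enrich_p: float
    rank_p: float
    direction_ok: bool
    enrich_p_adj: float = float("nan")
    rank_p_adj: float = float("nan")
    category: str = ""
    subcase: str = ""
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Motif curation filter
# ---------------------------------------------------------------------------


def filter_motifs_by_similarity(
    tf_table: str | Path | pd.DataFrame, sr_cutoff: float = SR_CUTOFF_DEFAULT
) -> list[str]:
    """Keep motifs attributable to a single TF.

    The table needs columns ``motif_id``, ``best_cross_TF_similarity`` (the
    similarity-regression score of the TF's DNA-binding domain to its
    nearest other TF) and ``exclusion_rule``.  Motifs whose similarity
    *exceeds* the cutoff (boundary inclusive: a score equal to the cutoff is
    retained) or that carry an explicit exclusion rule are dropped.
    """
    df = (
        tf_table
        if isinstance(tf_table, pd.DataFrame)
        else pd.read_csv(tf_table, sep="\t")
    )
    required = {"motif_id", "best_cross_TF_similarity", "exclusion_rule"}
    if df.empty and not required <= set(df.columns):
        return []
    missing = required - set(df.columns)
    if missing:
        raise SignatureError(f"TF metadata table missing columns {sorted(missing)}")
    sr = pd.to_numeric(df["best_cross_TF_similarity"], errors="coerce")
    rule = df["exclusion_rule"].fillna("None").astype(str).str.strip()
    keep = (sr.isna() | (sr <= sr_cutoff)) & rule.isin(["", "None", "none", "NA"])
    return df.loc[keep, "motif_id"].astype(str).tolist()


# ---------------------------------------------------------------------------
# The two tests
# ---------------------------------------------------------------------------


def enrichment_test(
    battery: GeneBattery,
    candidate_genes: frozenset[str] | set[str],
    genome_size: int,
    genome_universe: set[str] | None = None,
    permissive: bool = False,
) -> tuple[int, float, GeneBattery]:
    """Hypergeometric upper tail P(X >= n_with_motif) for the number of
    motif-bearing battery genes (population ``genome_size``, successes
    ``|candidate_genes|``, draws ``|battery|``).

    With a ``genome_universe``, battery genes outside it raise an error (or
    are dropped when ``permissive``); the returned battery reflects any
    drop.
    """
    genes = set(battery.genes)
    if genome_universe is not None:
        offenders = sorted(genes - set(genome_universe))
        if offenders:
            if not permissive:
                raise SignatureError(
                    f"battery {battery.label!r}: gene(s) outside the genome "
                    f"universe: {offenders[:10]}"
                )
            genes -= set(offenders)
            if not genes:
                raise SignatureError(
                    f"battery {battery.label!r}: no genes left after dropping "
                    "ids outside the genome universe"
                )
            battery = GeneBattery(battery.label, frozenset(genes), battery.source)
    if genome_size < len(candidate_genes):
        raise SignatureError("genome_size smaller than the candidate set")
    n_with = len(genes & set(candidate_genes))
    p = float(hypergeom.sf(n_with - 1, genome_size, len(candidate_genes), len(genes)))
    return n_with, min(p, 1.0), battery


def rank_test(
    battery_ranks: np.ndarray | list[float], genome_ranks: np.ndarray | list[float]
) -> tuple[float, bool, list[str]]:
    """Two-sided rank-sums p for battery vs genome normalized ranks, plus the
    direction guard (battery median above the genome median).

    An empty battery rank list yields p = 1 with a flag (no motif-bearing
    battery genes to rank).
    """
    battery_ranks = np.asarray(battery_ranks, dtype=float)
    genome_ranks = np.asarray(genome_ranks, dtype=float)
    if len(battery_ranks) == 0:
        return 1.0, False, ["no_motif_bearing_battery_genes"]
    if len(genome_ranks) == 0:
        raise SignatureError("genome rank list is empty")
    stat = ranksums(battery_ranks, genome_ranks)
    direction_ok = float(np.median(battery_ranks)) > float(np.median(genome_ranks))
    return float(stat.pvalue), direction_ok, []


def randomized_tail_pvalue(
    observed: int, genome_size: int, successes: int, draws: int, u: float
) -> float:
    """Randomization-smoothed hypergeometric upper-tail p-value.

    ``P(X > observed) + u * P(X = observed)`` with ``u ~ Uniform(0, 1)`` is
    exactly Uniform(0, 1) under the null, which makes it the right object
    for verifying the calibration of the discrete enrichment tests; the
    reported p-values remain the conservative tail ``P(X >= observed)``.
    """
    p_upper = float(hypergeom.sf(observed - 1, genome_size, successes, draws))
    return p_upper - u * float(hypergeom.pmf(observed, genome_size, successes, draws))


def classify_signature(
    enrich_p_adj: float, rank_p_adj: float, direction_ok: bool, alpha: float = ALPHA
) -> tuple[str, str]:
    """Three-way call from the adjusted p-values.

    coordinated: enriched and well ranked; piecemeal: not enriched but well
    ranked; other: not well ranked (or ranked in the wrong direction).  The
    returned subcase distinguishes the two ways of being ``other``.
    """
    ranked = rank_p_adj < alpha and direction_ok
    enriched = enrich_p_adj < alpha
    if ranked and enriched:
        return "coordinated", ""
    if ranked:
        return "piecemeal", ""
    return "other", ("enriched_not_ranked" if enriched else "neither")


def bh_adjust(pvalues: list[float] | np.ndarray, alpha: float = ALPHA) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise SignatureError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=alpha, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Run-level orchestration
# ---------------------------------------------------------------------------


def run_signature_analysis(
    motif_data: dict[str, MotifGenomeData],
    batteries: list[GeneBattery],
    expression: set[tuple[str, str]],
    genome_size: int,
    genome_universe: set[str] | None = None,
    alpha: float = ALPHA,
    permissive: bool = False,
) -> list[SignatureResult]:
    """Run both tests for every (motif, battery) pair where the motif's TF is
    expressed in the battery's class, BH-correct each test family across the
    whole collection, and classify each pair.

    ``expression`` holds (motif_id, battery_label) pairs; motifs missing
    from ``motif_data`` are skipped.
    """
    results: list[SignatureResult] = []
    for battery in batteries:
        for motif_id, data in motif_data.items():
            if (motif_id, battery.label) not in expression:
                continue
            n_with, enrich_p, used = enrichment_test(
                battery, data.candidates, genome_size, genome_universe, permissive
            )
            in_batt = sorted(set(used.genes) & set(data.candidates))
            batt_ranks = data.ranks.loc[in_batt].to_numpy(dtype=float)
            rank_p, direction_ok, flags = rank_test(batt_ranks, data.genome_ranks)
            results.append(
                SignatureResult(
                    motif_id=motif_id,
                    battery_label=battery.label,
                    n_battery=len(used.genes),
                    n_with_motif=n_with,
                    prop_with_motif=n_with / len(used.genes),
                    genome_prop=len(data.candidates) / genome_size,
                    enrich_p=enrich_p,
                    rank_p=rank_p,
                    direction_ok=direction_ok,
                    flags=flags,
                )
            )
    if results:
        enrich_adj = bh_adjust([r.enrich_p for r in results], alpha)
        rank_adj = bh_adjust([r.rank_p for r in results], alpha)
        for r, ea, ra in zip(results, enrich_adj, rank_adj):
            r.enrich_p_adj = float(ea)
            r.rank_p_adj = float(ra)
            r.category, r.subcase = classify_signature(
                r.enrich_p_adj, r.rank_p_adj, r.direction_ok, alpha
            )
    return results


def signature_frame(results: list[SignatureResult]) -> pd.DataFrame:
    """Tabular view of signature results (one row per motif x battery)."""
    return pd.DataFrame(
        [
            {
                "motif_id": r.motif_id,
                "battery_label": r.battery_label,
                "n_battery": r.n_battery,
                "n_with_motif": r.n_with_motif,
                "prop_with_motif": r.prop_with_motif,
                "genome_prop": r.genome_prop,
                "enrich_p": r.enrich_p,
                "rank_p": r.rank_p,
                "enrich_p_adj": r.enrich_p_adj,
                "rank_p_adj": r.rank_p_adj,
                "direction_ok": r.direction_ok,
                "category": r.category,
                "subcase": r.subcase,
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )
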