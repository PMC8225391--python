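"""Pairwise cofactor co-occurrence analysis within gene batteries.

Two motifs co-occur in a battery when genes carrying *both* motifs are
over-represented relative to an independence expectation: the expected
proportion is the product of the two genome-wide motif-bearing proportions,
and the observed joint count is tested against a hypergeometric null whose
success count is ``round(genome_size * p1 * p2)``.  The jointly hit battery
genes are additionally rank-tested once per motif against that motif's
genome-wide candidate ranks; joint rank significance requires both tests to
pass.

Combined with the two motifs' individual signature categories this yields a
three-way call: ``co_coordinated`` (both coordinated, co-enriched, jointly
well ranked), ``common_piecemeal`` (co-tests pass but at least one motif is
an individual piecemeal regulator) or ``independent``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .signatures import (
    ALPHA,
    GeneBattery,
    MotifGenomeData,
    SignatureError,
    SignatureResult,
    bh_adjust,
    rank_test,
)

CO_CATEGORIES = ("co_coordinated", "common_piecemeal", "independent")

_MIN_TAIL = np.nextafter(0.0, 1.0)


@dataclass
class CofactorResult:
    motif1: str
    motif2: str
    battery_label: str
    n_battery: int
    n_both: int
    expected_prop: float
    co_enrich_p: float
    rank_p_motif1: float
    rank_p_motif2: float
    direction_ok_motif1: bool
    direction_ok_motif2: bool
    co_enrich_p_adj: float = float("nan")
    rank_p_motif1_adj: float = float("nan")
    rank_p_motif2_adj: float = float("nan")
    category: str = ""
    flags: list[str] = field(default_factory=list)


def co_enrichment_test(
    battery: GeneBattery,
    candidates1: frozenset[str] | set[str],
    candidates2: frozenset[str] | set[str],
    genome_size: int,
) -> tuple[int, float, list[str]]:
    """Upper-tail hypergeometric p for the joint motif count in the battery.

    Successes are ``K = round(genome_size * p1 * p2)`` with ``p_i`` the
    genome-wide proportion of genes bearing motif i (the independence
    expectation).  A degenerate null (K = 0 with a positive observation)
    reports the smallest representable tail with a flag.
    """
    if genome_size < max(len(candidates1), len(candidates2)):
        raise SignatureError("genome_size smaller than a candidate set")
    genes = set(battery.genes)
    n_both = len(genes & set(candidates1) & set(candidates2))
    p1 = len(candidates1) / genome_size
    p2 = len(candidates2) / genome_size
    expected_prop = p1 * p2
    successes = int(round(genome_size * expected_prop))
    if successes == 0:
        if n_both > 0:
            return n_both, _MIN_TAIL, ["degenerate_null_K0"]
        return 0, 1.0, []
    p = float(hypergeom.sf(n_both - 1, genome_size, successes, len(genes)))
    return n_both, min(p, 1.0), []


def co_rank_tests(
    genes_both: set[str],
    data1: MotifGenomeData,
    data2: MotifGenomeData,
) -> tuple[float, float, bool, bool, list[str]]:
    """Rank-sums test of the jointly hit battery genes, once per motif,
    against that motif's genome-wide candidate ranks.

    An empty joint set yields (1, 1) with a flag.
    """
    if not genes_both:
        return 1.0, 1.0, False, False, ["no_joint_genes"]
    flags: list[str] = []
    out = []
    for data in (data1, data2):
        present = sorted(set(genes_both) & set(data.candidates))
        ranks = data.ranks.loc[present].to_numpy(dtype=float)
        p, ok, f = rank_test(ranks, data.genome_ranks)
        flags.extend(f)
        out.append((p, ok))
    (p1, ok1), (p2, ok2) = out
    return p1, p2, ok1, ok2, flags


def classify_cofactor(
    result: CofactorResult,
    category1: str,
    category2: str,
    alpha: float = ALPHA,
) -> str:
    """Three-way co-signature call from the adjusted p-values and the two
    motifs' individual signature categories in the same battery."""
    co_tests_pass = (
        result.co_enrich_p_adj < alpha
        and result.rank_p_motif1_adj < alpha
        and result.direction_ok_motif1
        and result.rank_p_motif2_adj < alpha
        and result.direction_ok_motif2
    )
    if not co_tests_pass:
        return "independent"
    if category1 == "coordinated" and category2 == "coordinated":
        return "co_coordinated"
    if "piecemeal" in (category1, category2):
        return "common_piecemeal"
    return "independent"


def run_cofactor_analysis(
    motif_data: dict[str, MotifGenomeData],
    batteries: list[GeneBattery],
    expression: set[tuple[str, str]],
    signature_results: list[SignatureResult],
    genome_size: int,
    alpha: float = ALPHA,
) -> list[CofactorResult]:
    """Pairwise co-occurrence analysis for every battery and every unordered
    pair of motifs co-expressed in it.

    BH correction is applied across all rows, with the co-enrichment
    p-values as one family and the pooled per-motif rank p-values as a
    second family.  Classification needs both motifs' individual signature
    results for the battery; a missing one raises an error.
    """
    sig_index = {
        (s.motif_id, s.battery_label): s.category for s in signature_results
    }
    results: list[CofactorResult] = []
    for battery in batteries:
        expressed = sorted(
            m for m in motif_data if (m, battery.label) in expression
        )
        for m1, m2 in combinations(expressed, 2):
            d1, d2 = motif_data[m1], motif_data[m2]
            n_both, co_p, flags = co_enrichment_test(
                battery, d1.candidates, d2.candidates, genome_size
            )
            genes_both = set(battery.genes) & set(d1.candidates) & set(d2.candidates)
            rp1, rp2, ok1, ok2, rank_flags = co_rank_tests(genes_both, d1, d2)
            results.append(
                CofactorResult(
                    motif1=m1,
                    motif2=m2,
                    battery_label=battery.label,
                    n_battery=len(battery.genes),
                    n_both=n_both,
                    expected_prop=(len(d1.candidates) / genome_size)
                    * (len(d2.candidates) / genome_size),
                    co_enrich_p=co_p,
                    rank_p_motif1=rp1,
                    rank_p_motif2=rp2,
                    direction_ok_motif1=ok1,
                    direction_ok_motif2=ok2,
                    flags=flags + rank_flags,
                )
            )
    if results:
        co_adj = bh_adjust([r.co_enrich_p for r in results], alpha)
        rank_family = [r.rank_p_motif1 for r in results] + [
            r.rank_p_motif2 for r in results
        ]
        rank_adj = bh_adjust(rank_family, alpha)
        n = len(results)
        for i, r in enumerate(results):
            r.co_enrich_p_adj = float(co_adj[i])
            r.rank_p_motif1_adj = float(rank_adj[i])
            r.rank_p_motif2_adj = float(rank_adj[i + n])
            key1 = (r.motif1, r.battery_label)
            key2 = (r.motif2, r.battery_label)
            if key1 not in sig_index or key2 not in sig_index:
                missing = key1 if key1 not in sig_index else key2
                raise SignatureError(
                    f"missing individual signature result for motif "
                    f"{missing[0]!r} in battery {missing[1]!r}"
                )
            r.category = classify_cofactor(r, sig_index[key1], sig_index[key2], alpha)
    return results


def cofactor_frame(results: list[CofactorResult]) -> pd.DataFrame:
    """Tabular view of cofactor results (one row per pair x battery)."""
    return pd.DataFrame(
        [
            {
                "motif1": r.motif1,
                "motif2": r.motif2,
                "battery_label": r.battery_label,
                "n_battery": r.n_battery,
                "n_both": r.n_both,
                "expected_prop": r.expected_prop,
                "co_enrich_p": r.co_enrich_p,
                "rank_p_motif1": r.rank_p_motif1,
                "rank_p_motif2": r.rank_p_motif2,
                "co_enrich_p_adj": r.co_enrich_p_adj,
                "rank_p_motif1_adj": r.rank_p_motif1_adj,
                "rank_p_motif2_adj": r.rank_p_motif2_adj,
                "direction_ok_motif1": r.direction_ok_motif1,
                "direction_ok_motif2": r.direction_ok_motif2,
                "category": r.category,
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )
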