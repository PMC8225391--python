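"""End-to-end orchestration: scan -> assign -> features -> rank -> tests.

The functions here tie the per-module steps together for both in-memory
worlds (the synthetic generator) and on-disk genome panels (FASTA + GFF3
per species plus an ortholog table), and produce the
:class:`~phylofoot.signatures.MotifGenomeData` bundles the signature and
cofactor statistics consume.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    AssignedMatch,
    GeneModel,
    assign_hits,
    compute_upstream_intervals,
    load_annotation,
    load_genome,
)
from .features import OrthologMap, build_feature_table, load_ortholog_map
from .motifs import Motif, Pssm, RawHit, build_pssm, scan_sequence
from .ranking import (
    TargetClassifier,
    build_training_set,
    rank_targets,
    train_classifier,
)
from .signatures import MotifGenomeData


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def estimate_background(sequences: dict[str, str]) -> np.ndarray:
    """0-order letter frequencies (A,C,G,T) of a genome, ignoring Ns."""
    counts = Counter()
    for seq in sequences.values():
        counts.update(seq.upper())
    totals = np.array([counts.get(c, 0) for c in "ACGT"], dtype=float)
    if totals.sum() == 0:
        return np.full(4, 0.25)
    return totals / totals.sum()


@dataclass
class ScanResult:
    """Genome-wide scan of one motif across a species panel."""

    motif: Motif
    pssm: Pssm
    p_threshold: float
    hits_by_species: dict[str, list[RawHit]]
    assigned_by_species: dict[str, list[AssignedMatch]]
    feature_table: pd.DataFrame
    genome_size: int  # protein-coding genes in the reference annotation

    @property
    def candidates(self) -> frozenset[str]:
        """Reference genes with >= 1 scoring (upstream/intron) match."""
        return frozenset(self.feature_table.index)


def scan_panel(
    sequences_by_species: dict[str, dict[str, str]],
    genes_by_species: dict[str, list[GeneModel]],
    omap: OrthologMap,
    motif: Motif,
    p_threshold: float = 1e-4,
    max_distance: int | None = None,
    pseudocount: float = 0.1,
    granularity: int = 1000,
    genome_background: bool = False,
) -> ScanResult:
    """Scan every species genome with the motif, assign hits to gene
    compartments and build the cross-species feature table.

    ``max_distance`` bounds the upstream search distance (``None`` searches
    the full intergenic stretch).  ``genome_background`` replaces the
    motif's background with the 0-order composition of the reference
    genome before building the PSSM.
    """
    if genome_background:
        bg = estimate_background(sequences_by_species[omap.reference_species])
        motif = Motif(
            id=motif.id,
            alt_name=motif.alt_name,
            width=motif.width,
            prob_matrix=motif.prob_matrix,
            background=bg,
            nsites=motif.nsites,
        )
    pssm = build_pssm(motif, pseudocount=pseudocount, granularity=granularity)
    hits_by_species: dict[str, list[RawHit]] = {}
    assigned_by_species: dict[str, list[AssignedMatch]] = {}
    for sp, seqs in sequences_by_species.items():
        genes = genes_by_species[sp]
        lengths = {sid: len(s) for sid, s in seqs.items()}
        compute_upstream_intervals(genes, lengths, max_distance)
        hits: list[RawHit] = []
        for seq_id, seq in seqs.items():
            hits.extend(scan_sequence(pssm, seq_id, seq, p_threshold))
        hits_by_species[sp] = hits
        assigned_by_species[sp] = assign_hits(hits, genes)
    table = build_feature_table(omap, assigned_by_species)
    return ScanResult(
        motif=motif,
        pssm=pssm,
        p_threshold=p_threshold,
        hits_by_species=hits_by_species,
        assigned_by_species=assigned_by_species,
        feature_table=table,
        genome_size=len(genes_by_species[omap.reference_species]),
    )


def scan_world(world, motif: Motif | None = None, **kwargs) -> ScanResult:
    """Convenience wrapper over :func:`scan_panel` for a synthetic world
    (defaults to the world's first planted motif)."""
    motif = motif if motif is not None else world.motifs[0]
    return scan_panel(
        world.sequences, world.genes, world.ortholog_map, motif, **kwargs
    )


@dataclass
class RankResult:
    """A fitted ranking model plus the genome-wide ranked candidate table."""

    model: TargetClassifier
    ranked: pd.DataFrame  # gene_id index: probability, rank, normalized_rank
    summary: pd.DataFrame  # ranked columns followed by the feature block
    dropped_positives: list[str]


def rank_candidates(
    scan: ScanResult,
    positives: list[str],
    kind: str = "gaussian_process",
    seed: int = 0,
    standardize: bool = True,
    model: TargetClassifier | None = None,
) -> RankResult:
    """Train (or reuse) a classifier on the validated positives and rank the
    whole candidate table."""
    dropped: list[str] = []
    if model is None:
        ts = build_training_set(positives, scan.feature_table, seed=seed)
        dropped = ts.dropped
        model = train_classifier(ts, kind=kind, seed=seed, standardize=standardize)
    ranked = rank_targets(model, scan.feature_table)
    summary = ranked.join(scan.feature_table)
    return RankResult(
        model=model, ranked=ranked, summary=summary, dropped_positives=dropped
    )


def motif_genome_data(scan: ScanResult, rank: RankResult) -> MotifGenomeData:
    """Bundle the genome-wide candidate set and normalized ranks for the
    signature and cofactor statistics."""
    return MotifGenomeData(
        motif_id=scan.motif.id,
        candidates=scan.candidates,
        ranks=rank.ranked["normalized_rank"],
    )


def load_panel(
    genome_dir: str | Path,
    species_panel: list[str],
    orthologs_path: str | Path,
) -> tuple[dict[str, dict[str, str]], dict[str, list[GeneModel]], OrthologMap]:
    """Load an on-disk panel: ``{sp}.fa`` and ``{sp}.gff3`` per species plus
    a tab-separated ortholog table (reference = first panel species)."""
    genome_dir = Path(genome_dir)
    sequences: dict[str, dict[str, str]] = {}
    genes: dict[str, list[GeneModel]] = {}
    for sp in species_panel:
        fasta = genome_dir / f"{sp}.fa"
        gff = genome_dir / f"{sp}.gff3"
        if not fasta.exists() or not gff.exists():
            raise PipelineError(
                "load", f"missing {fasta.name} or {gff.name} for species {sp}"
            )
        sequences[sp] = load_genome(fasta)
        genes[sp] = load_annotation(fasta, gff, sp)
    omap = load_ortholog_map(orthologs_path, species_panel)
    return sequences, genes, omap
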