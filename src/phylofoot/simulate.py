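"""Synthetic multi-species genomes with planted TF binding sites.

The generator emulates the study design of cross-species footprinting on a
panel of related genomes: every species carries the same ordered set of
orthologous genes (gene structures re-drawn per species, sequence i.i.d.
from the background), a configurable fraction of reference genes are
designated true targets, and each target's ortholog independently receives
one planted binding site per motif — in the upstream intergenic region or a
random intron — with probability ``conservation_prob``.  Conservation is
thus modeled directly by the planting probability rather than by simulated
sequence evolution, matching the pipeline's alignment-free conservation
features.

Planted sites never overlap one another or exon boundaries, so truth labels
stay unambiguous; site orientation is randomized to exercise both strands.
Identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .features import OrthologMap
from .motifs import ALPHABET, Motif, motif_from_consensus
from .signatures import GeneBattery

FIDELITY = {"high": 0.95, "medium": 0.85, "low": 0.70}


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for :func:`generate_world`.

    Defaults model the desk-scale version of an eight-genome panel: 2000
    orthologous genes per species, 2.5% designated true targets (50 genes),
    per-species planting probability 0.9 and high-fidelity sites.  Length
    samplers (uniform, bp) loosely follow compact nematode-like gene
    structure: 1-3 exons of 100-300 bp, introns of 60-200 bp, intergenic
    stretches of 300-800 bp.
    """

    n_species: int = 8
    n_genes: int = 2000
    positive_fraction: float = 0.025
    conservation_prob: float = 0.9
    signal_strength: str = "high"
    background_letter_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    exon_count_range: tuple[int, int] = (1, 3)  # inclusive
    exon_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (60, 200)
    intergenic_length_range: tuple[int, int] = (300, 800)
    strand_mode: str = "plus"  # "plus" or "random"
    species_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 20:
            raise SimulationError("n_genes must be >= 20")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise SimulationError("positive_fraction must be in [0, 1]")
        if not 0.0 <= self.conservation_prob <= 1.0:
            raise SimulationError("conservation_prob must be in [0, 1]")
        if self.signal_strength not in FIDELITY:
            raise SimulationError(f"signal_strength must be one of {sorted(FIDELITY)}")
        if abs(sum(self.background_letter_freqs) - 1.0) > 1e-6:
            raise SimulationError("background letter frequencies must sum to 1")
        if self.strand_mode not in ("plus", "random"):
            raise SimulationError("strand_mode must be 'plus' or 'random'")

    @property
    def species(self) -> list[str]:
        if self.species_names is not None:
            if len(self.species_names) != self.n_species:
                raise SimulationError("species_names length != n_species")
            return list(self.species_names)
        return [f"s{i + 1:02d}" for i in range(self.n_species)]

    @property
    def reference(self) -> str:
        return self.species[0]


@dataclass
class World:
    """An in-memory synthetic study: genomes, gene models, ortholog map,
    planted-site truth table and the designated target genes."""

    cfg: SimConfig
    motifs: list[Motif]
    species: list[str]
    reference: str
    sequences: dict[str, dict[str, str]]  # species -> {sequence_id: sequence}
    genes: dict[str, list[GeneModel]]
    ortholog_map: OrthologMap
    truth: pd.DataFrame
    targets: list[str]  # reference gene ids

    @property
    def seq_lengths(self) -> dict[str, dict[str, int]]:
        return {
            sp: {sid: len(s) for sid, s in seqs.items()}
            for sp, seqs in self.sequences.items()
        }


def demo_motifs(n: int = 2) -> list[Motif]:
    """Deterministic high-information demo motifs (width 12, sharp columns)."""
    consensuses = ["TGCATAACGTCA", "CCGGATTGTGAC", "ATCGGCTAATGC"]
    if n > len(consensuses):
        raise SimulationError(f"at most {len(consensuses)} demo motifs available")
    return [
        motif_from_consensus(c, motif_id=f"demo{i + 1}", p_consensus=0.97)
        for i, c in enumerate(consensuses[:n])
    ]


def _sample_site(motif: Motif, fidelity: float, rng: np.random.Generator) -> str:
    letters = []
    for row in motif.prob_matrix:
        cons = int(row.argmax())
        if rng.random() < fidelity:
            letters.append(cons)
        else:
            off = row.copy()
            off[cons] = 0.0
            if off.sum() <= 0:
                off = np.ones(4)
                off[cons] = 0.0
            letters.append(int(rng.choice(4, p=off / off.sum())))
    return "".join(ALPHABET[b] for b in letters)


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_RC[c] for c in reversed(s))


def generate_world(cfg: SimConfig, motif: Motif | list[Motif]) -> World:
    """Generate the multi-species study world.

    ``motif`` may be a single motif or a list; every motif is planted into
    the same designated target genes (at non-overlapping positions), which
    makes multi-motif worlds usable as cofactor fixtures.
    """
    motifs = [motif] if isinstance(motif, Motif) else list(motif)
    if not motifs:
        raise SimulationError("at least one motif is required")
    max_w = max(m.width for m in motifs)
    min_region = min(cfg.intergenic_length_range[0], cfg.intron_length_range[0])
    if max_w + 2 > min_region:
        raise SimulationError(
            f"motif width {max_w} does not fit the configured region lengths"
        )
    rng = np.random.default_rng(cfg.seed)
    species = cfg.species
    fidelity = FIDELITY[cfg.signal_strength]
    bg = np.asarray(cfg.background_letter_freqs)
    uniform_bg = np.allclose(bg, 0.25)

    n_pos = int(round(cfg.n_genes * cfg.positive_fraction))
    target_idx = set(
        int(i) for i in rng.choice(cfg.n_genes, size=n_pos, replace=False)
    )
    if cfg.strand_mode == "plus":
        strands = ["+"] * cfg.n_genes
    else:
        strands = ["+" if rng.random() < 0.5 else "-" for _ in range(cfg.n_genes)]

    sequences: dict[str, dict[str, str]] = {}
    genes: dict[str, list[GeneModel]] = {}
    truth_rows: list[dict] = []
    entries: dict[str, dict[str, str]] = {}
    ref_ids: list[str] = []

    for sp in species:
        seq_id = f"{sp}_chr1"
        ig_lo, ig_hi = cfg.intergenic_length_range
        ex_lo, ex_hi = cfg.exon_length_range
        in_lo, in_hi = cfg.intron_length_range
        nex_lo, nex_hi = cfg.exon_count_range

        gene_models: list[GeneModel] = []
        cursor = 0
        ig_spans: list[tuple[int, int]] = []  # intergenic segment before gene j
        for j in range(cfg.n_genes):
            ig_len = int(rng.integers(ig_lo, ig_hi + 1))
            ig_spans.append((cursor, cursor + ig_len))
            cursor += ig_len
            n_ex = int(rng.integers(nex_lo, nex_hi + 1))
            exons: list[tuple[int, int]] = []
            pos = cursor
            for e in range(n_ex):
                if e > 0:
                    pos += int(rng.integers(in_lo, in_hi + 1))
                ex_len = int(rng.integers(ex_lo, ex_hi + 1))
                exons.append((pos, pos + ex_len))
                pos += ex_len
            span = (cursor, pos)
            cursor = pos
            gid = f"{sp}_g{j:05d}"
            strand = strands[j]
            tss = span[0] if strand == "+" else span[1] - 1
            gene_models.append(
                GeneModel(
                    gene_id=gid,
                    species=sp,
                    sequence_id=seq_id,
                    strand=strand,
                    tss=tss,
                    span=span,
                    exons=exons,
                )
            )
        trailing = int(rng.integers(ig_lo, ig_hi + 1))
        ig_spans.append((cursor, cursor + trailing))
        total = cursor + trailing

        if uniform_bg:
            codes = rng.integers(0, 4, size=total, dtype=np.int8)
        else:
            codes = rng.choice(4, size=total, p=bg).astype(np.int8)
        seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].copy()

        # plant sites into target genes
        for j in sorted(target_idx):
            g = gene_models[j]
            used: list[tuple[int, int]] = []
            for m in motifs:
                if rng.random() >= cfg.conservation_prob:
                    continue
                introns = g.introns
                if introns and rng.random() < 0.5:
                    region = introns[int(rng.integers(0, len(introns)))]
                    compartment = "intron"
                else:
                    # upstream intergenic segment of gene j
                    region = ig_spans[j] if g.strand == "+" else ig_spans[j + 1]
                    compartment = "upstream"
                a, b = region
                site = _sample_site(m, fidelity, rng)
                orientation = "+" if rng.random() < 0.5 else "-"
                planted = site if orientation == "+" else _revcomp(site)
                start = None
                for _ in range(100):
                    cand = int(rng.integers(a, b - m.width + 1))
                    if all(
                        cand + m.width <= u0 or cand >= u1 for u0, u1 in used
                    ):
                        start = cand
                        break
                if start is None:
                    continue  # region saturated; skip rather than overlap
                used.append((start, start + m.width))
                seq[start : start + m.width] = np.frombuffer(
                    planted.encode(), dtype=np.uint8
                )
                truth_rows.append(
                    {
                        "gene_id": f"{species[0]}_g{j:05d}",
                        "species": sp,
                        "species_gene_id": g.gene_id,
                        "sequence_id": seq_id,
                        "start": start,
                        "end": start + m.width,
                        "strand": orientation,
                        "compartment": compartment,
                        "motif_id": m.id,
                    }
                )

        sequences[sp] = {seq_id: seq.tobytes().decode("ascii")}
        genes[sp] = gene_models

    for j in range(cfg.n_genes):
        ref = f"{species[0]}_g{j:05d}"
        ref_ids.append(ref)
        entries[ref] = {sp: f"{sp}_g{j:05d}" for sp in species}

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id",
            "species",
            "species_gene_id",
            "sequence_id",
            "start",
            "end",
            "strand",
            "compartment",
            "motif_id",
        ],
    )
    omap = OrthologMap(
        reference_species=species[0], species=list(species), entries=entries
    )
    return World(
        cfg=cfg,
        motifs=motifs,
        species=list(species),
        reference=species[0],
        sequences=sequences,
        genes=genes,
        ortholog_map=omap,
        truth=truth,
        targets=[f"{species[0]}_g{j:05d}" for j in sorted(target_idx)],
    )


def generate_batteries(
    targets: list[str],
    gene_pool: list[str],
    size: int | tuple[int, int],
    target_fraction: float,
    n_batteries: int,
    seed: int,
    label_prefix: str = "batt",
) -> list[GeneBattery]:
    """Sample batteries mixing target and background genes.

    ``size`` is a fixed battery size or an inclusive (low, high) range
    sampled per battery.  Each battery draws ``round(size *
    target_fraction)`` target genes and the rest from the non-target pool,
    without replacement within a battery.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise SimulationError("target_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    target_arr = np.asarray(sorted(targets), dtype=object)
    background = np.asarray(
        sorted(set(gene_pool) - set(targets)), dtype=object
    )
    batteries: list[GeneBattery] = []
    for i in range(n_batteries):
        if isinstance(size, tuple):
            n = int(rng.integers(size[0], size[1] + 1))
        else:
            n = int(size)
        n_t = int(round(n * target_fraction))
        n_b = n - n_t
        if n_t > len(target_arr) or n_b > len(background):
            raise SimulationError(
                f"battery size {n} (targets {n_t}) exceeds the available pools"
            )
        chosen: list[str] = []
        if n_t:
            chosen.extend(rng.choice(target_arr, size=n_t, replace=False))
        if n_b:
            chosen.extend(rng.choice(background, size=n_b, replace=False))
        batteries.append(
            GeneBattery(
                label=f"{label_prefix}{i:04d}_f{target_fraction:g}",
                genes=frozenset(chosen),
                source="synthetic",
            )
        )
    return batteries


# ---------------------------------------------------------------------------
# File emission (the exact dialects the pipeline consumes)
# ---------------------------------------------------------------------------


def write_world(world: World, outdir: str | Path) -> None:
    """Emit per-species FASTA + GFF3, the ortholog map, the truth table and
    the target list under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp in world.species:
        with open(outdir / f"{sp}.fa", "w") as fh:
            for seq_id, seq in world.sequences[sp].items():
                fh.write(f">{seq_id}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        with open(outdir / f"{sp}.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for g in world.genes[sp]:
                s, e = g.span
                attrs = f"ID={g.gene_id};gene_biotype=protein_coding"
                fh.write(
                    f"{g.sequence_id}\tsim\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                tid = f"{g.gene_id}.t1"
                fh.write(
                    f"{g.sequence_id}\tsim\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={tid};Parent={g.gene_id}\n"
                )
                for k, (a, b) in enumerate(g.exons, 1):
                    fh.write(
                        f"{g.sequence_id}\tsim\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                        f"ID={tid}.e{k};Parent={tid}\n"
                    )
    omap_frame = world.ortholog_map.to_frame()
    omap_frame.reindex(columns=world.species).to_csv(
        outdir / "orthologs.tsv", sep="\t", index=False
    )
    world.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    (outdir / "targets.txt").write_text("\n".join(world.targets) + "\n")
    (outdir / "species.txt").write_text("\n".join(world.species) + "\n")


def write_batteries(batteries: list[GeneBattery], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("battery_label\tgene_id\n")
        for b in batteries:
            for g in sorted(b.genes):
                fh.write(f"{b.label}\t{g}\n")
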