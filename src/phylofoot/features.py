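"""Cross-species motif feature vectors for reference genes.

Per reference gene and per species the scoring compartments (upstream,
intron) contribute six features — match count, maximum score and mean score
for each compartment — plus two panel-wide conservation counts: the number
of species whose ortholog carries at least one upstream (respectively
intronic) match.  With S species that is 6*S + 2 features per gene.
Conservation is alignment-free: features depend only on per-species match
counts and scores, never on match coordinates.

Species without an ortholog (or whose ortholog has no matches) contribute
all-zero features and do not count toward conservation; zero therefore
conflates "no ortholog" with "ortholog without matches", a documented
limitation of the dense encoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotation import AssignedMatch


class OrthologMapError(ValueError):
    """Raised for malformed ortholog tables."""


@dataclass
class OrthologMap:
    """reference gene id -> {species: ortholog gene id} (reference included)."""

    reference_species: str
    species: list[str]
    entries: dict[str, dict[str, str]]

    def reverse_index(self, species: str) -> dict[str, str]:
        """ortholog gene id in ``species`` -> reference gene id."""
        return {
            orthologs[species]: ref
            for ref, orthologs in self.entries.items()
            if species in orthologs
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ref_gene": ref, **orthologs} for ref, orthologs in self.entries.items()
        ]
        return pd.DataFrame(rows).set_index("ref_gene")


def load_ortholog_map(path: str | Path, species_panel: list[str]) -> OrthologMap:
    """Load a tab-separated ortholog table (header = species names, first
    panel species = reference; empty cell = no ortholog)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise OrthologMapError(f"{path}: zero ortholog entries")
    unknown = [c for c in df.columns if c not in species_panel]
    if unknown:
        raise OrthologMapError(
            f"{path}: species column(s) {unknown} not in the configured panel"
        )
    reference = species_panel[0]
    if reference not in df.columns:
        raise OrthologMapError(f"{path}: missing reference species column {reference!r}")
    if df[reference].duplicated().any():
        dup = df[reference][df[reference].duplicated()].iloc[0]
        raise OrthologMapError(f"{path}: duplicate reference gene id {dup!r}")
    entries: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        ref = row[reference]
        orthologs = {reference: ref}
        for sp in species_panel[1:]:
            if sp in df.columns:
                val = row[sp]
                if isinstance(val, str) and val.strip() not in ("", "-", "."):
                    orthologs[sp] = val.strip()
        entries[ref] = orthologs
    return OrthologMap(reference_species=reference, species=list(species_panel), entries=entries)


_COMPARTMENT_TAG = {"upstream": "up", "intron": "in"}


def feature_columns(species: list[str]) -> list[str]:
    """Canonical feature-column order for a species panel."""
    cols = []
    for sp in species:
        for tag in ("upFreq", "inFreq", "upMax", "inMax", "upAvg", "inAvg"):
            cols.append(f"f_{sp}_{tag}")
    return cols + ["up_cons", "in_cons"]


def _matches_frame(
    matches_by_species: dict[str, list[AssignedMatch]], omap: OrthologMap
) -> pd.DataFrame:
    rows = []
    for sp, matches in matches_by_species.items():
        rev = omap.reverse_index(sp)
        for m in matches:
            if not m.scoring:
                continue
            ref = rev.get(m.gene_id)
            if ref is None:
                continue
            rows.append((ref, sp, _COMPARTMENT_TAG[m.compartment], m.hit.score))
    return pd.DataFrame(rows, columns=["ref_gene", "species", "comp", "score"])


def build_feature_table(
    omap: OrthologMap,
    matches_by_species: dict[str, list[AssignedMatch]],
) -> pd.DataFrame:
    """One feature row per reference gene with >= 1 scoring match in >= 1
    species (the candidate target-gene universe), ordered by gene id.

    The index is the reference gene id; columns follow
    :func:`feature_columns` for the map's species panel.
    """
    cols = feature_columns(omap.species)
    df = _matches_frame(matches_by_species, omap)
    if df.empty:
        return pd.DataFrame(columns=cols, index=pd.Index([], name="gene_id"))
    agg = (
        df.groupby(["ref_gene", "species", "comp"])["score"]
        .agg(freq="count", mx="max", avg="mean")
        .reset_index()
    )
    wide = agg.pivot(index="ref_gene", columns=["species", "comp"])
    table = pd.DataFrame(index=wide.index)
    for sp in omap.species:
        for comp in ("up", "in"):
            for stat, tag in (("freq", "Freq"), ("mx", "Max"), ("avg", "Avg")):
                key = (stat, sp, comp)
                col = f"f_{sp}_{comp}{tag}"
                table[col] = wide[key] if key in wide.columns else 0.0
    table = table.fillna(0.0)
    for comp in ("up", "in"):
        freq_cols = [f"f_{sp}_{comp}Freq" for sp in omap.species]
        table[f"{comp}_cons"] = (table[freq_cols] > 0).sum(axis=1).astype(float)
    table = table[cols].sort_index()
    table.index.name = "gene_id"
    return table


def extract_features(
    ref_gene: str,
    omap: OrthologMap,
    matches_by_species: dict[str, list[AssignedMatch]],
) -> pd.Series:
    """Feature vector for a single reference gene (all zeros when it has no
    scoring matches anywhere in the panel)."""
    if ref_gene not in omap.entries:
        raise OrthologMapError(f"unknown reference gene {ref_gene!r}")
    orthologs = omap.entries[ref_gene]
    restricted = {
        sp: [m for m in matches if m.gene_id == orthologs.get(sp)]
        for sp, matches in matches_by_species.items()
    }
    table = build_feature_table(omap, restricted)
    if ref_gene in table.index:
        return table.loc[ref_gene].rename(ref_gene)
    return pd.Series(0.0, index=feature_columns(omap.species), name=ref_gene)
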