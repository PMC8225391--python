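"""Tab-separated readers/writers for every pipeline artifact.

All tables are plain TSV with a header row; genomic coordinates in these
files are 1-based inclusive (converted from the 0-based half-open internal
convention).  Every reader validates the header schema so that re-reading
any written file reproduces the in-memory table exactly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotation import AssignedMatch
from .motifs import RawHit
from .signatures import GeneBattery

HIT_COLUMNS = [
    "motif_id",
    "sequence_id",
    "start",
    "end",
    "strand",
    "score",
    "p-value",
    "matched_sequence",
]
ASSIGNED_COLUMNS = HIT_COLUMNS + ["gene_id", "compartment", "distance_to_tss"]


class SchemaError(ValueError):
    """Raised when a file does not match the expected table schema."""


def _check_schema(df: pd.DataFrame, expected: list[str], path) -> None:
    if list(df.columns)[: len(expected)] != expected:
        raise SchemaError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )


def hits_frame(hits: list[RawHit], motif_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif_id": motif_id,
                "sequence_id": h.sequence_id,
                "start": h.start + 1,
                "end": h.end,
                "strand": h.strand,
                "score": round(h.score, 6),
                "p-value": h.pvalue,
                "matched_sequence": h.matched_seq,
            }
            for h in hits
        ],
        columns=HIT_COLUMNS,
    )


def write_hits(hits: list[RawHit], motif_id: str, path: str | Path) -> None:
    hits_frame(hits, motif_id).to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_schema(df, HIT_COLUMNS, path)
    return df


def assigned_frame(matches: list[AssignedMatch], motif_id: str) -> pd.DataFrame:
    rows = []
    for m in matches:
        h = m.hit
        rows.append(
            {
                "motif_id": motif_id,
                "sequence_id": h.sequence_id,
                "start": h.start + 1,
                "end": h.end,
                "strand": h.strand,
                "score": round(h.score, 6),
                "p-value": h.pvalue,
                "matched_sequence": h.matched_seq,
                "gene_id": m.gene_id,
                "compartment": m.compartment,
                "distance_to_tss": m.distance_to_tss,
            }
        )
    return pd.DataFrame(rows, columns=ASSIGNED_COLUMNS)


def write_assigned(
    matches: list[AssignedMatch], motif_id: str, path: str | Path
) -> None:
    assigned_frame(matches, motif_id).to_csv(path, sep="\t", index=False)


def read_assigned(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_schema(df, ASSIGNED_COLUMNS, path)
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def write_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """The per-gene summary: probability, rank, normalized_rank, features."""
    out = summary.reset_index().rename(columns={"index": "gene_id"})
    if "gene_id" not in out.columns:
        out = out.rename(columns={out.columns[0]: "gene_id"})
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_summary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_schema(df, ["gene_id", "probability", "rank", "normalized_rank"], path)
    return df.set_index("gene_id")


def write_cv_report(folds: pd.DataFrame, path: str | Path) -> None:
    folds.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cv_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_schema(df, ["repeat", "fold", "recall", "rank_sums_z"], path)
    return df


def read_batteries(path: str | Path, source: str = "file") -> list[GeneBattery]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_schema(df, ["battery_label", "gene_id"], path)
    return [
        GeneBattery(label=label, genes=frozenset(group["gene_id"]), source=source)
        for label, group in df.groupby("battery_label", sort=True)
    ]


def read_expression(path: str | Path) -> set[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_schema(df, ["tf_id", "battery_label"], path)
    return set(zip(df["tf_id"], df["battery_label"]))


def write_expression(pairs: set[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf_id\tbattery_label\n")
        for tf, label in sorted(pairs):
            fh.write(f"{tf}\t{label}\n")


def read_positives(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_run_metadata(path: str | Path, **params) -> None:
    with open(path, "w") as fh:
        for key in sorted(params):
            fh.write(f"{key}={params[key]}\n")
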