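"""DNA binding motifs, log-odds scoring matrices and sequence scanning.

A motif is a position probability matrix over A/C/G/T plus a 0-order
background model.  Scanning follows the standard log-odds scheme: each
window of motif width on either strand is scored as the sum of per-position
log2 odds of the observed letter versus the background.  Match p-values are
exact tail probabilities of the score distribution of a random background
word, computed by dynamic programming on an integer score lattice (the
matrix is discretized onto ``granularity`` bins, per-position score
distributions are convolved under the background letter probabilities, and
the tail sum of the resulting distribution maps every achievable score to
``P(score of a random word >= s)``).

Reported hit scores come from the same discretized matrix that the p-value
lattice uses, so score and p-value are exactly monotone in each other; the
discretization error of a reported score is below
``width * score_range / granularity`` bits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ENCODE_TABLE = np.full(256, -1, dtype=np.int8)
for _c, _i in _CODE.items():
    _ENCODE_TABLE[ord(_c)] = _i
    _ENCODE_TABLE[ord(_c.lower())] = _i


class MemeParseError(ValueError):
    """Raised when a MEME minimal motif file cannot be parsed."""


class MotifValidationError(ValueError):
    """Raised when motif probabilities violate the model's invariants."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0 C=1 G=2 T=3; others -> -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_TABLE[raw]


@dataclass(frozen=True)
class Motif:
    """A position probability matrix with background frequencies.

    ``prob_matrix`` is ``width x 4`` over A,C,G,T; each row sums to one.
    ``nsites`` is the number of aligned sites the matrix was estimated from
    (``None`` when the source file does not state it).
    """

    id: str
    width: int
    prob_matrix: np.ndarray
    background: np.ndarray
    alt_name: str = ""
    nsites: int | None = None

    def __post_init__(self) -> None:
        pm = np.asarray(self.prob_matrix, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "prob_matrix", pm)
        object.__setattr__(self, "background", bg)
        if pm.shape != (self.width, 4):
            raise MotifValidationError(
                f"motif {self.id}: matrix shape {pm.shape} != ({self.width}, 4)"
            )
        if (pm < 0).any() or (bg < 0).any():
            raise MotifValidationError(f"motif {self.id}: negative probability")
        if np.abs(pm.sum(axis=1) - 1.0).max() > 1e-6:
            raise MotifValidationError(f"motif {self.id}: rows do not sum to 1")
        if abs(bg.sum() - 1.0) > 1e-6:
            raise MotifValidationError(f"motif {self.id}: background does not sum to 1")

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[b] for b in self.prob_matrix.argmax(axis=1))


def motif_from_consensus(
    consensus: str,
    motif_id: str | None = None,
    p_consensus: float = 0.97,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    nsites: int | None = None,
) -> Motif:
    """Build a motif whose columns put ``p_consensus`` on the consensus letter
    and spread the remainder evenly over the other three letters."""
    consensus = consensus.upper()
    if not set(consensus) <= set(ALPHABET):
        raise MotifValidationError(f"consensus {consensus!r} has non-ACGT letters")
    off = (1.0 - p_consensus) / 3.0
    pm = np.full((len(consensus), 4), off)
    for i, c in enumerate(consensus):
        pm[i, _CODE[c]] = p_consensus
    return Motif(
        id=motif_id or consensus,
        width=len(consensus),
        prob_matrix=pm,
        background=np.asarray(background, dtype=float),
        nsites=nsites,
    )


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------

_FLOAT_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def _parse_background(tokens: list[str], lineno: int) -> np.ndarray:
    if len(tokens) % 2 != 0:
        raise MemeParseError(f"line {lineno}: malformed background frequency line")
    freqs = dict.fromkeys(ALPHABET, 0.25)
    for letter, value in zip(tokens[0::2], tokens[1::2]):
        if letter.upper() not in freqs:
            raise MemeParseError(f"line {lineno}: unknown background letter {letter!r}")
        freqs[letter.upper()] = float(value)
    return np.array([freqs[c] for c in ALPHABET])


def parse_meme(path: str | Path) -> list[Motif]:
    """Parse motifs from a MEME minimal text file, in file order.

    A missing background line defaults to the uniform distribution.  Rows of
    the letter-probability matrix deviating from a unit sum by at most 1e-3
    are renormalized; larger deviations raise :class:`MotifValidationError`.
    """
    lines = Path(path).read_text().splitlines()
    background = np.full(4, 0.25)
    motifs: list[Motif] = []
    saw_version = False
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.lower().startswith("meme version"):
            saw_version = True
        elif line.startswith("Background letter frequencies"):
            tokens: list[str] = []
            j = i + 1
            while j < n and lines[j].strip() and not lines[j].startswith(("MOTIF", "letter-")):
                tokens.extend(lines[j].split())
                j += 1
            background = _parse_background(tokens, i + 1)
            if abs(background.sum() - 1.0) > 1e-3:
                raise MotifValidationError(
                    f"line {i + 1}: background frequencies sum to {background.sum():g}"
                )
            background = background / background.sum()
            i = j - 1
        elif line.startswith("MOTIF"):
            fields = line.split()
            if len(fields) < 2:
                raise MemeParseError(f"line {i + 1}: MOTIF line without an identifier")
            motif_id = fields[1]
            alt = fields[2] if len(fields) > 2 else ""
            i += 1
            # seek the letter-probability header
            while i < n and not lines[i].strip().startswith("letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise MemeParseError(
                        f"line {i + 1}: motif {motif_id} has no letter-probability matrix"
                    )
                i += 1
            if i >= n:
                raise MemeParseError(
                    f"line {n}: motif {motif_id} has no letter-probability matrix"
                )
            header = lines[i].strip()
            attrs = dict(re.findall(r"(\w+)=\s*([-\w.+]+)", header))
            alength = int(attrs.get("alength", 4))
            if alength != 4:
                raise MemeParseError(f"line {i + 1}: alength={alength}, expected 4 (DNA)")
            declared_w = int(attrs["w"]) if "w" in attrs else None
            nsites = int(round(float(attrs["nsites"]))) if "nsites" in attrs else None
            rows: list[list[float]] = []
            i += 1
            while i < n:
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL", "letter-")):
                    break
                values = _FLOAT_RE.findall(stripped)
                if len(values) != len(stripped.split()):
                    break  # non-numeric line terminates the matrix
                if len(values) != 4:
                    raise MemeParseError(
                        f"line {i + 1}: expected 4 probabilities, found {len(values)}"
                    )
                rows.append([float(v) for v in values])
                i += 1
                if declared_w is not None and len(rows) == declared_w:
                    break
            i -= 1
            if declared_w is not None and len(rows) != declared_w:
                raise MemeParseError(
                    f"line {i + 1}: motif {motif_id} declares w={declared_w} "
                    f"but has {len(rows)} matrix rows"
                )
            if not rows:
                raise MemeParseError(f"line {i + 1}: motif {motif_id} has an empty matrix")
            pm = np.array(rows)
            sums = pm.sum(axis=1)
            dev = np.abs(sums - 1.0)
            if dev.max() > 1e-3:
                bad = int(dev.argmax())
                raise MotifValidationError(
                    f"motif {motif_id}: matrix row {bad + 1} sums to {sums[bad]:.6f} "
                    "(deviates from 1 by more than 1e-3)"
                )
            pm = pm / sums[:, None]
            motifs.append(
                Motif(
                    id=motif_id,
                    alt_name=alt,
                    width=pm.shape[0],
                    prob_matrix=pm,
                    background=background.copy(),
                    nsites=nsites,
                )
            )
        i += 1
    if not saw_version:
        raise MemeParseError("line 1: missing 'MEME version' header")
    if not motifs:
        raise MemeParseError("file contains no MOTIF blocks")
    return motifs


def write_meme(motifs: Iterable[Motif], path: str | Path) -> None:
    """Write motifs in MEME minimal text format (uniform-background header
    comes from the first motif's background)."""
    motifs = list(motifs)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{c} {f:.5f}" for c, f in zip(ALPHABET, bg)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.id} {m.alt_name}".rstrip() + "\n")
            ns = f" nsites= {m.nsites}" if m.nsites is not None else ""
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width}{ns}\n")
            for row in m.prob_matrix:
                fh.write(" " + "  ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# PSSM construction and the score p-value lattice
# ---------------------------------------------------------------------------


@dataclass
class Pssm:
    """Log-odds scoring matrix with an exact score -> p-value mapping.

    ``logodds`` holds log2 odds in bits.  ``int_matrix`` is the discretized
    matrix (per-row minimum mapped to 0) on a lattice of bin width ``eps``
    bits; ``tail[k]`` is the probability that a random background word scores
    at least ``k`` lattice units above the minimum achievable score
    ``offset``.
    """

    motif_id: str
    width: int
    logodds: np.ndarray
    background: np.ndarray
    pseudocount: float
    granularity: int
    eps: float = field(init=False)
    offset: float = field(init=False)
    int_matrix: np.ndarray = field(init=False)
    tail: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        lo = np.asarray(self.logodds, dtype=float)
        row_min = lo.min(axis=1)
        row_max = lo.max(axis=1)
        self.offset = float(row_min.sum())
        score_range = float((row_max - row_min).sum())
        self.eps = score_range / self.granularity if score_range > 0 else 1.0
        self.int_matrix = np.rint((lo - row_min[:, None]) / self.eps).astype(np.int64)
        # exact distribution of the discretized score of a random word
        max_int = int(self.int_matrix.max(axis=1).sum())
        pmf = np.zeros(max_int + 1)
        pmf[0] = 1.0
        top = 0
        for i in range(self.width):
            new = np.zeros(max_int + 1)
            row = self.int_matrix[i]
            for b in range(4):
                p = self.background[b]
                if p > 0:
                    s = int(row[b])
                    new[s : s + top + 1] += p * pmf[: top + 1]
            top += int(row.max())
            pmf = new
        self.tail = np.cumsum(pmf[::-1])[::-1]
        self.tail[0] = 1.0  # guard against round-off; P(S >= min) is 1 by definition

    # -- score bookkeeping ---------------------------------------------------

    @property
    def max_score(self) -> float:
        """Maximum achievable score: the sum of row maxima of ``logodds``."""
        return float(self.logodds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.logodds.min(axis=1).sum())

    def score_of_lattice(self, k: int | np.ndarray) -> np.ndarray:
        return self.offset + np.asarray(k) * self.eps

    def pvalue_of_lattice(self, k: int | np.ndarray) -> np.ndarray:
        idx = np.clip(np.asarray(k, dtype=np.int64), 0, len(self.tail) - 1)
        return self.tail[idx]

    def pvalue_of_score(self, score: float) -> float:
        """p-value of a score in bits (mapped to the nearest lattice bin)."""
        k = int(round((score - self.offset) / self.eps))
        return float(self.pvalue_of_lattice(k))

    def score_word(self, word: str) -> tuple[float, float]:
        """(score, p-value) of a single width-length word; NaN score for
        words containing non-ACGT letters."""
        codes = encode_sequence(word)
        if len(codes) != self.width or (codes < 0).any():
            return float("nan"), 1.0
        k = int(self.int_matrix[np.arange(self.width), codes].sum())
        return float(self.score_of_lattice(k)), float(self.pvalue_of_lattice(k))


def build_pssm(
    motif: Motif, pseudocount: float = 0.1, granularity: int = 1000
) -> Pssm:
    """Build a log-odds PSSM with background-weighted pseudocount smoothing.

    With a known site count ``n`` the smoothed probability of letter ``b`` at
    position ``i`` is ``(p[i,b]*n + pc*bg[b]) / (n + pc)``; without one the
    matrix itself is smoothed as ``(p[i,b] + pc*bg[b]) / (1 + pc)``.  Scores
    are ``log2(smoothed / bg)`` in bits.
    """
    if pseudocount <= 0:
        raise MotifValidationError("pseudocount must be > 0")
    if granularity < 100:
        raise MotifValidationError("granularity must be >= 100")
    bg = motif.background
    present = motif.prob_matrix.max(axis=0) > 0
    if (bg[present] == 0).any():
        bad = ALPHABET[int(np.nonzero(present & (bg == 0))[0][0])]
        raise MotifValidationError(
            f"motif {motif.id}: background frequency of {bad} is zero but the "
            "letter occurs in the motif"
        )
    if motif.nsites:
        smoothed = (motif.prob_matrix * motif.nsites + pseudocount * bg) / (
            motif.nsites + pseudocount
        )
    else:
        smoothed = (motif.prob_matrix + pseudocount * bg) / (1.0 + pseudocount)
    safe_bg = np.where(bg > 0, bg, 1.0)
    logodds = np.log2(np.where(bg > 0, smoothed / safe_bg, 0.0))
    return Pssm(
        motif_id=motif.id,
        width=motif.width,
        logodds=logodds,
        background=bg,
        pseudocount=pseudocount,
        granularity=granularity,
    )


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RawHit:
    """A scored motif match on a genomic sequence.

    Coordinates are 0-based half-open; ``matched_seq`` is the scanned window,
    reverse-complemented for minus-strand hits so it always reads in motif
    orientation.
    """

    sequence_id: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float
    matched_seq: str


def _window_int_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    width = matrix.shape[0]
    n_win = len(codes) - width + 1
    total = np.zeros(n_win, dtype=np.int64)
    safe = np.clip(codes, 0, 3)
    for i in range(width):
        total += matrix[i][safe[i : i + n_win]]
    return total


def scan_sequence(
    pssm: Pssm, sequence_id: str, sequence: str, p_threshold: float
) -> list[RawHit]:
    """Score every width-length window on both strands; return hits with
    p-value <= ``p_threshold`` sorted by start (then + before -).

    Windows containing any non-ACGT letter are skipped.  A sequence shorter
    than the motif yields an empty list.
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    w = pssm.width
    codes = encode_sequence(sequence)
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return []
    bad = (codes < 0).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(bad)])
    clean = (cum[w:] - cum[:-w]) == 0

    hits: list[RawHit] = []
    rc_matrix = pssm.int_matrix[::-1, ::-1]
    for strand, matrix in (("+", pssm.int_matrix), ("-", rc_matrix)):
        ints = _window_int_scores(codes, matrix)
        pvals = pssm.pvalue_of_lattice(ints)
        keep = clean & (pvals <= p_threshold)
        for idx in np.nonzero(keep)[0]:
            start = int(idx)
            window = sequence[start : start + w].upper()
            hits.append(
                RawHit(
                    sequence_id=sequence_id,
                    start=start,
                    end=start + w,
                    strand=strand,
                    score=float(pssm.score_of_lattice(int(ints[idx]))),
                    pvalue=float(pvals[idx]),
                    matched_seq=window if strand == "+" else reverse_complement(window),
                )
            )
    hits.sort(key=lambda h: (h.start, 0 if h.strand == "+" else 1))
    return hits


def brute_force_scan(
    pssm: Pssm, sequence_id: str, sequence: str, p_threshold: float
) -> list[RawHit]:
    """Reference window scorer: scores each window by a per-letter Python
    loop over the discretized matrix.  Independent of the vectorized scan
    path; intended for cross-checks on short sequences."""
    w = pssm.width
    hits: list[RawHit] = []
    seq = sequence.upper()
    for start in range(len(seq) - w + 1):
        window = seq[start : start + w]
        if any(c not in _CODE for c in window):
            continue
        for strand, word in (("+", window), ("-", reverse_complement(window))):
            k = sum(pssm.int_matrix[i][_CODE[c]] for i, c in enumerate(word))
            pv = float(pssm.pvalue_of_lattice(int(k)))
            if pv <= p_threshold:
                hits.append(
                    RawHit(
                        sequence_id=sequence_id,
                        start=start,
                        end=start + w,
                        strand=strand,
                        score=float(pssm.score_of_lattice(int(k))),
                        pvalue=pv,
                        matched_seq=word,
                    )
                )
    hits.sort(key=lambda h: (h.start, 0 if h.strand == "+" else 1))
    return hits
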