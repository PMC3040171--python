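"""Genomic data model, readers/writers for standard flat formats, interval algebra.

Coordinates are 0-based half-open throughout (BED-native). The 5' position of a
minus-strand read is its *rightmost* base, i.e. ``end - 1`` in BED terms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from intervaltree import IntervalTree

VALID_BASES = set("ACGTN")
BASE_ORDER = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


class ParseError(ValueError):
    """Malformed input file; message names the offending line/position."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read, reduced to its 5' coordinate and strand."""

    chrom: str
    pos5: int
    strand: str
    read_len: int

    def __post_init__(self):
        if self.pos5 < 0:
            raise ValueError("pos5 must be >= 0")
        if self.read_len <= 0:
            raise ValueError("read_len must be > 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read strand must be +/- (got {self.strand!r})")


class MappabilityProfile:
    """Per-chromosome sorted, disjoint mappable intervals.

    The complement of the profile is the non-mappable space. Intervals are
    normalized (sorted, overlapping/adjacent runs merged) on construction.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._by_chrom: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._by_chrom[chrom] = np.asarray(merged, dtype=np.int64)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def intervals(self, chrom: str) -> np.ndarray:
        """(n, 2) array of [start, end) mappable intervals for chrom."""
        return self._by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    def gaps_within(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Non-mappable sub-intervals of [start, end), as an (n, 2) array.

        A chromosome absent from the profile is treated as fully mappable:
        profiles are typically provided only for regions of interest, and an
        empty profile must behave as "no correction".
        """
        ivs = self._by_chrom.get(chrom)
        if ivs is None or len(ivs) == 0:
            return np.empty((0, 2), dtype=np.int64)
        gaps = []
        cur = start
        for s, e in ivs:
            if e <= start:
                continue
            if s >= end:
                break
            if s > cur:
                gaps.append((cur, min(s, end)))
            cur = max(cur, e)
        if cur < end:
            gaps.append((cur, end))
        return np.asarray(gaps, dtype=np.int64) if gaps else np.empty((0, 2), dtype=np.int64)

    def is_mappable(self, chrom: str, pos: int) -> bool:
        ivs = self._by_chrom.get(chrom)
        if ivs is None or len(ivs) == 0:
            return True
        i = np.searchsorted(ivs[:, 0], pos, side="right") - 1
        return i >= 0 and pos < ivs[i, 1]


@dataclass
class SequenceRecord:
    id: str
    seq: str
    origin: GenomicInterval | None = None
    clipped: bool = False  # True when the window ran off a chromosome end

    def __post_init__(self):
        self.seq = self.seq.upper()
        if len(self.seq) == 0:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ParseError(
                f"record {self.id!r}: non-IUPAC character {self.seq[pos]!r} at position {pos}"
            )
        if self.origin is not None and len(self.origin) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: origin length {len(self.origin)} != sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# BED reads
# ---------------------------------------------------------------------------

def read_reads(path: str | Path, dialect: str = "bed") -> list[AlignedRead]:
    """Read aligned reads from a 6-column BED file.

    For + reads pos5 = BED start; for − reads pos5 = BED end − 1.
    """
    if dialect != "bed":
        raise ValueError(f"unsupported dialect {dialect!r}")
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, s, e, _name, _score, strand = fields[:6]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: read strand must be + or -, got {strand!r}")
            pos5 = start if strand == "+" else end - 1
            reads.append(AlignedRead(chrom, pos5, strand, end - start))
    return reads


def write_reads(reads: Sequence[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            if r.strand == "+":
                start, end = r.pos5, r.pos5 + r.read_len
            else:
                start, end = r.pos5 - r.read_len + 1, r.pos5 + 1
            fh.write(f"{r.chrom}\t{start}\t{end}\tr{i}\t0\t{r.strand}\n")


def write_intervals(intervals: Sequence[GenomicInterval], path: str | Path,
                    names: Sequence[str] | None = None,
                    scores: Sequence[float] | None = None) -> None:
    """Write intervals as BED6."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED (3+ columns) as GenomicIntervals; strand taken from column 6 if present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_ORIGIN_RE = re.compile(r"^(\S+):(\d+)-(\d+)\(([+\-.])\)$")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; headers ``id`` or ``id chrom:start-end(strand)`` carry genome origin."""
    records: list[SequenceRecord] = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            parts = title.split(None, 1)
            rec_id = parts[0] if parts else ""
            if not rec_id:
                raise ParseError(f"{path}: FASTA record with empty header")
            origin = None
            if len(parts) > 1:
                m = _ORIGIN_RE.match(parts[1].strip())
                if m:
                    origin = GenomicInterval(m.group(1), int(m.group(2)), int(m.group(3)), m.group(4))
            if not seq:
                raise ParseError(f"{path}: record {rec_id!r} has no sequence")
            records.append(SequenceRecord(rec_id, seq, origin=origin))
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.origin is not None:
                o = rec.origin
                header += f" {o.chrom}:{o.start}-{o.end}({o.strand})"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def extract_windows(genome: Sequence[SequenceRecord], centers: Sequence[tuple[str, int]],
                    width: int) -> list[SequenceRecord]:
    """Extract fixed-width windows centered on (chrom, pos) positions.

    Windows clipped at chromosome ends are padded with N and flagged.
    """
    if width % 2 != 0:
        raise ValueError("width must be even")
    chrom_seq = {rec.id: rec.seq for rec in genome}
    half = width // 2
    out: list[SequenceRecord] = []
    for i, (chrom, pos) in enumerate(centers):
        if chrom not in chrom_seq:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        seq = chrom_seq[chrom]
        lo, hi = pos - half, pos + half
        left_pad = max(0, -lo)
        right_pad = max(0, hi - len(seq))
        window = "N" * left_pad + seq[max(0, lo) : min(hi, len(seq))] + "N" * right_pad
        origin = None
        if left_pad == 0 and right_pad == 0:
            origin = GenomicInterval(chrom, lo, hi)
        out.append(SequenceRecord(f"win{i}_{chrom}_{pos}", window, origin=origin,
                                  clipped=left_pad > 0 or right_pad > 0))
    return out


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def count_overlaps(query: Sequence[GenomicInterval],
                   subject: Sequence[GenomicInterval]) -> list[int]:
    """Per query interval, number of subject intervals sharing >= 1 bp (strand ignored)."""
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(subject):
        # unique payload: duplicated subject intervals must each count
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    counts = []
    for q in query:
        tree = trees.get(q.chrom)
        counts.append(len(tree.overlap(q.start, q.end)) if tree is not None else 0)
    return counts


# ---------------------------------------------------------------------------
# PWM flat formats (TRANSFAC and JASPAR)
# ---------------------------------------------------------------------------

def _normalize_counts(counts: np.ndarray, pseudocount: float, name: str) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ParseError(f"motif {name!r}: expected a 4 x w count matrix")
    if np.any(counts < 0):
        raise ParseError(f"motif {name!r}: negative count")
    col_sums = counts.sum(axis=0)
    if np.any(col_sums == 0):
        j = int(np.argmax(col_sums == 0))
        raise ParseError(f"motif {name!r}: column {j} has all-zero counts")
    probs = (counts + pseudocount) / (col_sums + 4.0 * pseudocount)
    return probs


def read_transfac(path: str | Path, pseudocount: float = 0.25):
    """Read TRANSFAC-format count matrices, normalized to pseudocounted PWMs."""
    from .pwm import PWM  # local import: pwm depends on core_io types

    pwms = []
    name = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tag = line[:2]
            if tag == "ID" or tag == "DE":
                name = line[2:].strip() or name
            elif tag == "P0" or tag == "PO":
                rows = []
            elif tag == "XX":
                continue
            elif line.strip() == "//":
                if rows:
                    counts = np.asarray(rows, dtype=float).T  # rows are positions
                    pwms.append(PWM(name or f"motif{len(pwms)+1}",
                                    _normalize_counts(counts, pseudocount, name or "?"),
                                    source="database"))
                name, rows = None, []
            elif line[:2].strip().isdigit():
                fields = line.split()
                try:
                    vals = [float(x) for x in fields[1:5]]
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}:{lineno}: malformed TRANSFAC count row") from exc
                if len(vals) != 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 counts (A C G T)")
                rows.append(vals)
    if rows:  # trailing block without //
        counts = np.asarray(rows, dtype=float).T
        pwms.append(PWM(name or f"motif{len(pwms)+1}",
                        _normalize_counts(counts, pseudocount, name or "?"), source="database"))
    return pwms


def write_transfac(pwms, path: str | Path, scale: float = 1e10) -> None:
    """Write PWMs as TRANSFAC count blocks.

    Probabilities are written as counts at a large fixed scale so that reading
    them back (with the default pseudocount) reproduces the probabilities to
    better than 1e-9.
    """
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID {pwm.name}\nXX\nP0      A      C      G      T\n")
            for j in range(pwm.width):
                vals = "  ".join(f"{pwm.probs[i, j] * scale:.6f}" for i in range(4))
                fh.write(f"{j + 1:02d}  {vals}\n")
            fh.write("XX\n//\n")


def read_jaspar(path: str | Path, pseudocount: float = 0.25):
    """Read JASPAR flat format: ``>name`` then 4 base rows ``A [ counts ]``."""
    from .pwm import PWM

    pwms = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise ParseError(f"{path}:{i + 1}: expected '>' header, got {line!r}")
        name = line[1:].split()[0] if line[1:].split() else f"motif{len(pwms)+1}"
        rows = {}
        for k in range(4):
            if i + 1 + k >= len(lines):
                raise ParseError(f"{path}:{i + 1}: truncated JASPAR block {name!r}")
            row = lines[i + 1 + k].strip()
            m = re.match(r"^([ACGT])\s*\[?\s*([^\]]*?)\s*\]?\s*$", row)
            if not m:
                raise ParseError(f"{path}:{i + 2 + k}: malformed JASPAR base row")
            try:
                rows[m.group(1)] = [float(x) for x in m.group(2).split()]
            except ValueError as exc:
                raise ParseError(f"{path}:{i + 2 + k}: non-numeric count") from exc
        widths = {len(v) for v in rows.values()}
        if len(rows) != 4 or len(widths) != 1:
            raise ParseError(f"{path}: motif {name!r}: ragged or missing base rows")
        counts = np.asarray([rows[b] for b in BASE_ORDER], dtype=float)
        pwms.append(PWM(name, _normalize_counts(counts, pseudocount, name), source="database"))
        i += 5
    return pwms


def write_jaspar(pwms, path: str | Path, scale: float = 1e10) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for i, base in enumerate(BASE_ORDER):
                vals = " ".join(f"{pwm.probs[i, j] * scale:.6f}" for j in range(pwm.width))
                fh.write(f"{base} [ {vals} ]\n")
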