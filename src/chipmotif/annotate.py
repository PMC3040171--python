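"""Motif post-processing: database matching with calibrated similarity
E-values, filtering, virtual combining, and distance-distribution statistics.

Similarity of two PWMs is the best ungapped alignment (all offsets with at
least ``MIN_OVERLAP`` aligned columns, both target orientations) under a
per-column metric (Pearson correlation of probability columns by default,
ALLR available). E-values are calibrated against simulated null profiles:
alignment scores of column-shuffled database PWM pairs, Fisher z-transformed
and fitted with a Gumbel (extreme-value) distribution per width bucket;
E(score) = N_db * P_null(S >= score).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.stats import gumbel_r

from .discover import MotifResult
from .peakcall import BindingEvent
from .pwm import PWM, Background, MotifOccurrence, reverse_complement

MIN_OVERLAP = 4


@dataclass(frozen=True)
class MotifMatch:
    query: str
    target: str
    offset: int
    strand: str
    sim_score: float
    evalue: float


@dataclass
class MotifLabel:
    """A 'virtual' combination: member motifs share a label; PWMs untouched."""

    label: str
    members: list[str]
    occurrences: list[MotifOccurrence] = field(default_factory=list)

    def __post_init__(self):
        if not self.members:
            raise ValueError("a motif label needs at least one member")


@dataclass
class DistanceSummary:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_total: int                    # binned distances
    n_unmatched: int = 0            # occurrences with no resolvable center
    n_out_of_range: int = 0         # matched but outside the histogram range
    cooccurrence_fraction: float | None = None

    def __post_init__(self):
        if int(self.counts.sum()) != self.n_total:
            raise ValueError("histogram counts must sum to n_total")

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


# ---------------------------------------------------------------------------
# PWM alignment
# ---------------------------------------------------------------------------

def _column_similarity(q: np.ndarray, t: np.ndarray, metric: str,
                       bg: np.ndarray) -> np.ndarray:
    """(wq, wt) matrix of per-column-pair similarities."""
    if metric == "pcc":
        qc = q - q.mean(axis=0, keepdims=True)
        tc = t - t.mean(axis=0, keepdims=True)
        qn = np.linalg.norm(qc, axis=0)
        tn = np.linalg.norm(tc, axis=0)
        denom = qn[:, None] * tn[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = (qc.T @ tc) / denom
        sim[~np.isfinite(sim)] = 0.0
        return sim
    if metric == "allr":
        lq = np.log2(q / bg[:, None])
        lt = np.log2(t / bg[:, None])
        return (q.T @ lt + (t.T @ lq).T) / 2.0
    raise ValueError(f"unknown metric {metric!r}")


def align_pwms(query: PWM, target: PWM, metric: str = "pcc",
               background: Background | None = None,
               min_overlap: int = MIN_OVERLAP) -> tuple[int, str, float]:
    """Best ungapped alignment of query vs target over offsets and strands.

    Returns (offset, strand, score): offset is the target start relative to
    the query start, strand the target orientation. Score = mean per-column
    similarity over the overlap. Ties broken by smaller |offset|, then +.
    """
    if query.width < min_overlap or target.width < min_overlap:
        raise ValueError(f"PWMs must have >= {min_overlap} columns to align")
    bg = (background or Background()).freqs
    best: tuple[float, int, str] | None = None
    for strand in ("+", "-"):
        tgt = target if strand == "+" else reverse_complement(target)
        sim = _column_similarity(query.probs, tgt.probs, metric, bg)
        for off in range(-(tgt.width - min_overlap), query.width - min_overlap + 1):
            diag = np.diagonal(sim, offset=-off)
            if len(diag) < min_overlap:
                continue
            score = float(diag.mean())
            key = (score, -abs(off), strand == "+")
            if best is None or key > (best[0], -abs(best[1]), best[2] == "+"):
                best = (score, off, strand)
    assert best is not None
    return best[1], best[2], best[0]


# ---------------------------------------------------------------------------
# Null calibration and database matching
# ---------------------------------------------------------------------------

def _fisher_z(score: float | np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(score, -1.0 + 1e-9, 1.0 - 1e-9))


@dataclass
class NullModel:
    """Gumbel fits of null (column-shuffled) alignment scores per width bucket.

    Scores are Fisher z-transformed before fitting (the raw mean-PCC score is
    bounded at 1, which an unbounded extreme-value law cannot represent).
    Buckets are keyed by min(width_query, width_target).
    """

    params: dict[int, tuple[float, float, int]]  # width -> (loc, scale, n)
    metric: str = "pcc"
    n_samples: int = 0
    seed: int | None = None
    widened: list[int] = field(default_factory=list)

    def tail_prob(self, score: float, w_query: int, w_target: int) -> float:
        v = min(w_query, w_target)
        key = min(self.params, key=lambda k: abs(k - v))
        loc, scale, _ = self.params[key]
        return float(gumbel_r.sf(_fisher_z(score), loc=loc, scale=scale))

    def evalue(self, score: float, w_query: int, w_target: int, n_db: int) -> float:
        return max(n_db * self.tail_prob(score, w_query, w_target), 1e-300)


def calibrate_null(db: Sequence[PWM], n_samples: int = 300,
                   rng: np.random.Generator | int | None = None,
                   metric: str = "pcc") -> NullModel:
    """Simulate null alignment-score profiles from column-shuffled db pairs.

    Per width bucket (min of the two widths), ``n_samples`` random shuffled
    pairs are aligned and a Gumbel is fitted by maximum likelihood to the
    Fisher z-transformed scores. Buckets that cannot be filled from the
    database (fewer than 2 candidate motifs) are merged into the nearest
    bucket and flagged.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    if not db:
        raise ValueError("empty database")
    rng = np.random.default_rng(rng)
    widths = sorted({p.width for p in db})
    params: dict[int, tuple[float, float, int]] = {}
    widened: list[int] = []
    for v in widths:
        sources = [p for p in db if p.width == v]
        partners = [p for p in db if p.width >= v]
        if not sources or not partners:
            widened.append(v)
            continue
        scores = np.empty(n_samples)
        for i in range(n_samples):
            a = sources[int(rng.integers(0, len(sources)))]
            b = partners[int(rng.integers(0, len(partners)))]
            pa = PWM(a.name, a.probs[:, rng.permutation(a.width)])
            pb = PWM(b.name, b.probs[:, rng.permutation(b.width)])
            scores[i] = align_pwms(pa, pb, metric=metric)[2]
        z = _fisher_z(scores)
        loc, scale = gumbel_r.fit(z)
        params[v] = (float(loc), float(max(scale, 1e-6)), n_samples)
    if not params:
        raise ValueError("could not calibrate any width bucket")
    return NullModel(params, metric=metric, n_samples=n_samples, widened=widened)


def match_database(queries: Sequence[PWM], db: Sequence[PWM], null: NullModel,
                   n_best: int = 5) -> dict[str, list[MotifMatch]]:
    """Per query, the n_best database matches sorted by ascending E-value."""
    if not db:
        raise ValueError("empty database")
    out: dict[str, list[MotifMatch]] = {}
    for q in queries:
        matches = []
        for t in db:
            off, strand, score = align_pwms(q, t, metric=null.metric)
            ev = null.evalue(score, q.width, t.width, len(db))
            matches.append(MotifMatch(q.name, t.name, off, strand, score, ev))
        matches.sort(key=lambda m: (m.evalue, m.target))
        out[q.name] = matches[:n_best]
    return out


def filter_matches(results: dict[str, list[MotifMatch]],
                   name_patterns: Sequence[str] | None = None,
                   evalue_max: float | None = None) -> dict[str, list[MotifMatch]]:
    """Keep queries with >= 1 match passing the (optional) name and E-value filters."""
    out: dict[str, list[MotifMatch]] = {}
    patterns = [p.lower() for p in name_patterns] if name_patterns else None
    for query, matches in results.items():
        ok = [m for m in matches
              if (patterns is None or any(p in m.target.lower() for p in patterns))
              and (evalue_max is None or m.evalue <= evalue_max)]
        if ok:
            out[query] = matches
    return out


def combine(motifs: Sequence[MotifResult], label: str,
            selector: Sequence[str] | Callable[[MotifResult], bool]) -> MotifLabel:
    """Virtually combine motifs under one label; member PWMs are not modified.

    ``selector`` is a list of motif names or a predicate over MotifResult.
    The pooled occurrence list is the concatenation of member occurrences.
    """
    if callable(selector):
        chosen = [m for m in motifs if selector(m)]
    else:
        wanted = set(selector)
        chosen = [m for m in motifs if m.pwm.name in wanted]
    if not chosen:
        raise ValueError(f"selector for label {label!r} selected no motifs")
    pooled: list[MotifOccurrence] = []
    for m in chosen:
        pooled.extend(m.occurrences)
    return MotifLabel(label, [m.pwm.name for m in chosen], pooled)


# ---------------------------------------------------------------------------
# Distance statistics
# ---------------------------------------------------------------------------

def _resolve_centers(events) -> tuple[dict[str, np.ndarray] | None, dict[str, float] | None]:
    """Events as genomic positions per chromosome, or per-sequence centers."""
    if isinstance(events, dict):
        return None, {k: float(v) for k, v in events.items()}
    by_chrom: dict[str, list[float]] = {}
    for ev in events:
        if isinstance(ev, BindingEvent):
            by_chrom.setdefault(ev.chrom, []).append(float(ev.mu))
        else:
            chrom, pos = ev
            by_chrom.setdefault(chrom, []).append(float(pos))
    return {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}, None


def distance_to_peak(occurrences: Sequence[MotifOccurrence], events,
                     bin_width: int = 10, half_range: int = 200) -> DistanceSummary:
    """Histogram of signed distances occurrence midpoint − nearest event center.

    ``events`` may be BindingEvents, (chrom, pos) tuples (both matched through
    each occurrence's genomic provenance), or a dict seq_id -> center for
    region-relative occurrences. Occurrences with no resolvable center go to
    the unmatched tally; matched distances beyond ±half_range are tallied as
    out-of-range, so all input occurrences are accounted for.
    """
    by_chrom, per_seq = _resolve_centers(events)
    edges = np.arange(-half_range, half_range + bin_width, bin_width, dtype=float)
    distances = []
    unmatched = 0
    for occ in occurrences:
        if per_seq is not None:
            center = per_seq.get(occ.seq_id)
            if center is None:
                unmatched += 1
                continue
            distances.append(occ.midpoint - center)
        else:
            mid = occ.genomic_midpoint
            if mid is None or occ.genomic.chrom not in by_chrom:
                unmatched += 1
                continue
            centers = by_chrom[occ.genomic.chrom]
            i = np.searchsorted(centers, mid)
            cands = centers[max(0, i - 1) : i + 1]
            distances.append(mid - cands[np.argmin(np.abs(cands - mid))])
    distances = np.asarray(distances)
    in_range = (distances >= edges[0]) & (distances < edges[-1])
    counts, _ = np.histogram(distances[in_range], bins=edges)
    return DistanceSummary(edges, counts, int(in_range.sum()), unmatched,
                           int((~in_range).sum()))


def pairwise_distances(occ_a: Sequence[MotifOccurrence],
                       occ_b: Sequence[MotifOccurrence],
                       max_gap: int = 200, bin_width: int = 10) -> DistanceSummary:
    """Signed midpoint distances (B − A) on sequences carrying both motifs.

    The co-occurrence fraction is #sequences with both motifs divided by
    #sequences with the rarer motif. For a self-pair the zero-distance
    self-comparisons are excluded.
    """
    same = occ_a is occ_b
    by_a: dict[str, list[MotifOccurrence]] = {}
    by_b: dict[str, list[MotifOccurrence]] = {}
    for o in occ_a:
        by_a.setdefault(o.seq_id, []).append(o)
    for o in occ_b:
        by_b.setdefault(o.seq_id, []).append(o)
    both = sorted(set(by_a) & set(by_b))
    rarer = min(len(by_a), len(by_b))
    frac = len(both) / rarer if rarer else 0.0
    edges = np.arange(-max_gap, max_gap + bin_width, bin_width, dtype=float)
    distances = []
    out_of_range = 0
    for sid in both:
        for a in by_a[sid]:
            for b in by_b[sid]:
                if same and a.start == b.start and a.strand == b.strand:
                    continue
                d = b.midpoint - a.midpoint
                if edges[0] <= d < edges[-1]:
                    distances.append(d)
                else:
                    out_of_range += 1
    counts, _ = np.histogram(np.asarray(distances), bins=edges)
    return DistanceSummary(edges, counts, len(distances),
                           n_out_of_range=out_of_range,
                           cooccurrence_fraction=frac)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_occurrences(occurrences_by_label: dict[str, Sequence[MotifOccurrence]],
                       path: str | Path, fmt: str = "bed") -> None:
    """Export labeled occurrences as BED6 (genomic) or TSV (region-relative).

    BED requires genomic provenance on every occurrence; a mix raises an error
    naming the offending label.
    """
    if fmt == "bed":
        rows = []
        for label, occs in occurrences_by_label.items():
            for o in occs:
                if o.genomic is None:
                    raise ValueError(
                        f"label {label!r}: occurrence without genomic provenance; use fmt='tsv'")
                rows.append((o.genomic.chrom, o.genomic.start, o.genomic.end,
                             label, o.score, o.genomic.strand))
        rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
        with open(path, "w") as fh:
            for chrom, s, e, label, score, strand in rows:
                fh.write(f"{chrom}\t{s}\t{e}\t{label}\t{score:.4f}\t{strand}\n")
    elif fmt == "tsv":
        rows = []
        for label, occs in occurrences_by_label.items():
            for o in occs:
                rows.append((o.seq_id, o.start, o.end, label, o.score, o.strand, o.pval))
        rows.sort(key=lambda r: (r[0], r[1], r[3]))
        with open(path, "w") as fh:
            fh.write("seq_id\tstart\tend\tlabel\tscore\tstrand\tpval\n")
            for r in rows:
                fh.write(f"{r[0]}\t{r[1]}\t{r[2]}\t{r[3]}\t{r[4]:.4f}\t{r[5]}\t{r[6]:.3e}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def export_histogram(summary: DistanceSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_lo\tbin_hi\tcount\n")
        for lo, hi, c in zip(summary.bin_edges[:-1], summary.bin_edges[1:], summary.counts):
            fh.write(f"{lo:g}\t{hi:g}\t{int(c)}\n")
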