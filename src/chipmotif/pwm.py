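"""Position weight matrices: scoring, exact score-distribution p-values, scanning.

The score of a word x under a PWM is the log2 likelihood ratio
``sum_j log2(theta[x_j, j] / b[x_j])``. Its null distribution for an i.i.d.
background word is computed exactly by column-wise convolution on a discretized
score grid (granularity ``GRANULARITY`` log2 units), which bounds the p-value
error by w * granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .core_io import BASE_ORDER, GenomicInterval, SequenceRecord

GRANULARITY = 1e-3  # score-grid step, in log2 units

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASE_ORDER):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequences(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences into a padded (n, Lmax) int8 matrix plus a length vector."""
    lens = np.asarray([len(s) for s in seqs], dtype=np.int64)
    lmax = int(lens.max()) if len(lens) else 0
    codes = np.full((len(seqs), lmax), 4, dtype=np.int8)
    for i, s in enumerate(seqs):
        codes[i, : lens[i]] = _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    return codes, lens


@dataclass
class Background:
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise ValueError("background must be 4 positive frequencies")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @classmethod
    def from_sequences(cls, seqs: Sequence[str]) -> "Background":
        counts = np.zeros(4)
        for s in seqs:
            codes = _CODE[np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)]
            counts += np.bincount(codes[codes < 4], minlength=4)
        if counts.sum() == 0:
            return cls()
        return cls((counts + 1.0) / (counts.sum() + 4.0))


@dataclass
class PWM:
    """Column-stochastic 4 x w probability matrix; rows ordered A, C, G, T."""

    name: str
    probs: np.ndarray
    source: str = "denovo"

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("PWM must be a 4 x w matrix")
        if np.any(self.probs <= 0):
            raise ValueError("PWM entries must be strictly positive (pseudocounted)")
        if np.any(np.abs(self.probs.sum(axis=0) - 1.0) > 1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        return "".join(BASE_ORDER[i] for i in np.argmax(self.probs, axis=0))

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, pseudocount: float = 0.25,
                    source: str = "denovo") -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudocount) / (counts.sum(axis=0) + 4.0 * pseudocount)
        return cls(name, probs, source=source)


@dataclass(frozen=True)
class MotifOccurrence:
    seq_id: str
    start: int
    end: int
    strand: str
    score: float
    pval: float
    genomic: GenomicInterval | None = None

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def genomic_midpoint(self) -> float | None:
        if self.genomic is None:
            return None
        return (self.genomic.start + self.genomic.end) / 2.0


def log_odds(pwm: PWM, background: Background | None = None) -> np.ndarray:
    """4 x w matrix of log2(theta / b)."""
    bg = background or Background()
    return np.log2(pwm.probs / bg.freqs[:, None])


def reverse_complement(pwm: PWM) -> PWM:
    """Reverse columns and swap A<->T, C<->G rows."""
    return PWM(pwm.name, pwm.probs[::-1, ::-1].copy(), source=pwm.source)


def information_content(pwm: PWM, background: Background | None = None) -> np.ndarray:
    """Per-column relative entropy (bits) of the PWM vs the background."""
    bg = background or Background()
    return np.sum(pwm.probs * np.log2(pwm.probs / bg.freqs[:, None]), axis=0)


def trim(pwm: PWM, ic_min: float, background: Background | None = None,
         min_width: int = 4) -> PWM:
    """Drop maximal low-information flanking runs from both ends.

    Never trims below ``min_width`` columns.
    """
    ic = information_content(pwm, background)
    lo, hi = 0, pwm.width
    while hi - lo > min_width and ic[lo] < ic_min:
        lo += 1
    while hi - lo > min_width and ic[hi - 1] < ic_min:
        hi -= 1
    if lo == 0 and hi == pwm.width:
        return pwm
    return PWM(pwm.name, pwm.probs[:, lo:hi].copy(), source=pwm.source)


class ScoreDistribution:
    """Exact distribution of the PWM log-odds score of an i.i.d. background word.

    Scores are rounded to a grid of step ``granularity``; all probabilities
    are exact on that grid (column-wise convolution, 4 shifted adds per column).
    """

    def __init__(self, pwm: PWM, background: Background | None = None,
                 granularity: float = GRANULARITY):
        self.background = background or Background()
        self.g = granularity
        S = log_odds(pwm, self.background)
        self.ints = np.rint(S / granularity).astype(np.int64)  # (4, w)
        lo_j = self.ints.min(axis=0)
        hi_j = self.ints.max(axis=0)
        self.lo = int(lo_j.sum())
        self.hi = int(hi_j.sum())
        dist = np.zeros(1)
        dist[0] = 1.0
        bg = self.background.freqs
        for j in range(pwm.width):
            span = int(hi_j[j] - lo_j[j])
            new = np.zeros(len(dist) + span)
            for c in range(4):
                off = int(self.ints[c, j] - lo_j[j])
                new[off : off + len(dist)] += bg[c] * dist
            dist = new
        self.pmf = dist  # pmf[i] = P(score grid index = lo + i)
        # survival[i] = P(score >= lo + i)
        self.survival = np.cumsum(dist[::-1])[::-1]
        grid = (self.lo + np.arange(len(dist))) * granularity
        self._grid = grid
        self.mean = float(np.dot(dist, grid))
        self.var = float(np.dot(dist, (grid - self.mean) ** 2))

    @property
    def max_score(self) -> float:
        return self.hi * self.g

    @property
    def min_score(self) -> float:
        return self.lo * self.g

    def rounded_matrix(self) -> np.ndarray:
        """The (w, 4) grid-rounded scoring matrix consistent with this distribution."""
        return (self.ints * self.g).T.copy()

    def sf(self, threshold: float) -> float:
        """P(score >= threshold) for a background word."""
        if np.isneginf(threshold):
            return 1.0
        t = int(np.ceil(threshold / self.g - 1e-9))
        if t > self.hi:
            return 0.0
        if t <= self.lo:
            return 1.0
        return float(self.survival[t - self.lo])

    def score_threshold(self, pval: float) -> float:
        """Smallest grid score s with P(score >= s) <= pval (inf if unattainable)."""
        idx = np.searchsorted(-self.survival, -pval, side="left")
        if idx >= len(self.survival):
            return np.inf
        return (self.lo + idx) * self.g

    def truncated_moments(self, threshold: float) -> tuple[float, float]:
        """Mean and variance of the score conditional on score >= threshold."""
        t = int(np.ceil(threshold / self.g - 1e-9))
        i0 = max(0, t - self.lo)
        p = self.pmf[i0:]
        tot = p.sum()
        if tot <= 0:
            return self.max_score, 0.0
        g = self._grid[i0:]
        m = float(np.dot(p, g) / tot)
        v = float(np.dot(p, (g - m) ** 2) / tot)
        return m, v


def score_pvalue(pwm: PWM, background: Background | None = None,
                 threshold_score: float = 0.0,
                 granularity: float = GRANULARITY) -> float:
    """Exact (grid-discretized) p-value P(score(X) >= threshold) for background X."""
    return ScoreDistribution(pwm, background, granularity).sf(threshold_score)


def scan(pwm: PWM, sequences: Sequence[SequenceRecord], p_threshold: float = 2e-4,
         background: Background | None = None, both_strands: bool = True,
         dist: ScoreDistribution | None = None) -> list[MotifOccurrence]:
    """Report every window whose score p-value is <= p_threshold.

    Windows containing N are skipped; sequences shorter than the PWM width are
    skipped. Scores use the grid-rounded matrix so thresholding and reported
    p-values are exactly consistent with the score distribution.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    if dist is None:
        dist = ScoreDistribution(pwm, background)
    w = pwm.width
    thr = dist.score_threshold(p_threshold)
    if np.isinf(thr):
        return []
    seq_strs = [rec.seq for rec in sequences]
    codes, lens = encode_sequences(seq_strs)
    if codes.shape[1] < w:
        return []
    smat_p = dist.rounded_matrix()
    nofs = codes.shape[1] - w + 1
    sp = np.empty((len(sequences), nofs))
    _kernels.window_scores(codes, lens, smat_p, sp)
    strands: list[tuple[str, np.ndarray]] = [("+", sp)]
    if both_strands:
        rc_dist_mat = (reverse_complement_ints(dist.ints) * dist.g).T.copy()
        sm = np.empty_like(sp)
        _kernels.window_scores(codes, lens, rc_dist_mat, sm)
        strands.append(("-", sm))
    occs: list[MotifOccurrence] = []
    eps = dist.g * 1e-6
    for si, rec in enumerate(sequences):
        hits: list[tuple[int, str, float]] = []
        for strand, smat in strands:
            idx = np.nonzero(smat[si] >= thr - eps)[0]
            for o in idx:
                hits.append((int(o), strand, float(smat[si, o])))
        hits.sort(key=lambda h: (h[0], h[1]))
        for o, strand, score in hits:
            genomic = None
            if rec.origin is not None:
                genomic = GenomicInterval(rec.origin.chrom, rec.origin.start + o,
                                          rec.origin.start + o + w, strand)
            occs.append(MotifOccurrence(rec.id, o, o + w, strand, score,
                                        dist.sf(score), genomic=genomic))
    return occs


def reverse_complement_ints(ints: np.ndarray) -> np.ndarray:
    """Reverse-complement a 4 x w integer score matrix (rows A,C,G,T)."""
    return ints[::-1, ::-1].copy()


def logo_matrix(pwm: PWM, background: Background | None = None) -> np.ndarray:
    """IC-scaled 4 x w matrix (the numeric content of a sequence logo)."""
    ic = information_content(pwm, background)
    return pwm.probs * ic[None, :]
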