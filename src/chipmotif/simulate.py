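"""Synthetic ChIP-Seq data: directional reads around planted binding events and
background sequences with planted PWM sites.

The generators emulate the standard data-generating picture of a transcription
factor ChIP-Seq experiment: ~175 bp immunoprecipitated fragments centered on
binding sites, sequenced from one end as short (35 bp) directional reads, so
that + and − read 5' coordinates pile up on opposite flanks of each site. All
randomness flows through an explicit numpy Generator; identical seed and
configuration give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import AlignedRead, GenomicInterval, SequenceRecord
from .pwm import PWM, BASE_ORDER

DEFAULT_FRAG_MEAN = 175.0
DEFAULT_FRAG_SD = 35.0
DEFAULT_READ_LEN = 35
DEFAULT_N_FRAG = 100


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset; fully determines recovery metrics."""

    events: list = field(default_factory=list)   # (chrom, mu*, n_frag, delta*)
    sites: list = field(default_factory=list)    # (seq_id, offset, strand, motif name)
    skips: list = field(default_factory=list)    # placements abandoned after re-draws
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(events=[tuple(e) for e in d["events"]],
                   sites=[tuple(s) for s in d["sites"]],
                   skips=[tuple(s) for s in d["skips"]], seed=d["seed"])


def sim_reads(events: Sequence[tuple], chrom_lengths: dict[str, int],
              frag_mean: float = DEFAULT_FRAG_MEAN, frag_sd: float = DEFAULT_FRAG_SD,
              read_len: int = DEFAULT_READ_LEN, noise_rate: float = 0.0,
              map_gaps: Sequence[GenomicInterval] = (),
              rng: np.random.Generator | int | None = None,
              ) -> tuple[list[AlignedRead], list[AlignedRead], SimTruth]:
    """Simulate treatment and control reads around planted binding events.

    Each event is ``(chrom, mu)`` or ``(chrom, mu, n_frag)``. Per fragment,
    length ~ Normal(frag_mean, frag_sd) truncated > read_len; the fragment is
    centered on mu and emits one read: a + read whose 5' end is the fragment's
    left end, or a − read whose 5' end is the rightmost base, with equal
    probability. With frag_sd = 0 the two 5'-coordinate modes are separated by
    exactly frag_mean − 1, which is recorded as the event's true separation
    delta*. Uniform noise reads (``noise_rate`` per bp per strand pair) go into
    both treatment and control; control contains noise only. Reads whose pos5
    falls inside a map gap are deleted from both samples.
    """
    if frag_mean <= read_len:
        raise ValueError("frag_mean must exceed read_len")
    rng = np.random.default_rng(rng)
    seed = None
    truth = SimTruth(seed=seed)
    treatment: list[AlignedRead] = []

    gap_arr: dict[str, np.ndarray] = {}
    for g in map_gaps:
        gap_arr.setdefault(g.chrom, [])
    for g in map_gaps:
        gap_arr[g.chrom].append((g.start, g.end))

    def in_gap(chrom: str, pos: int) -> bool:
        for s, e in gap_arr.get(chrom, ()):
            if s <= pos < e:
                return True
        return False

    for ev in events:
        chrom, mu = ev[0], float(ev[1])
        n_frag = int(ev[2]) if len(ev) > 2 else DEFAULT_N_FRAG
        delta_star = frag_mean - 1.0
        truth.events.append((chrom, mu, n_frag, delta_star))
        for _ in range(n_frag):
            length = read_len - 1.0
            while length <= read_len:
                length = rng.normal(frag_mean, frag_sd) if frag_sd > 0 else frag_mean
            left = int(round(mu - length / 2.0))
            right_5p = left + int(round(length)) - 1
            if rng.random() < 0.5:
                pos5, strand = left, "+"
            else:
                pos5, strand = right_5p, "-"
            pos5 = max(0, min(pos5, chrom_lengths[chrom] - 1))
            if not in_gap(chrom, pos5):
                treatment.append(AlignedRead(chrom, pos5, strand, read_len))

    def noise_reads() -> list[AlignedRead]:
        out: list[AlignedRead] = []
        for chrom in sorted(chrom_lengths):
            length = chrom_lengths[chrom]
            n = rng.poisson(noise_rate * length)
            pos = rng.integers(0, length, size=n)
            strands = rng.random(n) < 0.5
            for p, plus in zip(pos, strands):
                if not in_gap(chrom, int(p)):
                    out.append(AlignedRead(chrom, int(p), "+" if plus else "-", read_len))
        return out

    treatment.extend(noise_reads())
    control = noise_reads()
    return treatment, control, truth


def _sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    cols = [rng.choice(4, p=pwm.probs[:, j]) for j in range(pwm.width)]
    return "".join(BASE_ORDER[c] for c in cols)


_COMP = str.maketrans("ACGT", "TGCA")


def sim_sequences(n: int, length: int, background=None,
                  motifs: Sequence[tuple] = (),
                  rng: np.random.Generator | int | None = None,
                  ) -> tuple[list[SequenceRecord], SimTruth]:
    """Generate i.i.d. background sequences with planted PWM sites.

    ``motifs`` is a list of ``(pwm, occupancy, position_dist)`` where
    position_dist is one of:

    - ``"uniform"``: site start uniform over admissible offsets;
    - ``("center", sd)``: site midpoint ~ Normal(sequence midpoint, sd),
      clipped to admissible range (sd = 0 plants exactly at the midpoint);
    - ``("fixed", offset)``: fixed start offset;
    - ``("lag", ref_index, lag)``: planted only in sequences where motif
      ``ref_index`` was planted, at the reference start + lag.

    Overlapping plants are re-drawn up to 10 times, then skipped (recorded in
    the truth's ``skips``). Each site's letters are sampled column-wise from
    the PWM; strand is chosen uniformly.
    """
    from .pwm import Background

    bg = background or Background()
    rng = np.random.default_rng(rng)
    truth = SimTruth()
    records: list[SequenceRecord] = []
    for s in range(n):
        letters = rng.choice(4, size=length, p=bg.freqs)
        seq = list("".join(BASE_ORDER[c] for c in letters))
        occupied: list[tuple[int, int]] = []
        planted_starts: dict[int, int] = {}  # motif index -> start
        for mi, (pwm, occupancy, posdist) in enumerate(motifs):
            w = pwm.width
            if length < w:
                raise ValueError("sequence length shorter than motif width")
            if isinstance(posdist, tuple) and posdist[0] == "lag":
                _, ref_idx, lag = posdist
                if ref_idx not in planted_starts:
                    continue
                if rng.random() >= occupancy:
                    continue
                start = planted_starts[ref_idx] + int(lag)
                if not (0 <= start <= length - w) or any(
                        start < e and o < start + w for o, e in occupied):
                    truth.skips.append((f"seq{s}", pwm.name))
                    continue
                starts = [start]
            else:
                if rng.random() >= occupancy:
                    continue
                starts = []
                for _attempt in range(10):
                    if posdist == "uniform":
                        cand = int(rng.integers(0, length - w + 1))
                    elif isinstance(posdist, tuple) and posdist[0] == "center":
                        sd = float(posdist[1])
                        mid = length / 2.0 + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                        cand = int(round(mid - w / 2.0))
                        cand = max(0, min(cand, length - w))
                    elif isinstance(posdist, tuple) and posdist[0] == "fixed":
                        cand = int(posdist[1])
                    else:
                        raise ValueError(f"unknown position_dist {posdist!r}")
                    if not any(cand < e and o < cand + w for o, e in occupied):
                        starts = [cand]
                        break
                if not starts:
                    truth.skips.append((f"seq{s}", pwm.name))
                    continue
            for start in starts:
                site = _sample_site(pwm, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    site = site.translate(_COMP)[::-1]
                seq[start : start + w] = list(site)
                occupied.append((start, start + w))
                planted_starts[mi] = start
                truth.sites.append((f"seq{s}", start, strand, pwm.name))
        records.append(SequenceRecord(f"seq{s}", "".join(seq)))
    return records, truth
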