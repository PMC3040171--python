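"""Iterative de novo motif discovery: spaced-dyad seeding, genetic-algorithm
search with log-E-value fitness, ZOOPS EM refinement, thresholded scanning and
masking.

Search protocol, per discovery round: over-represented words seed a population
of spaced dyads; a genetic algorithm evolves the population, where each
individual is converted to a letter-probability matrix, refined by EM on a
training half of the sequences, and scored on a held-out half (the split
prevents EM over-fitting from inflating the apparent enrichment). The best
motif passing the log-E cutoff is re-refined, trimmed, scanned against all
sequences, reported, and its occurrences are masked with N before the next
round. All randomness flows through one numpy Generator seeded from the
configuration, so identical seed + input give identical output.

The fitness is a log E-value: logE = ln W + ln P(Binom(W, p*) >= n)
+ ln P(mean site score >= observed | n sites, each >= threshold), where W is
the number of scanned windows, p* the attained scan p-value, and the
conditional mean-score term uses the threshold-truncated exact score
distribution with a CLT tail. Lower is fitter; the default cutoff 0 keeps
motifs better than one expected by chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binom, norm

from . import _kernels
from .core_io import BASE_ORDER, SequenceRecord
from .pwm import (PWM, Background, MotifOccurrence, ScoreDistribution,
                  encode_sequences, reverse_complement, scan, trim)

UNFIT = np.inf  # sentinel fitness for motifs with no occurrences


@dataclass(frozen=True)
class SpacedDyad:
    word1: str
    spacer: int
    word2: str

    def __post_init__(self):
        for w in (self.word1, self.word2):
            if not (3 <= len(w) <= 6) or set(w) - set(BASE_ORDER):
                raise ValueError(f"dyad word {w!r} must be a 3-6 mer over ACGT")
        if self.spacer < 0:
            raise ValueError("spacer must be >= 0")

    @property
    def width(self) -> int:
        return len(self.word1) + self.spacer + len(self.word2)


@dataclass
class Individual:
    """One GA individual: a spaced dyad with its EM-refined PWM and fitness."""

    dyad: SpacedDyad
    fitness: float = UNFIT
    refined_pwm: PWM | None = None
    fold_enrichment: float = 0.0


@dataclass
class DiscoveryConfig:
    n_pop: int = 100
    n_gen: int = 5
    p_threshold: float = 2e-4
    logE_cutoff: float = 0.0
    max_motifs: int = 10
    prior: str = "uniform"            # "uniform" or "centered"
    enrichment_weighting: bool = False
    seed: int = 0
    k_range: tuple[int, int] = (3, 6)
    max_spacer: int = 10
    mutation_prob: float = 0.1
    tournament_size: int = 2
    elitism: int = 1
    em_iters_ga: int = 6              # EM iterations while scoring GA individuals
    em_iters_final: int = 50          # EM iterations for the reported motif
    ga_subsample: int = 100           # training sequences used during GA scoring
    ic_min: float = 0.1               # flank-trimming threshold, bits
    background: str = "uniform"       # "uniform" or "observed"
    dedup_pcc: float = 0.9

    def __post_init__(self):
        if self.n_pop < 2:
            raise ValueError("n_pop must be >= 2")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")


@dataclass
class MotifResult:
    pwm: PWM
    occurrences: list[MotifOccurrence]
    logE: float
    fold_enrichment: float
    n_sites: int
    palindromic: bool = False
    round: int = 0

    def __post_init__(self):
        if self.n_sites != len(self.occurrences):
            raise ValueError("n_sites must equal len(occurrences)")


@dataclass
class FitnessResult:
    logE: float
    occurrences: list[MotifOccurrence]
    fold_enrichment: float
    n_windows: int


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def _kmer_tables(seqs: Sequence[str], ks: Sequence[int], bg: Background):
    """Per k: (counts over all 4^k words, expected counts, z-score weights)."""
    codes, lens = encode_sequences(seqs)
    tables = {}
    logbg = np.log(bg.freqs)
    for k in ks:
        counts = np.zeros(4**k)
        pow4 = 4 ** np.arange(k - 1, -1, -1)
        n_windows = 0
        for i in range(codes.shape[0]):
            row = codes[i, : lens[i]]
            if len(row) < k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(row, k)
            ok = (win < 4).all(axis=1)
            n_windows += int(ok.sum())
            if ok.any():
                vals = win[ok].astype(np.int64) @ pow4
                counts += np.bincount(vals, minlength=4**k)
        digits = (np.arange(4**k)[:, None] // pow4[None, :]) % 4
        word_logp = logbg[digits].sum(axis=1)
        expected = n_windows * np.exp(word_logp)
        z = (counts - expected) / np.sqrt(np.maximum(expected, 1e-9))
        weights = np.maximum(z, 0.0) ** 2
        if weights.sum() == 0:
            weights = counts.astype(float)
        if weights.sum() == 0:
            weights = np.ones_like(counts)
        tables[k] = (counts, weights / weights.sum(), digits)
    return tables


def seed_population(sequences: Sequence[SequenceRecord], k_range: tuple[int, int] = (3, 6),
                    max_spacer: int = 10, n_pop: int = 100,
                    rng: np.random.Generator | int | None = None,
                    background: Background | None = None) -> list[Individual]:
    """Sample a population of spaced dyads biased toward over-represented words.

    Word sampling probability is proportional to the squared positive
    over-representation z-score (observed vs background-expected count), so
    strongly enriched words dominate the seed pool.
    """
    if not sequences:
        raise ValueError("no sequences")
    seqs = [r.seq for r in sequences]
    if max(len(s) for s in seqs) < k_range[1]:
        raise ValueError("sequences shorter than the maximum word length")
    rng = np.random.default_rng(rng)
    bg = background or Background()
    ks = list(range(k_range[0], k_range[1] + 1))
    tables = _kmer_tables(seqs, ks, bg)

    def sample_word() -> str:
        k = int(rng.choice(ks))
        _, probs, _ = tables[k]
        idx = int(rng.choice(len(probs), p=probs))
        word = ""
        for _ in range(k):
            word = BASE_ORDER[idx % 4] + word
            idx //= 4
        return word

    pop = []
    for _ in range(n_pop):
        d = SpacedDyad(sample_word(), int(rng.integers(0, max_spacer + 1)), sample_word())
        pop.append(Individual(d))
    return pop


def dyad_to_pwm(dyad: SpacedDyad, pseudo: float = 0.05) -> PWM:
    """Letter-probability matrix: dyad letters get mass 1-3*pseudo, spacers uniform."""
    w = dyad.width
    probs = np.full((4, w), 0.25)
    letters = list(dyad.word1) + [None] * dyad.spacer + list(dyad.word2)
    for j, letter in enumerate(letters):
        if letter is not None:
            probs[:, j] = pseudo
            probs[BASE_ORDER.index(letter), j] = 1.0 - 3.0 * pseudo
    return PWM(f"dyad_{dyad.word1}_{dyad.spacer}_{dyad.word2}", probs)


# ---------------------------------------------------------------------------
# EM refinement (ZOOPS)
# ---------------------------------------------------------------------------

@dataclass
class EMResult:
    pwm: PWM
    loglik_trace: list[float]
    n_iter: int
    gamma: float


def _position_prior(lens: np.ndarray, w: int, nofs: int, kind: str) -> np.ndarray:
    pi = np.zeros((len(lens), nofs))
    for i, L in enumerate(lens):
        n_valid = int(L) - w + 1
        if n_valid <= 0:
            continue
        if kind == "uniform":
            pi[i, :n_valid] = 1.0 / n_valid
        elif kind == "centered":
            mid = (L - w) / 2.0
            weights = 1.0 - np.abs(np.arange(n_valid) - mid) / (mid + 1.0)
            weights = np.clip(weights, 1e-3, None)
            pi[i, :n_valid] = weights / weights.sum()
        else:
            raise ValueError(f"unknown positional prior {kind!r}")
    return pi


def em_refine(pwm0: PWM, sequences: Sequence[SequenceRecord],
              max_iter: int = 50, tol: float = 1e-4, prior: str = "uniform",
              weights: Sequence[float] | None = None,
              background: Background | None = None, pseudocount: float = 0.25,
              return_details: bool = False):
    """ZOOPS EM: refine a starting PWM against a sequence set.

    Per sequence the latent state is {no site} or {site at offset o, strand s};
    the positional prior is uniform or center-weighted (triangular); optional
    per-sequence weights emphasize strongly enriched regions. The M-step uses
    posterior-weighted letter counts plus a Dirichlet pseudocount. Iterates
    until max |delta Theta| < tol or max_iter. The penalized observed-data
    log-likelihood is non-decreasing (recorded in the trace).
    """
    bg = background or Background()
    w = pwm0.width
    seqs = [r.seq for r in sequences]
    if not seqs:
        raise ValueError("no sequences")
    if w > max(len(s) for s in seqs):
        raise ValueError("PWM wider than every sequence")
    codes, lens = encode_sequences(seqs)
    nofs = codes.shape[1] - w + 1
    if nofs <= 0:
        raise ValueError("PWM wider than every sequence")
    pi = _position_prior(lens, w, nofs, prior)
    wt = np.ones(len(seqs)) if weights is None else np.asarray(weights, dtype=float)
    if len(wt) != len(seqs) or np.any(wt < 0):
        raise ValueError("weights must be non-negative, one per sequence")
    if wt.sum() > 0:
        wt = wt * (len(wt) / wt.sum())

    theta = pwm0.probs.copy()
    gamma = 0.5
    trace: list[float] = []
    sp = np.empty((len(seqs), nofs))
    sm = np.empty((len(seqs), nofs))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        smat = np.log2(theta / bg.freqs[:, None]).T.copy()      # (w, 4)
        smat_rc = smat[::-1, ::-1].copy()
        _kernels.window_scores(codes, lens, smat, sp)
        _kernels.window_scores(codes, lens, smat_rc, sm)
        counts = np.zeros((w, 4))
        stats = np.zeros(3)
        _kernels.zoops_estep(codes, lens, sp, sm, pi, wt, gamma, counts, stats)
        penalty = pseudocount * np.log(theta).sum()
        trace.append(float(stats[0]) + penalty)
        new_theta = (counts.T + pseudocount) / (counts.sum(axis=1) + 4.0 * pseudocount)
        gamma = float(np.clip(stats[1] / max(stats[2], 1e-12), 1e-3, 1.0 - 1e-3))
        delta = float(np.max(np.abs(new_theta - theta)))
        theta = new_theta
        if delta < tol:
            break
    out = PWM(pwm0.name, theta, source=pwm0.source)
    if return_details:
        return EMResult(out, trace, n_iter, gamma)
    return out


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def _count_valid_windows(sequences: Sequence[SequenceRecord], w: int,
                         both_strands: bool = True) -> int:
    codes, lens = encode_sequences([r.seq for r in sequences])
    if codes.shape[1] < w:
        return 0
    valid = 0
    win_ok = np.lib.stride_tricks.sliding_window_view(codes, w, axis=1) < 4
    ok = win_ok.all(axis=2)
    for i, L in enumerate(lens):
        n_valid = int(L) - w + 1
        if n_valid > 0:
            valid += int(ok[i, :n_valid].sum())
    return valid * (2 if both_strands else 1)


def fitness(pwm: PWM, sequences: Sequence[SequenceRecord], p_threshold: float = 2e-4,
            background: Background | None = None) -> FitnessResult:
    """Log-E-value fitness of a PWM on a sequence set (lower = fitter).

    Returns the occurrences at the scan threshold, the fold enrichment
    n / (W * p_threshold), and logE as described in the module docstring.
    No occurrences -> the unfit sentinel (+inf).
    """
    bg = background or Background()
    dist = ScoreDistribution(pwm, bg)
    occs = scan(pwm, sequences, p_threshold, bg, both_strands=True, dist=dist)
    W = _count_valid_windows(sequences, pwm.width, both_strands=True)
    n = len(occs)
    if n == 0 or W == 0:
        return FitnessResult(UNFIT, occs, 0.0, W)
    fold = n / (W * p_threshold)
    thr = dist.score_threshold(p_threshold)
    p_star = dist.sf(thr)
    log_p_count = float(binom.logsf(n - 1, W, min(max(p_star, 1e-300), 1.0)))
    m_t, v_t = dist.truncated_moments(thr)
    obs_mean = float(np.mean([o.score for o in occs]))
    if v_t <= 0:
        log_p_score = 0.0
    else:
        z = (obs_mean - m_t) / np.sqrt(v_t / n)
        log_p_score = float(norm.logsf(z))
    logE = float(np.log(W) + log_p_count + log_p_score)
    return FitnessResult(logE, occs, fold, W)


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

def _mutate(dyad: SpacedDyad, max_spacer: int, rng: np.random.Generator) -> SpacedDyad:
    """Point-mutate one letter, or shift the spacer by +/- 1."""
    if rng.random() < 0.5:
        which = rng.integers(0, 2)
        word = dyad.word1 if which == 0 else dyad.word2
        pos = int(rng.integers(0, len(word)))
        new = BASE_ORDER[int(rng.integers(0, 4))]
        word = word[:pos] + new + word[pos + 1 :]
        return SpacedDyad(word, dyad.spacer, dyad.word2) if which == 0 \
            else SpacedDyad(dyad.word1, dyad.spacer, word)
    shift = 1 if rng.random() < 0.5 else -1
    return SpacedDyad(dyad.word1, int(np.clip(dyad.spacer + shift, 0, max_spacer)),
                      dyad.word2)


def _crossover(d1: SpacedDyad, d2: SpacedDyad) -> tuple[SpacedDyad, SpacedDyad]:
    """Single-point crossover exchanging (spacer, word2)."""
    return (SpacedDyad(d1.word1, d2.spacer, d2.word2),
            SpacedDyad(d2.word1, d1.spacer, d1.word2))


class _Evaluator:
    """Caches (refine + score) per unique dyad; results are order-independent."""

    def __init__(self, train: list[SequenceRecord], eval_set: list[SequenceRecord],
                 config: DiscoveryConfig, background: Background,
                 weights: np.ndarray | None):
        self.train = train
        self.eval_set = eval_set
        self.config = config
        self.bg = background
        self.weights = weights
        self.cache: dict[SpacedDyad, tuple[float, PWM, float]] = {}

    def __call__(self, ind: Individual) -> Individual:
        hit = self.cache.get(ind.dyad)
        if hit is None:
            pwm0 = dyad_to_pwm(ind.dyad)
            refined = em_refine(pwm0, self.train, max_iter=self.config.em_iters_ga,
                                prior=self.config.prior, weights=self.weights,
                                background=self.bg)
            fit = fitness(refined, self.eval_set, self.config.p_threshold, self.bg)
            hit = (fit.logE, refined, fit.fold_enrichment)
            self.cache[ind.dyad] = hit
        ind.fitness, ind.refined_pwm, ind.fold_enrichment = hit
        return ind


def evolve(population: list[Individual], sequences: Sequence[SequenceRecord],
           config: DiscoveryConfig, rng: np.random.Generator | int | None = None,
           train: Sequence[SequenceRecord] | None = None,
           eval_set: Sequence[SequenceRecord] | None = None,
           background: Background | None = None,
           weights: Sequence[float] | None = None) -> list[Individual]:
    """Run the GA and return evaluated individuals passing the logE cutoff.

    Tournament selection, crossover of (spacer, word2), point mutation with
    probability ``mutation_prob``, elitism. When train/eval_set are not given,
    the sequences are split in half (train/held-out) for refinement vs scoring.
    """
    rng = np.random.default_rng(rng)
    bg = background or Background()
    sequences = list(sequences)
    if train is None or eval_set is None:
        perm = rng.permutation(len(sequences))
        half = len(sequences) // 2
        train = [sequences[i] for i in perm[:half]]
        eval_set = [sequences[i] for i in perm[half:]]
    train = list(train)[: max(2, config.ga_subsample)] if config.ga_subsample else list(train)
    wt = None
    if weights is not None:
        wt = np.asarray(weights, dtype=float)[: len(train)]
    evaluator = _Evaluator(train, list(eval_set), config, bg, wt)

    pop = [evaluator(ind) for ind in population]

    def tournament() -> Individual:
        best = None
        for _ in range(config.tournament_size):
            cand = pop[int(rng.integers(0, len(pop)))]
            if best is None or cand.fitness < best.fitness:
                best = cand
        return best

    for _gen in range(config.n_gen):
        pop.sort(key=lambda i: i.fitness)
        next_pop = [Individual(i.dyad) for i in pop[: config.elitism]]
        while len(next_pop) < config.n_pop:
            p1, p2 = tournament(), tournament()
            c1, c2 = _crossover(p1.dyad, p2.dyad)
            for child in (c1, c2):
                if rng.random() < config.mutation_prob:
                    child = _mutate(child, config.max_spacer, rng)
                if len(next_pop) < config.n_pop:
                    next_pop.append(Individual(child))
        pop = [evaluator(ind) for ind in next_pop]

    seen: dict[SpacedDyad, Individual] = {}
    for ind in pop:
        if ind.fitness <= config.logE_cutoff and ind.dyad not in seen:
            seen[ind.dyad] = ind
    return sorted(seen.values(), key=lambda i: (i.fitness, i.dyad.word1, i.dyad.spacer, i.dyad.word2))


# ---------------------------------------------------------------------------
# Masking and the discovery loop
# ---------------------------------------------------------------------------

def mask(sequences: Sequence[SequenceRecord],
         occurrences: Sequence[MotifOccurrence]) -> list[SequenceRecord]:
    """Replace occurrence spans with N; everything else unchanged."""
    by_id: dict[str, list[tuple[int, int]]] = {}
    for occ in occurrences:
        by_id.setdefault(occ.seq_id, []).append((occ.start, occ.end))
    known = {r.id for r in sequences}
    for sid in by_id:
        if sid not in known:
            raise ValueError(f"occurrence references unknown sequence {sid!r}")
    out = []
    for rec in sequences:
        spans = by_id.get(rec.id)
        if not spans:
            out.append(rec)
            continue
        chars = list(rec.seq)
        for s, e in spans:
            if not (0 <= s < e <= len(chars)):
                raise ValueError(f"occurrence [{s}, {e}) out of range for {rec.id!r}")
            chars[s:e] = "N" * (e - s)
        out.append(SequenceRecord(rec.id, "".join(chars), origin=rec.origin,
                                  clipped=rec.clipped))
    return out


def _pcc_align_score(p1: PWM, p2: PWM) -> float:
    """Mean-column-PCC alignment score used for deduplication.

    Requires the overlap to cover at least 3/4 of the shorter motif, so two
    motifs sharing only a short word are not collapsed.
    """
    from .annotate import align_pwms

    min_overlap = max(4, int(round(0.75 * min(p1.width, p2.width))))
    try:
        return align_pwms(p1, p2, min_overlap=min_overlap)[2]
    except ValueError:
        return -1.0


def _make_result(pwm_final: PWM, all_records: list[SequenceRecord],
                 eval_set: list[SequenceRecord], config: DiscoveryConfig,
                 bg: Background, name: str, round_no: int) -> MotifResult:
    eval_fit = fitness(pwm_final, eval_set, config.p_threshold, bg)
    occs = scan(pwm_final, all_records, config.p_threshold, bg, both_strands=True)
    W_all = _count_valid_windows(all_records, pwm_final.width)
    fold = len(occs) / (W_all * config.p_threshold) if W_all else 0.0
    palindromic = _pcc_align_score(pwm_final, reverse_complement(pwm_final)) >= config.dedup_pcc
    named = PWM(name, pwm_final.probs, source=pwm_final.source)
    return MotifResult(named, occs, eval_fit.logE, fold, len(occs),
                       palindromic=palindromic, round=round_no)


def discover_motifs(sequences: Sequence[SequenceRecord],
                    config: DiscoveryConfig | None = None,
                    seq_weights: Sequence[float] | None = None) -> list[MotifResult]:
    """Iterative discovery: seed -> evolve -> report best motif -> mask -> repeat.

    Stops when no motif passes the logE cutoff or ``max_motifs`` is reached.
    A motif aligning to a previously reported one (mean column PCC >=
    ``dedup_pcc``, either orientation) is not reported again; palindromic
    motifs (self reverse-complement alignment above the same threshold) are
    reported once with a flag.
    """
    config = config or DiscoveryConfig()
    sequences = list(sequences)
    if len(sequences) < 10:
        warnings.warn("fewer than 10 sequences: motif discovery will be unreliable")
    rng = np.random.default_rng(config.seed)
    bg = Background.from_sequences([r.seq for r in sequences]) \
        if config.background == "observed" else Background()

    perm = rng.permutation(len(sequences))
    half = len(sequences) // 2
    train_idx = perm[:half]
    eval_idx = perm[half:]
    weights_arr = None
    if config.enrichment_weighting and seq_weights is not None:
        seq_weights = np.asarray(seq_weights, dtype=float)
        weights_arr = seq_weights / max(seq_weights.mean(), 1e-12)

    masked = sequences
    results: list[MotifResult] = []
    for round_no in range(1, config.max_motifs + 3):
        if len(results) >= config.max_motifs:
            break
        train = [masked[i] for i in train_idx]
        eval_set = [masked[i] for i in eval_idx]
        try:
            pop = seed_population(masked, config.k_range, config.max_spacer,
                                  config.n_pop, rng, bg)
        except ValueError:
            break
        wt = weights_arr[train_idx] if weights_arr is not None else None
        winners = evolve(pop, masked, config, rng, train=train, eval_set=eval_set,
                         background=bg, weights=wt)
        if not winners:
            break
        best = winners[0]
        refined = em_refine(best.refined_pwm, train, max_iter=config.em_iters_final,
                            prior=config.prior,
                            weights=wt[: len(train)] if wt is not None else None,
                            background=bg)
        trimmed = trim(refined, config.ic_min, bg)
        result = _make_result(trimmed, masked, eval_set, config, bg,
                              f"m{len(results) + 1}", round_no)
        if result.logE > config.logE_cutoff or result.n_sites == 0:
            break
        duplicate = any(
            max(_pcc_align_score(result.pwm, prev.pwm),
                _pcc_align_score(result.pwm, reverse_complement(prev.pwm)))
            >= config.dedup_pcc
            for prev in results)
        masked = mask(masked, result.occurrences)
        if not duplicate:
            results.append(result)
    return results


def seeded_discover(pwm0: PWM, sequences: Sequence[SequenceRecord],
                    config: DiscoveryConfig | None = None,
                    seq_weights: Sequence[float] | None = None) -> MotifResult:
    """Refinement initialized from a user PWM, skipping the GA entirely.

    The seed PWM guides only the initialization; EM updates are unconstrained.
    The result may be unfit (logE above the cutoff) if the motif is absent.
    """
    config = config or DiscoveryConfig()
    sequences = list(sequences)
    rng = np.random.default_rng(config.seed)
    bg = Background.from_sequences([r.seq for r in sequences]) \
        if config.background == "observed" else Background()
    perm = rng.permutation(len(sequences))
    half = len(sequences) // 2
    train = [sequences[i] for i in perm[:half]]
    eval_set = [sequences[i] for i in perm[half:]]
    weights_arr = None
    if config.enrichment_weighting and seq_weights is not None:
        sw = np.asarray(seq_weights, dtype=float)
        weights_arr = (sw / max(sw.mean(), 1e-12))[perm[:half]]
    seeded = PWM(pwm0.name, pwm0.probs, source="seeded")
    refined = em_refine(seeded, train, max_iter=config.em_iters_final,
                        prior=config.prior, weights=weights_arr, background=bg)
    trimmed = trim(refined, config.ic_min, bg)
    return _make_result(trimmed, sequences, eval_set, config, bg,
                        f"{pwm0.name}_seeded", 1)
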