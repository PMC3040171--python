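# chipmotif

An integrated toolkit for analyzing transcription-factor ChIP-Seq
experiments: it detects binding events from directional aligned reads,
discovers the DNA motifs enriched under those events de novo, and
annotates/validates the motifs against reference databases with spatial
statistics. It is aimed at computational biologists who want the three
stages of a ChIP-Seq workflow — peak calling, motif discovery, motif
interpretation — as one coherent, scriptable library with a thin CLI,
fully testable on synthetic data with known ground truth.

## The models

**Binding events.** In ChIP-Seq, reads pile up on opposite strands flanking
each protein–DNA contact. Within a candidate region, forward and reverse
5′ read coordinates are modeled as a K-component mixture of shifted
Student-t densities with shared weights,

    forward: Σ_k w_k t_ν(μ_k − δ_k/2, σ²_fk),  reverse: Σ_k w_k t_ν(μ_k + δ_k/2, σ²_rk),

where μ_k is the binding position and δ_k ≈ the mean fragment length, with
a Normal(ξ=175, 50²) prior on δ and inverse-gamma priors on the spreads.
Parameters are fitted by MAP-EM; K is selected by BIC, which resolves
closely adjacent events that single-peak callers merge. Non-mappable
stretches are handled by truncating and renormalizing each component
density over the mappable subset (with expected read-loss imputation in
the M-step), which removes the location bias that read "holes" otherwise
cause. Events get an enrichment score relative to an optional control
sample, and an FDR-vs-score curve from a treatment/control exchange run.

**Motif discovery.** A genetic algorithm over *spaced dyads* (two short
words separated by a spacer) seeds candidate motifs from over-represented
words; each candidate is converted to a position weight matrix and refined
by ZOOPS EM; fitness is a log E-value built from the exact PWM
score-distribution (dynamic-programming convolution on a 1e-3-log2 grid,
so scan p-values are exact to the grid). Sites of each reported motif are
masked and the search repeats — yielding multiple motifs, dimers and
monomers, with automatic width trimming. A seeded mode refines a
user-supplied PWM directly, skipping the GA (~an order of magnitude
faster), for re-finding known motifs.

**Annotation.** Discovered PWMs are aligned to a reference database
(JASPAR/TRANSFAC flat formats) under a column-correlation similarity with
E-values calibrated on simulated (column-shuffled) null profiles. Motifs
can be filtered by name/E-value, "virtually" combined under one label
without modifying the PWMs, and validated spatially: distributions of
occurrence distances to predicted binding positions (relevant motifs
concentrate at peak centers; artifacts are flat) and pairwise
motif–motif distance distributions with co-occurrence fractions, the
building blocks for spotting cis-regulatory modules.

A `simulate` module generates directional reads around planted events and
background sequences with planted PWM sites — byte-reproducible given a
seed — so every claim above is exercised against known truth.

## Worked example

```python
import numpy as np
from chipmotif import simulate, peakcall, discover, annotate
from chipmotif.pwm import PWM

# plant an AP-1-like motif under 100 binding events on a toy chromosome
probs = np.full((4, 8), 0.1 / 3)
for j, b in enumerate("TGACTCAT"):
    probs["ACGT".index(b), j] = 0.9
ap1 = PWM("AP1_like", probs)

events = [("chr1", 5000 * (i + 1)) for i in range(100)]
treatment, control, truth = simulate.sim_reads(
    events, {"chr1": 510_000}, noise_rate=2e-3, rng=42)
calls = peakcall.call_peaks(treatment, control)
print(f"{len(calls)} binding events called from "
      f"{len(treatment)} treatment / {len(control)} control reads")
top = calls[0]
print(f"top event: mu={top.mu:.0f}  delta={top.delta:.0f}  "
      f"score={top.score:.1f}  95% CI [{top.ci_lo:.0f}, {top.ci_hi:.0f}]")

regions, site_truth = simulate.sim_sequences(
    len(calls), 400, motifs=[(ap1, 0.7, ("center", 25.0))], rng=42)
results = discover.discover_motifs(
    regions, discover.DiscoveryConfig(n_pop=50, n_gen=3, max_motifs=3, seed=42))
for m in results:
    print(f"motif {m.pwm.name}: consensus={m.pwm.consensus()}  "
          f"logE={m.logE:.1f}  sites={m.n_sites}  fold={m.fold_enrichment:.1f}")

summary = annotate.distance_to_peak(
    results[0].occurrences, {r.id: 200.0 for r in regions})
within = summary.counts[(summary.bin_centers >= -60) & (summary.bin_centers <= 60)].sum()
print(f"{100 * within / summary.n_total:.0f}% of occurrences within 60 bp of centers")
```

Output:

```
100 binding events called from 11022 treatment / 1014 control reads
top event: mu=269999  delta=173  score=105.0  95% CI [269995, 270002]
motif m1: consensus=ATGAGTCA  logE=-54.2  sites=62  fold=3.9
79% of occurrences within 60 bp of centers
```

All 100 planted events are recovered (the top one within a few bp of its
true position at 270,000, with δ̂ ≈ 173 matching the simulated ~175-bp
fragments); discovery returns exactly one motif — the reverse complement
of the planted AP-1-like consensus, strand is arbitrary — with a strongly
negative log E-value, and its occurrences concentrate at the window
centers, the signature of a directly bound motif.

The same pipeline is available from the shell:

```bash
chipmotif simulate reads --n-events 20 -o sim/
chipmotif callpeaks --treatment sim/treatment.bed --control sim/control.bed -o events.tsv
chipmotif extract --genome genome.fa --peaks events.bed --width 400 -o regions.fa
chipmotif discover --fasta regions.fa --rng 42 -o motifs/
chipmotif annotate --motifs motifs/motifs.transfac --db jaspar.txt -o report/
```

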