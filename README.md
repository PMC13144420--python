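# chemnuc

Analysis pipeline for **chemical nucleosome mapping**: from strand-specific
cleavage counts to single-base nucleosome dyad scores, unique/redundant
nucleosome maps, occupancy tracks, and the comparative statistics used to
contrast two chromatin conditions (e.g. interphase vs mitotic chromatin).

Chemical mapping engineers a cysteine into histone H4 (H4S47C) so that a
tethered copper–phenanthroline complex cleaves nucleosomal DNA at fixed
offsets from the dyad — the central base pair of the 147-bp wrap.  Each
strand is cut predominantly at strand-local offset −1 (primary site) and
secondarily at +6, which in reference coordinates places Watson cuts at
dyad −1/+6 and Crick cuts at dyad +1/−6.  Pairing cleavage peaks across
strands therefore produces three characteristic Crick−Watson distances:

| pairing               | lag (nt) |
|-----------------------|----------|
| primary–primary       | +2       |
| mixed                 | −5       |
| secondary–secondary   | −12      |

## What the package computes

- **NCP scores** — per-base nucleosome-center-positioning evidence via a
  fixed-offset template: `S_w(i) = w_p·watson[i−1] + w_s·watson[i+6]`,
  `S_c(i) = w_p·crick[i+1] + w_s·crick[i−6]`, `NCP(i) = √(S_w·S_c)`.
  The geometric mean requires support on both strands, suppressing
  single-strand artifacts.
- **Unique map** — greedy caller: repeatedly take the highest-scoring
  position ≥ 120 bp from all previous calls, then keep the top 90% by
  score.  **Redundant map** — every position scoring at least the unique
  map's minimum.
- **Occupancy** — redundant scores smoothed with a Gaussian kernel
  (σ = 20 bp, unit mass); an MNase variant smooths fragment-midpoint
  counts identically.
- **Comparative statistics** — sliding-window Pearson correlation (501 bp,
  1-bp step), ECDF summaries, 1-kb bin classification at r ≤ 0.15,
  region-of-interest enrichment (odds ratio, log₂ OR, χ² df = 1), and Wald
  tests on differences of short-linker (<30 bp) log odds ratios:
  `z = (logOR₁ − logOR₂)/√(SE₁² + SE₂²)`, `SE = √(1/a + 1/b + 1/c + 1/d)`.
- **Feature profiles** — anchor-centered aggregation (TSS, enhancers, CTCF
  motifs, exon boundaries), expression-quartile stratification, K-means
  clustering of per-site profiles, unique-nucleosome count differences,
  AA/TT/AT/TA dinucleotide periodicity, PWM refinement of peak centers.
- **Mechanics** — aggregation of DNA cyclizability (C-score) tracks around
  dyads, contrasting the dyad window (|d| ≤ 20 bp) with the shoulder band
  (42–73 bp), with G-band stratification.
- **Synthetic data** — fully ground-truthed toy datasets: genomes, planted
  two-condition landscapes with 10n+5-periodic linkers, regulatory
  repositioning, barrier loss with anti-phased arrays, fragile
  nucleosomes, chemical/MNase fragment BEDs under the −1/+6 cleavage
  model, and C-score tracks with dyad- or shoulder-enriched bendability.

## Worked example

Run the full two-condition pipeline on a synthetic 600-kb genome
(condition A ≈ dynamic/interphase-like, B ≈ compact/metaphase-like):

```sh
chemnuc run --outdir demo --seed 115
```

or equivalently from Python:

```python
from chemnuc.pipeline import RunConfig, run_pipeline, verify
cfg = RunConfig(outdir="demo", chrom_length=600_000, n_fragments=400_000,
                regulatory_every=5, barrier_every=5, seed=115)
run_pipeline(cfg)
verify("demo")
```

With these settings the run prints/writes (`demo/summary.json`):

- planted dyads 3208 (A) / 3198 (B); unique calls 2932 / 2925 after the
  top-90% retention;
- cleavage-lag spectrum top-3 modes `[2, -5, -12]` in both conditions —
  the primary–primary, mixed, and secondary–secondary pairings;
- 93.0% of scoreable positions with local correlation ≥ 0.5, and 29 of
  588 valid 1-kb bins classified low-correlation (r ≤ 0.15); these low
  bins are strongly enriched in planted regulatory regions (OR = 20.5,
  log₂ OR = 4.36, χ² p ≈ 2×10⁻¹⁷);
- short-linker odds ratio A vs B of 3.85 in regulatory regions vs 1.00 in
  stable regions; one-sided Wald comparison z = 4.89, p ≈ 5×10⁻⁷;
- a mean gain of 0.58 unique nucleosomes per ±1-kb regulatory window in
  condition A;
- shoulder−dyad C-score difference +0.298 in condition A regulatory
  nucleosomes (shoulder-enriched bendability) vs −0.294 in condition B
  (dyad-enriched), with shoulder peaks at ±57 bp.

`verify("demo")` re-checks dyad recovery, the ≥120-bp spacing invariant,
the lag triad, the regulatory short-linker test, the unique-count gain and
the mechanics discrimination against the planted truth (all pass above).

## Layout

```
src/chemnuc/
  io_formats.py         FASTA/BED/bedGraph/wiggle/GTF-lite/cytoband/PFM IO
  synthetic_data.py     ground-truthed landscape + fragment + C-score simulators
  ncp_scoring.py        cleavage counting, lag spectrum, NCP deconvolution
  nucleosome_maps.py    greedy caller, redundant map, occupancy, linkers, matching
  comparative_stats.py  local correlation, binning, enrichment, Wald tests
  feature_profiles.py   anchor profiles, K-means, periodicity, PWM scanning
  mechanics.py          C-score dyad/shoulder statistics, G-band strata
  pipeline.py, cli.py   orchestration, manifest/verify, `chemnuc` CLI
```

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
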