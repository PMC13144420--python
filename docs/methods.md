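# Methods

This note documents the models, conventions and parameter choices behind
`chemnuc`, and what the synthetic-data tests do and do not demonstrate
about real chemical-mapping data.

## Coordinates and containers

All coordinates are 0-based half-open; BED-family files are read natively
and GTF-lite input (1-based inclusive) is converted on read.  Dense tracks
carry an explicit coverage mask: zero is a legal value, distinct from
missing.  Fragments enter as BED intervals `[s, e)`; by convention a
fragment records a Watson-strand cleavage at `s` and a Crick-strand
cleavage at `e − 1`.  The simulator and the scorer share this convention
by contract (round-trip tested).

## Cleavage geometry and NCP scoring

A nucleosome dyad at reference position `D` is cleaved on each strand at
strand-local offsets −1 (primary, weight `w_p`) and +6 (secondary, weight
`1 − w_p`).  Strand-local means measured 5′→3′ along that strand, so the
mapping to reference coordinates is: Watson cut at `D + d`, Crick cut at
`D − d`.  Crick cuts therefore sit at reference `D + 1` and `D − 6`, and
the Crick-minus-Watson lag spectrum `score(d) = Σᵢ crick[i]·watson[i−d]`
has modes at `+2` (primary–primary), `−5` (both mixed pairings coincide)
and `−12` (secondary–secondary).  The sign convention `d = crick − watson`
is what yields this triad.

The NCP score inverts this geometry with a fixed-offset template:

    S_w(i) = w_p·watson[i−1] + w_s·watson[i+6]
    S_c(i) = w_p·crick[i+1] + w_s·crick[i−6]
    NCP(i) = sqrt(S_w(i) · S_c(i))

The geometric mean enforces both-strand support: a pile-up on one strand
alone scores zero.  For noise-free counts concentrated at the four offsets
of a dyad `D`, `NCP(D) = (w_p² + w_s²)·n` per strand-normalized count `n`,
strictly exceeding the satellite values `w_p·w_s·n` at `D ± 7`, so the
dyad is the unique local argmax for any `w_p`.  This scorer is a
documented, fully testable stand-in for iterative deconvolution: the
cleavage geometry is specified, the deconvolution internals are not.
Positions within template reach (6 bp) of chromosome ends are masked.
Optional background normalization divides by the mean total cleavage in a
±500-bp window plus ε = 0.5; it is off by default for simulations.

`estimate_template` re-fits `w_p` from cleavage counts at the two fixed
offsets around ≥100 provisional dyads (one refinement round; the offsets
themselves stay fixed).

## Nucleosome maps, occupancy, linkers

The **unique map** is called greedily: take the highest-scoring position,
exclude ± (120 − 1) bp, repeat while positive scores remain; ties break
leftmost.  The top `floor(0.9·n)` calls by score are retained (boundary
ties leftmost).  Note that at realistic spacing (~180 bp, i.e. below twice
the 120-bp exclusion) the caller emits essentially only true dyads, so the
top-90% retention removes ~10% of genuine calls by definition; recovery
benchmarks therefore evaluate the unfiltered call set, and the retention
is checked separately through the spacing invariant.

The **redundant map** is every position with NCP ≥ the unique map's
minimum score (a superset of the unique map).  **Occupancy** convolves the
redundant scores with a Gaussian kernel, σ = 20 bp, truncated at ±73 bp
(half a nucleosome) and normalized to unit mass.  A "weighted average"
with a constant full-window denominator differs from this unit-normalized
weighted sum only by a global constant, so correlations and profiles are
unaffected; we implement the normalized sum.  The MNase variant replaces
scores by fragment-midpoint counts (`midpoint = start + floor((len−1)/2)`)
under the same kernel.

**Linkers** are adjacent unique-dyad spacings minus 147 bp; negative
values (possible down to −27 at 120-bp spacing) are reported, not
clipped.  **Map matching** uses mutual nearest neighbours within 73 bp
(exposed); "identically positioned" uses the smaller map as denominator.
Both rules are package choices where the field's usage is loose.

## Comparative statistics

Local correlation is Pearson r over a centered 501-bp window at 1-bp
steps, computed with sliding sums; windows that are edge-truncated or have
(numerically) zero variance in either track are invalid — no shrunken
windows.  Bins are consecutive 1000-bp tiles; a bin is valid iff both
tracks have nonzero variance within it, and low-correlation means
r ≤ 0.15.  Enrichment tables use bins whose ROI overlap is ≥ 500 bp;
χ² is the uncorrected df = 1 statistic `N(ad−bc)²/∏margins` (Yates
correction deliberately not applied; exposed as an option would be
redundant since the closed form is tested).  Zero cells receive the
Haldane–Anscombe +0.5 on all four cells and the result is flagged.  Wald
comparisons between groups use natural-log odds ratios with
`SE = sqrt(1/a + 1/b + 1/c + 1/d)` and one-sided p-values (the scientific
question is "greater than"); two-sided values are also reported.  No
multiple-testing correction is applied by default; Benjamini–Hochberg is
available as a helper.

## Profiles, periodicity, motifs

Anchor profiles are strand-oriented (minus-strand rows reversed) with
per-column valid counts; anchors whose window leaves the genome are
dropped and counted.  Expression strata: FPKM = 0 is "no expression",
quartiles are computed among expressed genes only, and boundary ties go to
the lower group.  K-means uses k-means++ with a fixed seed, 10 restarts,
≤300 iterations; rows are not z-normalized by default (normalization
changes the clusters and is exposed as a flag); centroids are reported in
decreasing cluster-size order.  Count windows around anchors are closed on
both ends (`[pos−flank, pos+flank]`).

Periodicity detection linearly detrends the series and takes the power
argmax on a zero-padded (4096-point) Fourier grid within the candidate
period range; the phase comes from the complex coefficient at the
dominant period, mapped back to the x-origin of the series.  The power
ratio (peak over median power) must exceed 4 for a detection to be
flagged significant; numerically flat series report ratio 1.

PWMs are built from count matrices with a pseudocount of 0.8 split by the
background composition (uniform 0.25 unless given), log base 2.  Motif
refinement scans every placement on both strands; the refined center is
`start + floor(L/2)` of the best hit, ties resolving leftmost with +
strand first (numerical ties within 1e-9 are treated as exact, so the
result matches an exact-arithmetic scorer).

## Mechanics (C-scores)

C-scores are consumed, never predicted — the bendability predictor is out
of scope; synthetic tracks stand in for it.  Profiles average the track at
each dyad-relative offset with per-offset denominators, so dyads with
partially masked flanks still contribute where data exist.  The dyad
window is |d| ≤ 20 bp and the shoulder band 42–73 bp inclusive, pooled
over both sides by default (per-side output supports asymmetric shoulder
placement).  G-band stratification assigns each dyad its containing
cytoband's stain class; acen/gvar/stalk bands are excluded with counts.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes;
its defaults are the package's study conditions.

- **Linkers**: a mixture of a 10n+5 periodic component (10·K + 5 with K
  Poisson, mean 3 → mean periodic linker 35 bp) at weight 0.7 and a
  uniform 5–65 bp smooth component.  Mean linker ≈ 35 bp, mean spacing
  ≈ 182 bp — a realistic nucleosome repeat.  The exact mixture pmf is
  available for goodness-of-fit testing.
- **Regulatory regions** (condition A): linkers from a short-biased
  mixture — weight 0.8 on truncated 10n+5 values {5, 15, 25}, 0.2 on
  uniform 35–115 bp gaps — giving ≈74% linkers ≤ 30 bp, mean spacing
  ≈ 173 bp, and a mean unique-nucleosome gain of ≈0.5 per ±1-kb window
  relative to condition B (derived analytically from
  `2000·(1/s_A − 1/s_B)` before any benchmarking).  Fragility flags are
  set on 30% of regulatory condition-A dyads; the MNase protection factor
  for fragile nucleosomes defaults to 0.1 — a free parameter, not a
  published value.
- **Barrier regions**: condition A places a dyad exactly on the anchor
  with arrays phased off it; condition B omits it and starts its flanking
  arrays at anchor ± half the mean spacing (≈91 bp), i.e. anti-phased.
- **Stable regions**: identical dyad positions *and* identical sampling
  weights in both conditions (per-dyad abundances are Gamma(4, 0.25)).
- **Fragments**: each chemical fragment pairs a Watson cut at one dyad
  with a Crick cut at the next dyad downstream (length ≈ one repeat,
  constrained to 100–300 bp), offsets drawn ∝ (w_p, w_s) with Gaussian
  jitter (default sd 0.5 bp) plus a 5% uniform background.  Where a dyad
  has no reachable neighbour (chromosome ends; gaps wider than the
  allowed fragment length) the partner cut is placed at a fixed auxiliary
  anchor recorded in the truth manifest — this guarantees every planted
  dyad receives cuts on both strands, which is what makes exact noise-free
  recovery achievable; auxiliary anchors receive cuts on only one strand,
  so they can never masquerade as dyads (their coincidence is explicitly
  prevented).
- **C-score tracks**: Gaussian baseline noise plus per-dyad bumps — one at
  the dyad (sd 10 bp) or two at ±57 bp (the 42–73-bp band midpoint,
  sd 8 bp) depending on the region mode.

What the generator does **not** model: sequencing errors, PCR duplicates,
mappability, replication timing, GC bias, chromatin fibre structure.
Passing tests therefore demonstrate the correctness of the analysis
machinery and its behaviour under the stated noise model, not performance
on real libraries.

## Pipeline, seeds, problem sizes

A single `RunConfig` records every parameter with its standard default
(min spacing 120, keep fraction 0.90, σ 20 bp, window 501, bin 1000,
threshold 0.15, linker cutoff 30, flanks ±1000, w_p 0.75).  One global
seed fans out to per-stage seeds by hashing the stage name, so stages are
independently reproducible; reruns are byte-identical.  Every artifact is
listed in a JSON manifest with SHA-256 checksums, and `verify` re-checks a
run against its planted truth.

The bundled benchmarks use desk-scale problem sizes chosen to make the
statistics well-resolved while keeping runs interactive: 150–600-kb
genomes with 10⁵–4×10⁵ fragments for geometry and statistics, a 2-Mb
genome with 8×10⁵ fragments (≈65 regulatory windows) for the two-condition
contrast, and a 2-Mb genome at 200 fragments per nucleosome (≈2.2M
fragments) for recovery benchmarking.  Genome-scale figures from billions
of reads (e.g. tens of millions of called nucleosomes) are out of reach at
desk scale by design; the pipeline checks the corresponding *properties*
(lag triad, recovery, enrichment directionality, periodicity) instead.

## Known limitations

- The template NCP scorer is linear with fixed offsets; it does not
  deconvolve overlapping dyads closer than ~7 bp (the unique-map spacing
  makes this moot downstream, but the redundant map carries satellite
  positions at ±7 bp of strong dyads).
- Bin-level correlation ignores spatial autocorrelation between
  neighbouring bins; p-values are per-table, uncorrected.
- The ±1-kb unique-count window is closed on both ends; a half-open
  reading would differ by boundary dyads.
- Multi-chromosome spectra are pooled, not per-chromosome.
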