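# Methods

## Coordinate conventions

Every coordinate in the library is 0-based, half-open `[start, end)` —
the native convention of BED and UCSC chain files. Conversion to other
conventions (e.g. Ensembl's 1-based TSS positions) is the caller's
responsibility at the I/O boundary; the TSS reader documents its input as
already 0-based. The center of an even-width interval is
`floor((start+end)/2)`. Two intervals overlap when they share at least
one base; touching intervals (`end == start`) do *not* overlap but *are*
merged by `merge_intervals`, so a merged region is the closure of the
covered-base union. Printed percentages round half away from zero
(93.53 → 94, 86.52 → 87, 1.72 → 2), implemented in pure integer
arithmetic to avoid float-representation surprises at exact halves.

## Units of comparison

The unit of hotspot identity is the **center window**: the ±`halfwidth`
interval around the hotspot midpoint, clamped at chromosome bounds.
`halfwidth` defaults to 200 bp everywhere, giving the 400-bp windows used
for both same-assembly strain comparison and cross-species conservation.

"Overlapping within ±200 bp of the centers" admits two readings: window
overlap (|Δcenter| < 400 bp) or strict center distance (|Δcenter| ≤
200 bp). We implement window overlap as the default — it is the reading
consistent with treating the central 400-bp regions as the objects whose
overlaps are counted in the cross-species step, so one rule serves both
analyses — and expose the strict rule as an option
(`rule="center-distance"`). Sharing is reported directionally for both
sets, since A-in-B and B-in-A percentages differ whenever set sizes or
multiplicity differ.

## Liftover

`lift_interval` follows UCSC liftOver semantics:

* `minMatch` (default 0.1) is the minimum fraction of the interval's
  bases that must have an aligned image *through a single chain*. Mapped
  bases are counted by block intersection, which is provably equal to
  per-base enumeration and is what the brute-force oracle in the test
  suite checks.
* The mapped interval is the + strand span from the leftmost to the
  rightmost image, so insertions in the query (dq gaps) inflate
  `converted_length` above `mapped_bases` — the basis of the >800 bp
  exclusion rule for 400-bp windows (a converted span more than twice the
  window indicates a large gap inside it).
* Minus-strand chains store query coordinates counted from the 3' end;
  every reported image is converted to + strand via
  `pos' = q_size − 1 − raw`.
* When several chains cover an interval, the default `best-chain` policy
  takes the chain mapping the most bases (ties broken by higher chain
  score). If two chains *each* independently reach `minMatch`, the
  mapping is not attributable to a single locus and is failed with status
  `split_across_chains` (the analogue of liftOver's "Duplicated in new");
  a strict `reject` policy that fails any multi-chain coverage is
  available for testing.

`remap_center_windows` counts successes first and applies the
converted-length exclusion second, reporting both tallies
(`n_remapped`, `n_excluded_long`) so either accounting convention can be
read off the report.

## Conservation and promoters

Center windows of the lifted set and the native set that overlap each
other (≥ 1 bp) are pooled and merged into **conserved regions**; each
hotspot is conserved iff its window intersects a conserved region. Merging
can chain a window into a conserved region it did not directly overlap;
this matches the merged-region definition and affects only densely packed
sets. The category counts partition each input set; the lifted set's
denominator is the post-remap, post-exclusion count, and the native set's
is all called hotspots (both denominators are emitted).

Promoter windows are strand-aware: `[t − 2000, t + 200)` on + strand,
`[t − 200, t + 2000)` on −, clamped at chromosome bounds, with an
optional biotype filter (e.g. coding genes only) applied before window
construction. Hotspot-to-region co-localization defaults to
**center-in-region** — point containment is insensitive to called peak
widths, which vary strongly between calling pipelines — with full-interval
`any-overlap` as a flag. Cross-species promoter conservation merges
overlapping promoter windows of the two species, then cross-tabulates the
merged conserved promoters against hotspot centers (either species) and
conserved regions.

## Karyotype arithmetic

With one obligatory crossover per autosomal arm, the per-cell minimum is
`acrocentric + 2·(autosomes − acrocentric)` (single-armed acrocentrics
contribute one arm). Constants for the rat (20 autosomes, 8 acrocentric →
minimum 32) and mouse (19, all acrocentric → 19) karyotypes are provided;
the mean rate per autosome is plain division (27.4 nodules/cell over 20
autosomes → 1.37). Sex chromosomes are excluded throughout.

## Synthetic data

The generator emulates the *shape* of the real inputs, not their
sequence content:

* **Assembly pairs.** The derived genome is the source genome with
  planted deletions, insertions and inversions (non-overlapping,
  ≥ 1 bp apart, off the chromosome ends so chain blocks stay non-empty).
  One plus-strand chain per chromosome carries the colinear blocks;
  each inversion emits an additional single-block minus-strand chain, so
  the strand-flip code path is exercised exactly as by real
  `over.chain` files. The `TrueMap` oracle stores the piecewise segment
  map and is consistent with the emitted chain by construction; tests
  verify the agreement exhaustively, base by base.
* **Hotspot pairs.** `⌊f·n⌋` latent sites are shared; every latent site
  (shared or strain-specific) is placed with pairwise separation
  ≥ `min_separation` using per-chromosome spacing sampling, so at the
  default 50-bp jitter (≪ the 200-bp halfwidth) the planted fraction is
  recovered essentially exactly and false sharing cannot occur.
  Strengths are log-normal; shared pairs draw from a Gaussian copula
  with latent Pearson `ρ = 2·sin(π·r_s/6)` to plant a target Spearman
  `r_s`. X-linked strengths are drawn at a planted multiple (default 2×)
  of the autosomal distribution, emulating the single-X coverage
  asymmetry in males. Hotspot widths are drawn from 300–2000 bp so
  center-in and any-overlap rules are distinguishable.
* **Promoter landscapes.** A planted fraction `p` of hotspots each get a
  gene whose promoter window covers their center and no other center;
  remaining genes are placed clear of all centers. Genes are placed
  around fixed hotspots (rather than moving hotspots into promoters) so
  hotspot spacing guarantees survive; placement uses bounded rejection
  sampling and raises `SpecInfeasibleError` rather than silently degrade.

Default scenario parameters — 2000 hotspots per strain on a ~13-Mb
four-chromosome genome (the problem size used throughout the tests and
the acceptance script), shared fraction 0.88 for a same-allele strain
pair and 0.03 for a different-allele pair, Spearman 0.8 on shared
strengths, 40% orthologous sites and 40% of hotspots at promoters for
the cross-species scenario — mirror the relative magnitudes of the real
strain and species comparisons at a scale where every quantity is
recomputable in seconds.

What the generator does **not** model: sequence content and motifs, read
sampling noise in strengths beyond the log-normal, hotspot width/strength
correlation, clustered or telomere-biased hotspot placement, chain
fragmentation from repetitive DNA, and many-to-many orthology. Passing
tests therefore demonstrate correctness of the interval arithmetic,
liftover geometry and bookkeeping under known truth — not robustness to
every artefact of real SSDS data.

All randomness flows from a single `numpy` generator seeded by
`SimSpec.seed`; identical specs give byte-identical outputs.

## Numerical and degenerate-input choices

* Empty hotspot sets: remap reports carry `n_input = 0` with the percent
  omitted; fraction queries on empty sets raise `UndefinedFractionError`
  rather than return 0, since 0/0 is a contract violation, not a rate.
* Rank correlation requires ≥ 3 pairs (`InsufficientPairsError` below).
* One-to-one pairing for the correlation resolves many-to-many window
  overlaps greedily by center distance, ties broken toward the lower
  coordinate — deterministic and independent of input order.
* Missing/unparsable BED strength fields become 0 with no error; missing
  chain arithmetic is always an error (`CorruptChainError` naming the
  chain), because a mis-summed chain silently corrupts every downstream
  coordinate.
* Chromosome-name normalization ("1" vs "chr1") is opt-in; silent
  aliasing hides genuine assembly mismatches.

## Known limitations

* `lift_interval` reproduces liftOver's single-region behaviour, not its
  `-multiple` mode; split mappings are reported as failures, not emitted
  as fragments.
* Conservation denominators follow one convention (see above); totals
  printed in reports always come from the input data, never from
  externally quoted figures.
* `RegionIndex` bisection is O(log n) per query over merged runs — ample
  for tens of thousands of regions, not tuned for billions.
* The pseudoautosomal region cannot be treated specially (it is
  unannotated in the rat reference); sex chromosomes are simply excluded
  from strength correlation and karyotype arithmetic.
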