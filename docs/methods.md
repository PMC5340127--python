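# Methods

## The enrichment statistic

`repeatpeaks` tests whether a set of ChIP-seq peak summits falls inside a
repeat family (or a specific repeat element) more or less often than chance.
The observed statistic is the grouped overlap count between fixed-width
windows centred on peak summits (default 100 bp) and the repeat annotation.
Chance is an empirical Monte-Carlo null: `n_sets` random interval sets
(default 500), each matching the observed window set in interval count and
length multiset, are placed uniformly over the genome and counted
identically. With null mean *m* and sample standard deviation *s* the
Z-score is computed on whichever side the observation falls,

    obs <= m :  z = (obs - m) / s
    obs >  m :  z = (m - obs) / s

so *z* ≤ 0 always, and the one-tailed p-value is Φ(z) (standard normal CDF,
never doubled, so p ≤ 0.5). A direction flag carries the tail: `+` when the
observed count exceeds the null mean (enrichment), `-` when it falls below
(under-representation), `none` at exact equality.

**Calibration property.** Because the statistic folds both tails into one
sign, the null probability of p < α is α *per direction* and 2α over both
directions jointly. A p < 0.05 call is therefore a nominal-5% test of
enrichment and, separately, a nominal-5% test of depletion; consumers who
want a single two-sided family-wise rate should halve α or enable the
Benjamini–Hochberg option. The replicated calibration experiment in the
test suite confirms both per-direction rates empirically.

**Degenerate null.** When the null variance is zero the deviation cannot be
scaled: equality reports (z = 0, p = 0.5, `none`); any deviation reports
z = −∞ with p = 0, the appropriate direction, and a warning. p-values below
1e−300 render as `0` in written reports; the stored float keeps the
underflowed value.

**Null-model assumptions.** Random intervals are placed chromosome-first
(probability proportional to chromosome length, restricted to chromosomes
long enough for the drawn interval) and uniformly within the chromosome.
Intervals may overlap one another; no assembly-gap or blacklist masking and
no GC matching is applied — the null is the plain uniform-placement model,
deliberately. Each random set's RNG stream is derived from `(seed,
set_index)`, so set *k* can be regenerated in isolation and results are
independent of evaluation order.

## Counting rules

Overlap requires ≥ 1 shared base on the same chromosome; all coordinates are
0-based half-open, so touching intervals do not overlap. Two counting
granularities are offered: `pairs` (every overlapping (window, repeat) pair
counts once — the default, matching a pairwise-intersection listing) and
`distinct_windows` (a window counts at most once per key). Strand is ignored
throughout. Features lacking a family assignment (bare names in name-encoded
BED) join element-level statistics only. Keys with a zero observed count but
a nonzero null are retained in the report as depletion evidence; keys never
hit by either are dropped.

The counting engine pre-sorts repeat coordinates per (chromosome, key) and
answers each window batch with two binary searches; the test suite checks it
exactly against a brute-force double loop and against `bedtools intersect`.

## Ancillary procedures

* **Peak selection** — peaks pass on caller scores: FDR ≤ `fdr_max` and/or
  fold enrichment ≥ `ef_min`, combined with `or` (the convention behind
  peak-set definitions like "FDR = 0 or fold change ≥ 15") or `and`. A
  missing FDR fails the FDR criterion.
* **Summit windows** — `[summit − ⌊w/2⌋, summit − ⌊w/2⌋ + w)`, clamped to
  the chromosome (clamping shrinks, never shifts). Width defaults: 100 bp
  for enrichment counting, 200 bp for motif-discovery sequence export.
* **TSS proximity** — distance is min |summit − TSS| over same-chromosome
  TSS entries; proximal iff ≤ 5 kb (inclusive). Peaks on TSS-free
  chromosomes are distal with undefined distance.
* **DEG filters** — `adj_p_fc`: BH-adjusted p < 0.05 AND fold change beyond
  1.5× (BH computed from raw p when no adjusted column is supplied);
  `fpkm_fc`: ≥ 1 FPKM in ≥ 1 sample AND fold change beyond 1.5×. "Beyond"
  is strict and symmetric: max(fc, 1/fc) > 1.5, so a >1.5-fold drop
  qualifies like a >1.5-fold rise.
* **Peak–DEG linkage** — each filtered gene is linked to the nearest peak
  summit by TSS distance and tallied up/down × within/beyond 5 kb.
* **Probe utilities** — printed oligo sequences are normalised (5′-biotin
  tags, 5′/3′ markers and typesetting whitespace stripped); a duplex is
  valid iff the reverse oligo equals the reverse complement of the forward.
* **Fingerprints** — canonical C2H2 fingers match C-x(2,4)-C-x(12)-H-x(3,5)-H,
  scanned left-to-right, leftmost match first, spacers resolved
  shortest-first; matches never overlap. Taking the first conserved
  histidine as helix position 7, the DNA-contact quadruplet (helix
  positions −1, 2, 3, 6) sits at offsets −7, −5, −4, −1 from it; on the
  classic Zif268 finger 1 this extracts R,D,E,R. Degenerate (C2HC,
  long-linker) fingers are out of scope. Fingerprints are compared with
  fingers aligned from the C-terminus backwards; unpaired N-terminal
  fingers are reported, paired fingers contribute Hamming distance over the
  four contact positions.

## Synthetic fixtures

The generator emulates the shape of the real inputs, not their sequence
content. Defaults: a 3-chromosome genome (1 Mb / 500 kb / 250 kb — large
enough for stable nulls, small enough for seconds-scale tests);
non-overlapping repeat features placed by rejection sampling to a family
coverage target (within ±10% relative; mean feature length 500 bp, uniform
±50%); peak sets of 50 summits with a planting rule — a fraction *f* of
summits uniform inside a chosen family's footprint (enrichment) or all
summits uniform over its complement (depletion) — fold enrichment
log-normal (median 20), FDR 0; expression tables with N(0, 0.2) log2
fold-change noise for null genes, 4-fold planted effects, and log-normal
FPKM spanning the 1-FPKM filter boundary; zinc-finger proteins assembled
from canonical finger scaffolds joined by C/H-free linkers so the scanner's
ground truth is exact.

What passing these tests shows: the statistic is calibrated and recovers
planted signal under the uniform-placement null it assumes. What it does not
show: behaviour under real-genome artefacts the null ignores (assembly gaps,
mappability, GC structure, clustered repeats co-locating with open
chromatin), which can make uniform-null p-values anti-conservative on real
data — the standard caveat for this family of randomization tests.

## Experiment sizes and numerical choices

The replicated experiments in the test suite and acceptance script use: 500
calibration replicates (one family at 0.3 coverage, 50 windows, 100 random
sets each; per-direction false-call rate at p < 0.05 expected at the nominal
5%); 200 recovery replicates per direction. The enrichment planting uses a
family at 15% coverage with f = 0.9 — about 5× the ≈0.18 null per-window
hit probability on the default genome (coverage plus the window-length edge
term, 0.15 + n_feat·(w−1)/G) — and depletion uses exclusion from the
0.3-coverage family, whose null mean (~17) is large enough for a one-tailed
p < 0.01 depletion call at 50 windows. Null summaries use the sample (n−1)
standard deviation. Report rows sort by p ascending with ties broken by key
for byte-stable output. Random peak sets and all generators are
bit-reproducible from their seeds; RNG streams are spawned from (seed,
stream-id) pairs so no two stages share a stream.

## Known limitations

* The uniform null ignores gaps, mappability and base composition (by
  design, matching the described procedure); no GC-matched or
  chromosome-preserving shuffle is provided.
* One null (shared random sets) serves all keys of a run; p-values across
  keys are therefore correlated, which is intentional and cheaper than
  independent draws per key.
* No analytical (binomial/hypergeometric) null is offered.
* Element-level and family-level runs use separate calls; within a call the
  granularity is uniform.
* The fingerprint scanner detects canonical C2H2 fingers only.
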