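# Methods

## Model and assumptions

`stratcong` treats a rooted tree topology and a table of taxon first/last
appearances (FAD/LAD, Ma before present; larger = older) as the complete
input.  Branch lengths in input trees are ignored: all node ages are
recomputed by *basic dating*, which assigns every tip its FAD and every
internal node the oldest FAD among its descendant tips.  This is the
construction under which the minimum implied gap (MIG) is defined, and it is
the only time-scaling implemented — the four congruence metrics depend on
implied gaps, not on calibrated branch lengths, so alternative
palaeontological time-scaling methods (Hedman, equal, cal3) are out of
scope.

Polytomies are accepted everywhere a single tree is scored: dating and MIG
generalize unchanged, and for SCI the sister group of a child is the pooled
set of its parent's remaining children.  The extremal bounds Gmin and Gmax
remain defined over fully resolved rooted trees (the published
normalization), so GER and MSM* for a polytomous tree are still measured
against the binary-tree envelope.  The closed forms

- Gmin = max FAD − min FAD (attained by the pectinate tree ordered
  oldest-to-outermost),
- Gmax = Σ over all non-oldest taxa of (max FAD − FAD),

were verified against brute-force enumeration of all rooted binary labeled
topologies (15/105/945 at n = 4/5/6) before being relied on; the test suite
repeats this verification on every run.

FAD ties are legal and tie-safe: SCI counts a sister of equal age as
consistent (an equal-aged sister implies no ghost range), and the bound
formulas need no tie-breaking.  Undefined metrics — GER and MSM* when all
FADs coincide, RCI when every taxon is a point occurrence — are carried as
explicit missing values, excluded from every average and test, and never
coerced to 0 or 1, so per-dataset means retain their meaning.

### SCI denominator convention

Published implementations disagree on whether the root counts as an
automatically consistent node.  The default here excludes the root (n − 2
assessed nodes on a binary n-tip tree); `count_root=True` switches to the
root-included convention.  The choice shifts SCI by at most 1/(assessed+1)
and does not affect any other metric.

## Randomization tests

Two null models hold the topology fixed and break its association with the
ages:

- **shuffle** permutes whole (FAD, LAD) pairs across taxa, preserving each
  taxon's range length — and therefore the summed range length SRL — so RCI
  comparisons between observed and null remain meaningful;
- **sample** draws each taxon's age uniformly within [LAD, FAD] and treats
  the draw as a point occurrence.  "Sampled" randomization is not precisely
  defined in the literature this pipeline follows; this uniform-within-range
  reading is one plausible interpretation and is labelled as such.  Because
  point occurrences carry zero range length, RCI in sample-mode replicates
  keeps the *observed* SRL as its denominator (otherwise RCI would be
  undefined in every replicate).

All four metrics are oriented "higher is more congruent", so significance is
one-tailed: p = (#{null ≥ observed} + 1)/(n_eff + 1), which is never 0.
Replicates where a metric is undefined are skipped for that metric and the
effective count n_eff reduced, avoiding bias toward small p.  Tests can be
run per tree or on a tree-set mean (the mean is recomputed under every
replicate).  Null counting uses an absolute guard of 1e−9 when comparing
null to observed, protecting ties against last-ulp noise from re-summing
identical gap terms in a different order.

**Conservativeness for discrete statistics.**  SCI takes at most n − 1
distinct values, so under a true null its permutation p-values are
*super-uniform* (stochastically larger than uniform): the ties-count-as-
extreme rule piles mass toward p = 1.  This is a well-known property of
conservative permutation p-values, not an artifact; calibration checks that
demand exact uniformity will flag SCI while the continuously varying
metrics (RCI, GER, MSM*) calibrate cleanly.  Users combining SCI p-values
(e.g. via Fisher's method) should expect conservative results.

Reproducibility: each test expands a single integer seed through numpy
`SeedSequence` spawning; replicate *i* always consumes the *i*-th substream,
so results are independent of execution order and identical inputs + seed
give bit-identical output.  The CLI derives stage-level seeds by hashing
(global seed, stage name, item index), so a stage rerun in isolation
reproduces its part of a pipeline run.

## Dataset screening and summarization

Tree sets larger than the cap (default 500) are subsampled uniformly
without replacement before scoring; per-metric means weight every sampled
tree equally.  To limit non-independence from shared taxa, datasets are
screened by greedy sequential elimination: while any record has < 50%
unique taxa or the mean proportion is < 75% (defaults; both configurable),
the record with the lowest unique-taxon proportion is removed.  Ties break
toward the record sharing the most taxon occurrences with other retained
records, then toward the lexicographically smallest dataset id.  Uniqueness
is always evaluated against the currently retained records only, and every
elimination is logged with the proportions at that step, so alternative
orders can be audited.  The screening literature does not fix an
elimination order; this deterministic rule was chosen for auditability.

## Method comparison

Per-dataset, per-method metric means are compared with a paired Wilcoxon
signed-rank test on the differences (A − B).  The repeated-measures
structure of the underlying meta-analysis collapses to this pairing once
per-dataset means are taken; the per-dataset difference table is exported so
richer (e.g. mixed-effect) models can be fitted externally, and the
`strat_fig` metadata flag is carried through for the same reason.  Zero
differences are dropped (the standard signed-rank convention); the null
distribution is exact for ≤ 25 usable pairs and a tie-corrected normal
approximation above that; all-zero differences give p = 1.

The slope diagnostic fits ordinary least squares of method B's means on
method A's and tests t = (slope − 1)/SE on n − 2 degrees of freedom, with
both two- and one-sided p-values reported.  A numerically perfect fit
(SSE ≤ 1e−12 × SYY) makes the t statistic 0/0; such fits are flagged
`degenerate` with p = 1 if the slope equals the null exactly and p = 0
otherwise.

## Synthetic-study generator

Each dataset comprises a pure-birth (Yule) true tree grown to its tip
count, fossil ranges, and one tree set per "method" at a chosen noise
level.  Defaults (chosen once as a modest fossil-vertebrate-like study):

| parameter | default | units | rationale |
|-----------|---------|-------|-----------|
| `n_datasets` | 30 | — | enough pairs for a well-powered signed-rank test |
| `tips_range` | (20, 40) | tips | typical published-matrix sizes at desk scale |
| `birth_rate` | 0.1 | splits/lineage/Myr | root ages of tens of Myr at these sizes |
| `preservation_gap_mean` | 5 | Myr | exponential lag of FAD behind lineage origination |
| `range_length_mean` | 5 | Myr | exponential observed range duration |
| `trees_per_set` | 50 | trees | a small posterior-sample stand-in |
| `moves_a`, `moves_b` | 1, 10 | NNI moves | clearly separated accuracy levels |

The FAD is lagged from the tip's *origination* (its parent node's time),
truncated at 0, and the LAD follows from an independent exponential
duration, so FAD ≥ LAD ≥ 0 always holds and the true tree never implies a
negative gap at a tip.  In the zero-gap limit every FAD equals its parent
node's age; on trees where every internal node subtends a tip (ladders)
basic dating then recovers the true node ages and MIG equals the summed
internal-edge durations exactly.  On general topologies a node with two
internal children is dated younger than its true age, so MIG is *bounded
above* by the internal-edge sum — the test suite checks the equality on a
ladder and the bound on Yule trees.

Tree-set noise is modelled as independent random rooted
nearest-neighbour-interchange (NNI) moves applied to copies of the truth —
one interpretable knob, stated explicitly so users can substitute stronger
error models (e.g. SPR).  Each simulated dataset receives its own disjoint
taxon set, mimicking matrices that have already passed overlap screening.

What the generator does *not* emulate: extinction (pure birth only),
character data and real inference error structure (NNI noise is symmetric
and unbiased, unlike systematic method-specific biases), stratigraphic
biases beyond the exponential gap (facies, sea-level), taxon sharing across
datasets, and non-uniform fossil recovery.  Passing end-to-end tests on
synthetic studies therefore demonstrates that the pipeline recovers known
orderings and calibrates correctly under its own model — not that any
particular empirical contrast between inference methods is real.

## Problem sizes in the shipped checks

The test suite verifies the extremal bounds exhaustively at n = 4–6; null
calibration over 200 simulated datasets (10–30 tips, 199 replicates each);
direction-of-effect recovery over 20 studies of 30 datasets (20–40 tips, 50
trees per set, NNI 1 vs 10); and generator symmetry over 100 seeded studies
of 12 datasets.  `scripts/acceptance.py` runs one full 30-dataset study at
the same settings with 199 permutation replicates per dataset/method.
These sizes are the package's chosen desk-scale defaults; all of them are
configurable upward.

## Known limitations

- Basic dating only; no calibrated time-scaling.
- Gmin/Gmax (hence GER and MSM*) normalize against binary trees even for
  polytomous inputs, which can understate a consensus tree's relative fit.
- SCI permutation p-values are conservative (see above).
- Taxon matching between trees and range tables is exact string matching
  after whitespace normalization; no synonymy or rank-aware matching.
- The overlap filter's elimination order is one deterministic choice among
  several defensible ones; the log exists so others can be replayed.
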