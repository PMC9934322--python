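# Methods

## Problem and model

`recland` predicts the local crossover-recombination rate of a biparental
cross along a chromosome, using only a whole-genome alignment of the two
parental sequences plus the positions of CentO centromeric satellite hits.
The driving assumption is that locally similar parental sequences recombine
more, while centromeres (and a NOR short arm, where present) suppress
recombination regardless of similarity.

All tracks live on a fixed partition of the reference chromosome into
windows of `window_size` bases (default 100 kb — fine enough to place
crossovers, coarse enough that windows accumulate countable events). The
last window may be partial; every proportion is normalised by the actual
window length so chromosome ends are not inflated. Internally all
coordinates are 0-based half-open; the 1-based inclusive convention of the
aligner reports is converted exactly once, at parse time.

### Features

* **V** counts SNP and deletion rows of the variant report per window,
  divided by window length. Insertions in the query carry no reference base
  of their own and are excluded.
* **I** is the per-base union of reverse-orientation alignment blocks:
  overlapping blocks never double-count, because the quantity is "fraction
  of reference bases lying in inverted alignment".
* **A** attributes unaligned query bases to reference windows. The aligner
  reports say which query bases are covered but not where the uncovered ones
  "belong"; we locate each unaligned query segment between its flanking
  blocks in query order and attribute its length to the window containing
  the midpoint of the reference gap between those blocks' projections.
  Unaligned termini attach to the first/last aligned reference base. The
  proportion is clipped at 1 (a window can be "assigned" more absent bases
  than it has positions). The reference-window length is used as the
  denominator; attributing by query-segment length instead would change A's
  scale but not its support.

Identity is `Id0 = 1 − (V + I + A)`, clipped to [0, 1]. The clip matters
only when the three features overlap heavily; it keeps the downstream case
algebra inside its stated range (Id1 ∈ [−1, 2]).

### The four steps

Step 1 applies three guard rules in a fixed order with first match winning.
The printed rules are called mutually exclusive, but the guards of the
reward and correction cases can both hold; evaluating them in listed order
(penalty, reward, correction) is deterministic and matches the published
decision-tree layout. All inequalities are strict: a window with V exactly
equal to t4 matches no case. Step 2 clips negatives (rates cannot be
negative). Step 3 finds the centromere interval [c0, c1] as the
left-/right-most members of the union of the two parents' CentO-count
argmax sets, computed on each parent's own grid and compared by index. A
track with no positive count contributes nothing; only if both tracks are
silent is the centromere undeclarable (an error). The correction mask is 0
on [c0, c1] and ramps linearly over `ramp` windows (a structural constant,
50 by default, exposed for experimentation but not calibrated) on each
side, clamped into [0, 1] where a ramp would run off the chromosome. A
chromosome whose c1 lies in the first quarter (boundary counts as
telocentric) gets the binary mask instead: 0 strictly left of c1, 1 from c1
on. Step 4 smooths exponentially with the first window forced to zero —
observed recombination tracks start at zero — using
`Id4(w) = α·Id3(w) + (1−α)·Id4(w−1)`.

The final track is left unclipped: Id3 can reach 2 when the reward case
pushes identity above 1, and we do not truncate the smoothed output.

### Evaluation

The observed track (cM per window) is smoothed with the ordinary
exponential recurrence that *preserves* its first value, using the same α as
the model. Two metrics are computed between Id4 and the smoothed
observation: Pearson's r, and R² in residual form,
`1 − Σ(y−p)²/Σ(y−ȳ)²`, comparing predictions to observations directly.
The residual form can be negative (a prediction worse than the observed
mean), which is essential: centromere-only corrections really do score
negative R² while keeping a high r. A regression-form R² (the square of r
for a fitted line, never negative) is provided separately as
`r2_regression` for comparison, but is not the default. All windows enter
the metrics, centromeric zeros included; no masking rule is applied.

### Calibration

The seven case parameters are fitted on one chromosome by SLSQP over the
box [0, 1]⁷, minimising 1 − R². α is fixed at 0.1 and never optimised —
it is a smoothing choice, not a model parameter. The objective is smooth in
p1–p3 but piecewise constant in the thresholds (each guard reclassifies
finitely many windows), so:

* gradients use forward finite differences with step 1e-3, large enough to
  cross a guard boundary when feature values are dense near the current
  threshold;
* a seeded multistart is provided: the first start is the box centre
  (all 0.5), further starts are uniform in the box under the seed. The best
  start wins, and the reported objective is recomputed from the returned
  parameters, so reported and reproducible values agree to 1e-9. The run is
  fully deterministic given (seed, starts), and the start list for a larger
  `starts` is a prefix-extension of a smaller one, so more starts can never
  do worse.
* parameter values themselves are not identifiable — any threshold inside
  the same inter-value gap yields the same classification — so calibration
  quality is judged on R², never on parameter recovery.

Transfer (the intended use) applies a fitted parameter set unchanged to
other chromosomes. Twelve per-chromosome calibration presets for an
*indica* × *japonica* rice cross ship with the package.

## The synthetic generator

`recland.synth` exists so that every stage is testable without downloading
assemblies. Design choices:

* **Archetype mixture.** Each window is one of five archetypes — identical
  (background SNPs only), variant-rich, inverted, absent-heavy and
  absent-light — with disjoint feature ranges. This spans every guard
  regime of Step 1 with clear separation, which is what the tests need:
  thresholds then have wide equivalent-classification plateaus, making the
  piecewise-constant calibration objective tractable for multistart SLSQP.
  The cost is realism: real windowed divergence is continuous and
  autocorrelated, so passing calibration tests here demonstrates that the
  machinery recovers a recoverable optimum, not that real rice data is this
  well separated.
* **Integer counts.** Features are drawn as integer base counts, so every
  proportion is an exact rational of the window length and the emitted
  `show-coords`/`show-snps` text round-trips through the parsers and the
  feature extractor bit for bit. This round trip is the generator's defining
  correctness property.
* **Planted structure.** A CentO count peak (triangular, default 5 windows
  half-width, optional reference/query offset) marks the centromere, and the
  windows around it are forced to the absent-heavy archetype, mimicking the
  low identity usually seen in centromeric regions.
* **Observed track.** The noiseless observed track is constructed as the
  exact pre-image of the model's own Id4 under the evaluation smoothing
  (i.e. `[0, Id3(1:)]`), so at zero noise the smoothed observation equals
  the prediction and r = R² = 1 exactly — the anchor for self-consistency
  tests. Gaussian noise of `noise_sd` (default 0.05 cM per window) is added
  and the track truncated at zero. `rate_scale` defaults to 1 cM per model
  unit; any other scale preserves r but not R².
* **Determinism.** All randomness flows from the scenario seed through
  named substreams; identical scenarios are byte-identical, including the
  emitted report text.

Problem sizes used in the test suite (small multiples of the window size,
chromosomes of 0.25–12 Mb, 100 brute-force scenarios at 50 kb windows,
calibration at 120 windows with up to 100 starts) were chosen so the whole
suite exercises every code path at exact-oracle resolution while remaining
quick to run; they are far below real chromosome sizes, which the windowed
algorithms handle identically at higher n.

## Numerical notes

* Exponential smoothing is implemented as a linear IIR filter
  (`scipy.signal.lfilter`); the evaluation variant seeds the filter state so
  the first value is preserved, the model variant zeroes the first input.
* Case guards are vectorised with masked selection; the first-match order is
  enforced by masking later guards with earlier ones.
* CSVs are written with `%.17g` and read with round-trip float parsing so
  track round trips are exact.
* Degenerate inputs fail loudly: constant observed tracks (undefined R²),
  zero-variance correlation inputs, all-zero CentO tracks, alignment blocks
  beyond the chromosome end, query lengths shorter than the aligned
  coverage, and non-realisable synthetic proportions all raise with a
  message naming the offending quantity.
* Tie-breaks: c1 exactly at n/4 is telocentric; CentO count ties enter the
  argmax set (so ties widen [c0, c1]).

## Known limitations

* The model's output is on an identity-derived scale, not calibrated cM/Mb;
  comparisons with observations rely on r/R² after smoothing, and R² is
  scale-sensitive.
* Absent-base attribution is a modelling choice; other placements of
  unaligned query segments (e.g. proportional spreading) would change A
  locally.
* Window indices of reference and query are compared directly in centromere
  detection; strongly different parental chromosome lengths would shift the
  query peak's index relative to the reference frame.
* The aligner itself is never invoked; the package consumes its text
  reports.
* Multi-contig query assemblies are not modelled; the query is treated as a
  single coordinate system.
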