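# recland

Predict the local crossover-recombination landscape of a biparental cross
from a whole-genome alignment of the two parental genomes.

Meiotic crossovers are unevenly distributed along chromosomes: suppressed in
and around centromeres, and correlated with how similar the two parental
sequences are locally. `recland` turns that observation into a windowed
predictor aimed at plant breeders and geneticists who want to anticipate
where a specific cross (say, an *indica* × *japonica* rice cross) will
recombine, before genotyping a mapping population.

## The model

One parent is taken as reference and each chromosome pair is aligned
(MUMmer `nucmer`; `recland` parses the `show-coords -r` and `show-snps`
reports). The reference chromosome is cut into n windows of 100 kb, and for
each window w three divergence proportions are measured:

* **V(w)** — SNP and deletion positions per window length,
* **I(w)** — fraction of reference bases covered by reverse-orientation
  alignment blocks,
* **A(w)** — unaligned query bases attributed to the window.

The windowed sequence identity is

    Id0(w) = 1 − (V(w) + I(w) + A(w))

and the prediction is built in four steps:

1. **Cases** — three mutually exclusive rules (first match wins) reshape the
   identity with seven parameters p1–p3, t1–t4 ∈ [0, 1]:
   * Id0 < t1 and V > t4 → Id1 = Id0 − p1 (penalise divergent,
     variant-dominated windows),
   * Id0 < t2 and V < t4 → Id1 = Id0 + p2 (reward low-identity windows with
     few variants, which hide short near-perfect alignments),
   * A > t3 and V < t4 → Id1 = Id0 − p3 (correct windows whose absent bases
     flag assembly artefacts);
2. **Clipping** — Id2 = max(0, Id1);
3. **Centromere correction** — the centromere interval [c0, c1] is located
   from CentO satellite hit counts on both parents (the left-/right-most
   windows of the union of the two argmax sets) and Id2 is multiplied by a
   mask that is 0 on [c0, c1] and ramps linearly to 1 over 50 windows on
   each side; chromosomes whose centromere sits in the first quarter
   (a NOR short arm) have the whole short arm zeroed instead;
4. **Smoothing** — exponential smoothing with α = 0.1 and the first window
   forced to 0, giving the final track Id4.

The seven parameters are calibrated on one chromosome by bound-constrained
SLSQP minimising 1 − R² against the exponentially smoothed observed
recombination track (cM per 100 kb window), then applied unchanged to other
chromosomes. Predictions are scored with Pearson's r and the residual-form
coefficient of determination R² = 1 − SS_res/SS_tot (which may be negative).

## Worked example

Everything below runs on synthetic data with known ground truth — no
assemblies needed. Simulate a 5 Mb chromosome pair, extract features from
the emitted alignment reports, predict with the shipped `chr01` calibration
preset, and score against the simulated observed track:

```sh
recland simulate --seed 3 --chrom-length 5000000 --noise-sd 0.02 --out-dir demo
recland features --coords demo/alignment.coords --snps demo/alignment.snps \
    --ref-length 5000000 --qry-length 5636882 --chrom chrS1 --out demo/features.csv
recland predict --features demo/features.csv --cento-ref demo/cento_ref.bed \
    --cento-qry demo/cento_qry.bed --preset chr01 --chrom chrS1 \
    --out-prefix demo/prediction
recland evaluate --prediction demo/prediction.csv \
    --recombination demo/recombination.csv --chrom chrS1 --out demo/report.json
```

which prints

```
features: 50 windows -> demo/features.csv
case incidence: case1=10.0%, case2=64.0%, case3=0.0%, none=26.0%
r = 0.9989  R2 = 0.9971  n = 50
```

`case incidence` is the fraction of windows each Step-1 rule touched (this
simulated chromosome carries a broad low-identity centromeric valley, hence
the many reward-case windows). `r` and `R2` compare the predicted track with
the smoothed observed recombination; values near 1 are expected here because
the simulation's observed track was generated by the same model family.
Calibrating instead of using a preset recovers an equally good fit:

```sh
recland calibrate --features demo/features.csv --cento-ref demo/cento_ref.bed \
    --cento-qry demo/cento_qry.bed --recombination demo/recombination.csv \
    --chrom chrS1 --starts 50 --seed 1 --out demo/fitted.json
# R2 = 0.9975 (2954 evaluations, converged=True)
```

The same workflow is available as a library, including a scikit-learn
estimator:

```python
from recland import RecombinationPredictor, stack_inputs, SyntheticScenario
from recland.synth import generate_bundle

bundle = generate_bundle(SyntheticScenario(chrom_length=8_000_000, seed=11, noise_sd=0.0))
X = stack_inputs(bundle["features"], bundle["cento_ref"], bundle["cento_qry"])
est = RecombinationPredictor(starts=60, random_state=42)
est.fit(X, bundle["experimental"].rates)
print(est.params_, est.score(X, bundle["experimental"].rates))
```

## Layout

* `recland.alignio` — readers/writers: `show-coords`/`show-snps` reports,
  BED, recombination/feature/prediction CSV, BedGraph;
* `recland.features` — window grid, V/I/A extraction, identity, CentO counts;
* `recland.model` — the four model steps and case incidence;
* `recland.evaluate` — track smoothing, Pearson r, R² (residual and
  regression forms);
* `recland.calibrate` / `recland.estimator` — SLSQP calibration, transfer,
  and the scikit-learn estimator;
* `recland.synth` — synthetic scenario generator with exact round-trip
  emission of alignment reports;
* `recland.presets` — the twelve shipped per-chromosome calibrations;
* `recland.cli` — the `recland` command.
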