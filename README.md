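# gatkcan

Detection of somatic small-scale mutations (SNVs and indels) in **tumor-only**
exome sequencing. Without a matched normal, germline subtraction is
impossible: called variants must be separated into true somatic mutations and
artifacts using the variants' own statistics. This package implements a
catalog-aware filtering classifier with machine-trained cutoffs, a full
evaluation-metric suite, and a synthetic-cohort generator so that every stage
is testable without any external data.

It is intended for method developers and bioinformaticians working on
tumor-only variant filtering who want a reproducible, fully synthetic test bed
for catalog-aware filtering.

## The method

A called variant carries the usual GATK annotations and two additional
statistics:

- **QD** — variant quality divided by unfiltered depth;
- **FS** — Phred-scaled two-sided Fisher exact P for strand bias,
  −10·log₁₀ p of the 2×2 (ref/alt × forward/reverse) read-count table;
- **MQ** — RMS mapping quality;
- **MQRankSum** — Mann–Whitney z (mid-ranks, tie-corrected variance,
  continuity correction) of ALT- vs REF-read mapping qualities;
- **dNM** — distance in bp to the nearest known mutation in a reported-mutation
  catalog; dNM = 0 means the call coincides exactly with a known mutation;
- **Mann–Whitney strand test** — for one site across the tumors of a cohort,
  the two-sided P that the forward-minus-reverse ALT read-count differences
  share a distribution with the REF differences (exact when both groups ≤ 8
  and tie-free, normal approximation otherwise).

The decision rule, per variant class:

1. if dNM = 0, the call is a **true mutation** — no further filtering;
2. otherwise it is an **artifact** iff any strict comparison fails:
   FS > fs_max, QD < qd_min, 0 < dNM < dnm_min, strand-test P < mw_p_min,
   and for SNVs additionally MQ < mq_min or MQRankSum < mq_rank_sum_min.
   Missing statistics pass; ReadPosRankSum is never consulted.

The cutoffs (six for SNVs, four for indels) are trained by **particle swarm
optimization** maximizing the fitness

&nbsp;&nbsp;&nbsp;&nbsp;*f(α) = α·(1 − cFPR) + (1 − α)·TPR*

over a discretized search space (dNM/FS/MQ/MQRankSum/QD/MW-P partitioned into
1000/60/50/100/20/6 segments), with α swept from 0 to 1 in steps of 0.1 under
leave-one-tumor-out cross-validation on ten stage-stratified tumors
(2/3/2/3 for stages I–IV), then a final retrain at the selected α. Indel
cutoffs are trained on a 50-reported + 10-artifact split and evaluated on the
remainder. Evaluation uses TPR, conditional FPR (fraction of artifact calls
surviving the filter), precision, FPR per megabase of sampled reference
sites, and the Matthews correlation coefficient (MCC).

The GATK hard-filter defaults (SNV: QD < 2.0, FS > 60.0, MQ < 40.0,
MQRankSum < −12.5, ReadPosRankSum < −8.0; indel: QD < 2.0, FS > 200.0,
ReadPosRankSum < −20.0) are provided as the untrained baseline.

## Worked example

Everything composes as scikit-learn style estimators over a per-variant
feature frame:

```python
from gatkcan.simulate import CohortSpec, generate_catalog, simulate_cohort
from gatkcan.features import build_feature_frame
from gatkcan.estimators import HardFilterClassifier, PSOConfig, ThresholdRuleClassifier
from gatkcan.train import TrainingPlan, train_snv
from gatkcan.metrics import confusion_from_arrays, metric_set

catalog = generate_catalog(CohortSpec().genome, 2000, seed=301)
calls, truth, stages = simulate_cohort(CohortSpec(seed=301), catalog)
frame = build_feature_frame(calls, catalog, truth=truth, stages=stages)

result = train_snv(frame, plan=TrainingPlan(),
                   cfg=PSOConfig(n_particles=120, n_generations=30, seed=301))
print(result.alpha, round(result.fitness, 3))   # 0.1 1.0

held = CohortSpec(n_tumors=5, stage_counts={"I": 1, "II": 2, "III": 1, "IV": 1}, seed=302)
calls2, truth2, _ = simulate_cohort(held, catalog)
frame2 = build_feature_frame(calls2, catalog, truth=truth2)
y = frame2["label"].to_numpy(int)

trained = ThresholdRuleClassifier.from_threshold_set(result.thresholds)
print(metric_set(confusion_from_arrays(trained.predict(frame2), y)))
# MetricSet(tpr=1.0, cfpr=0.0208, precision=0.844, mcc=0.909, ...)
print(metric_set(confusion_from_arrays(HardFilterClassifier("snv").fit().predict(frame2), y)))
# MetricSet(tpr=1.0, cfpr=0.5292, precision=0.175, mcc=0.287, ...)
```

Reading: on a held-out five-tumor cohort with ~10% true mutations, the
trained thresholds keep every true mutation while letting only ~2% of
artifacts through (MCC 0.91); the untrained hard-filter defaults let ~53% of
artifacts through (MCC 0.29). The catalog-distance shortcut, the trained QD
band, and the cohort strand test do the work the fixed defaults cannot.

The same pipeline is scriptable from the shell:

```bash
gatkcan simulate --seed 3 --out sim/
gatkcan train --cohort-dir sim/ --seed 3 --particles 150 --generations 40 --out model/
gatkcan classify --vcf sim/T001.vcf --catalog sim/catalog.tsv \
                 --thresholds model/thresholds_snv.json --out classified/
gatkcan evaluate --classified-dir classified/ --truth sim/truth.tsv --out eval/
```

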