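# tnbc-subtyper

Molecular subtyping of triple-negative breast cancer (TNBC) from
microarray gene expression.

Breast tumors negative for the estrogen receptor (ER), the progesterone
receptor (PR) and HER2 — triple-negative tumors — lack the usual
therapeutic targets and are molecularly heterogeneous; expression-based
subtyping (the six Lehmann subtypes BL1, BL2, IM, M, MSL, LAR are the
common reference) guides target selection and trial design.  This package
implements, as a tested and reusable pipeline, the complete subtyping
analysis used for compiled multi-dataset cohorts, for bioinformaticians
who want to run, audit or extend each stage:

1. **I/O and pooling** — probes x samples TSV matrices (GEO
   series-matrix-like) with per-sample dataset labels, merged on the
   probe intersection;
2. **bimodal receptor filtering** — per receptor probe, a two-component
   Gaussian mixture `w_lo N(mu_lo, sd_lo²) + w_hi N(mu_hi, sd_hi²)` is
   fitted by EM; a sample is negative when its posterior probability of
   the high (expressed) component is < 0.5, TNBC when all three markers
   are negative, with an optional positive-control confirmation pass;
3. **normalization and filtering** — per-dataset quantile normalization
   onto the cohort reference; probes kept when their sample SD > 0.9
   (log2 units);
4. **consensus subtyping** — resampled k-means consensus clustering; the
   number of stable subtypes is the smallest k whose next proportional
   gain in consensus-CDF area, `Δ(k) = (A(k) − A(k−1))/A(k−1)`, drops
   below 0.05; final labels cut the average-linkage tree of `1 − M`;
5. **signature selection** — probes specific to a subtype versus the
   rest: fold change `2^(Δ log2 mean)` > 1.75 (up) or < 0.5 (down),
   > 80% of subtype samples on the expected side of the rest mean, and
   Welch t-test p < 1e-4;
6. **classification** — centroid-correlation scoring against signed
   subtype gene lists (a 47-probe five-subtype validation list ships with
   the package) and column-percentage cross-tabulation of two labelings.

A synthetic-cohort generator with planted receptor status, subtype
structure, batch shifts and noise makes every stage testable end to end
without downloading any data; see `docs/methods.md` for the models,
defaults and limitations.

## Worked example

Subtype discovery on a synthetic all-TNBC cohort (150 samples, 5 planted
subtypes, marker effect 2 log2 units, probe noise 0.5):

```python
import tnbc_subtyper as t
from sklearn.metrics import adjusted_rand_score

config = t.SimConfig(n_datasets=1, samples_per_dataset=150, tnbc_only=True,
                     batch_shift_sd=0.0, seed=0)
matrix, truth = t.generate_cohort(config)

normalized = t.normalize_per_dataset(matrix)
filtered = t.filter_by_sd(normalized, threshold=0.9).apply(normalized)
result = t.run_consensus(filtered, k_min=2, k_max=8, n_resamples=200, seed=0)

print("probes kept (SD > 0.9):", filtered.n_probes)
print("delta areas:", {k: round(v, 3) for k, v in result.deltas.items()})
print("chosen k:", result.chosen_k)
print("cluster sizes:", result.labels.value_counts().to_dict())
print("ARI vs planted subtypes:",
      round(adjusted_rand_score(truth.subtype, result.labels[truth.subtype.index]), 3))
```

prints

```
probes kept (SD > 0.9): 41
delta areas: {2: 0.401, 3: 0.536, 4: 0.205, 5: 0.072, 6: 0.031, 7: 0.025, 8: 0.02}
chosen k: 5
cluster sizes: {'C1': 41, 'C2': 33, 'C3': 27, 'C4': 25, 'C5': 24}
ARI vs planted subtypes: 1.0
```

Reading the numbers: of 1000 probes, 41 pass the variability filter (the
planted marker blocks); the consensus-CDF area still gains 7.2% going to
k = 5 but only 3.1% going to k = 6, so the scan stops at five stable
subtypes; the final assignment reproduces the planted partition exactly
(adjusted Rand index 1.0).  Continuing with
`t.select_all_signatures(normalized, result.labels)` recovers the planted
markers (10–11 probes per subtype at the default thresholds), and
`t.classify_by_signatures` / `t.cross_tabulate` compare any two labelings
as column percentages.

The same chain runs from the shell:

```bash
tnbc-subtyper simulate --seed 0 --out-prefix scratch/cohort
tnbc-subtyper normalize --in scratch/cohort.expression.tsv --out scratch/norm.tsv
tnbc-subtyper call-receptors --in scratch/norm.tsv --out scratch/calls.tsv
tnbc-subtyper subtype --in scratch/norm.tsv --labels-out scratch/labels.tsv --k-max 8
tnbc-subtyper run-all --out-dir scratch/run --seed 17   # full pipeline + JSON report
```

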