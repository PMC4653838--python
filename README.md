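# ibfe

Parameter-free integration of heterogeneous multi-omics patient matrices
into a single patient-similarity representation, with a simulation
benchmark of the factors that break naive integration and survival tools
for assessing the prognosis of discovered subtypes.

## The problem

Disease subtyping increasingly rests on several omics measurements of the
same patients — e.g. DNA methylation beta values, mRNA expression and
miRNA expression. Directly concatenating the matrices lets whichever data
type has the largest numeric scale or noise dominate clustering, and it
cannot reconcile data types that define patient groups incompletely or
contradictorily. This package implements a two-stage correlation mapping
that sidesteps those failure modes without any tunable parameter.

## The method

Given K aligned patient × feature matrices X⁽¹⁾ … X⁽ᴷ⁾ on M patients:

- **Step I** — for each data type k build the M × M patient similarity
  matrices P⁽ᵏ⁾ (Pearson correlation between patient rows) and S⁽ᵏ⁾
  (Spearman rank correlation, midranks for ties).
- **Step II** — stack them column-wise into the extracted feature matrix
  Y = [P⁽¹⁾ S⁽¹⁾ … P⁽ᴷ⁾ S⁽ᴷ⁾] (M × 2MK). Every column already lives in
  [−1, 1], so no rescaling is needed.
- **Step III** — the integrated similarity is Z = Pearson correlation of
  the rows of Y.

Variants: `ibfe1` uses both correlation kinds, `ibfe2` Pearson only,
`ibfe3` Spearman only. `ibfe3` is exactly invariant under strictly
increasing transforms of each data type, the mechanism behind the
method's robustness to scale conflicts.

## Worked example

```python
import numpy as np
from ibfe import IBFE, best_kmeans, nmi, simulate

# two data types on the same 100 patients with a planted 50/50 bipartition,
# observed at wildly conflicting scales (x^20 vs 20^x)
out = simulate(scenario="sd1", q=20, seed=1)

est = IBFE(variant="ibfe1").fit(out.datasets)
Z = est.similarity_          # 100 x 100 integrated patient similarity
pred = best_kmeans(est.embedding_, k=2, n_restarts=100, seed=0)

truth = out.true_labels.to_numpy()
print(round(float(Z.values[:50, :50].mean()), 3))   # 0.43
print(round(nmi(truth, pred), 3))                   # 1.0

from ibfe import direct_concatenate
raw = direct_concatenate(out.datasets).to_numpy()
print(round(nmi(truth, best_kmeans(raw, 2, n_restarts=100, seed=0)), 3))  # 0.035
```

The within-class block of Z is strongly positive while the between-class
block is negative, so k-means on the rows of Z recovers the planted
classes exactly (NMI = 1.0); on the raw concatenation the huge-scale
columns drown the structure and clustering is near random (NMI ≈ 0.035,
varying by seed).

The same pipeline is available from the shell:

```bash
ibfe simulate --scenario sd1 --q 20 --seed 7 -o sim/
ibfe integrate --inputs sim/T1.tsv --inputs sim/T2.tsv --variant ibfe1 -o Z.tsv
ibfe cluster --similarity Z.tsv --k 2 -o labels.tsv
ibfe benchmark --scenario sd1 --q 20 --repeats 20 --restarts 100 -o report.json
ibfe survival --labels labels.tsv --clinical clinical.tsv -o survival.json
```

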