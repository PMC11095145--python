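# dualscreen

Dual-path multi-attribute virtual screening for small molecules, plus the
common-effect meta-analysis statistics that typically accompany such
screens in translational studies.

## The problem

CNS-directed drug-repurposing screens want compounds that (a) cross the
blood-brain barrier (BBB) and (b) hit as many of a panel of desirable
activities — e.g. anti-inflammatory and antioxidative pathway assays —
as possible, while avoiding known toxicants.  `dualscreen` implements
this as a reusable toolkit:

* **Per-attribute binary classifiers on two routes.**  Attributes whose
  signal lives in bulk physicochemistry are modeled by a feed-forward
  network on a 12-descriptor panel (monoisotopic MW, Crippen LogP, Ertl
  TPSA, H-bond donors/acceptors, rotatable bonds, Fsp³, aromatic rings,
  Gasteiger max/min partial charge, N and O counts).  Attributes whose
  signal is structural are modeled by a graph convolutional network
  (GCN) on molecular graphs with 30-wide atom and 11-wide bond feature
  vectors; propagation is the symmetric-normalized form
  H′ = ReLU(D^(−1/2)(A+I)D^(−1/2) H W + b) with mean-pool readout.
* **Imbalance remediation.**  Bioassay labels are heavily skewed, so the
  tabular route supports SMOTE and ADASYN oversampling (training folds
  only), the graph route supports random majority downsampling, and both
  can train with the focal loss FL(p_t) = −α_t (1−p_t)^γ log p_t.
* **Cumulative scoring with a BBB gate.**  Each attribute probability is
  binarized at a decision threshold (default 0.5); the activity
  attributes are summed into an integer score; the screen keeps
  compounds that pass the BBB gate, reach score ≥ 5 (configurable), and
  are not flagged toxic.  Hits are ranked by (score, mean activity
  probability, identifier) — a total order.
* **Applicability checks.**  k-NN distance coverage in z-scored
  descriptor space against the training set, and an exact-gradient t-SNE
  (perplexity 30, 1000 iterations) for visual chemical-space overlap.
* **Meta-analysis.**  Inverse-variance common-effect pooling of log
  hazard ratios, Cochran's Q, I² with the overlapping Cochrane
  heterogeneity bands, and the Egger regression test for small-study
  bias.

Everything is exercised against synthetic fixtures with planted, exactly
known ground truth (`dualscreen.synthfix`): a combinatorial vocabulary of
700+ valid molecules, logistic label rules planted on descriptors,
substructure rules planted on graphs, screening tables with a known
gate/score/toxicity funnel, and study sets drawn around a known pooled
effect.

## Worked example

```python
import numpy as np
import dualscreen as ds
from dualscreen.molgraph import featurize_graph

v = ds.compute_descriptors("CCO")
print(f"ethanol: MW={v.exact_mol_wt:.4f} Da, LogP={v.mol_logp:.3f}, "
      f"TPSA={v.tpsa:.2f}, donors={v.num_h_donors}")

# recover a planted substructure rule with the graph path
bench = ds.generate_graph_benchmark(ds.GraphBenchSpec(n=500, seed=2))
graphs = [featurize_graph(s, i) for s, i in zip(bench.smiles, bench.ids)]
idx = np.random.default_rng(2).permutation(500)
tr, te = idx[:400], idx[400:]
model = ds.train_graph([graphs[i] for i in tr], bench.y[tr], ds.GraphNetConfig(seed=1))
probs = ds.predict(model, [graphs[i] for i in te])
_, _, auc = ds.roc_curve(bench.truth["clean_labels"][te], probs)
print(f"graph-path recovery of the planted substructure rule: held-out AUC = {auc:.3f}")

# run the screening funnel on a fixture with planted truth
fx = ds.generate_screen_fixture(ds.ScreenFixtureSpec(n=50, seed=7))
res = ds.run_screen(fx.table, fx.toxic, ds.ScreenConfig.from_schema(fx.schema))
print("funnel:", res.stage_counts)

# pool a study set
studies, _ = ds.generate_meta_fixture(12, float(np.log(0.85)), seed=4)
r = ds.pool_fixed(studies)
print(f"pooled HR {r.pooled_effect:.3f} (95% CI {r.ci_low:.3f}-{r.ci_high:.3f}), "
      f"Q={r.q:.2f}, I2={r.i2:.1f}% {r.heterogeneity_bands}")
```

prints

```
ethanol: MW=46.0419 Da, LogP=-0.001, TPSA=20.23, donors=1
graph-path recovery of the planted substructure rule: held-out AUC = 0.995
funnel: {'n_input': 50, 'n_gate_pass': 23, 'n_score_pass': 8, 'n_nontoxic': 5}
pooled HR 0.870 (95% CI 0.801-0.946), Q=14.16, I2=22.3% ('minor',)
```

The AUC is measured against the pre-noise planted labels, so it reads as
"how well did the model recover the rule"; the funnel counts equal the
generator's planted truth exactly (50 candidates → 23 pass the BBB gate
→ 8 reach the score threshold → 5 survive the toxicity filter); the
pooled hazard ratio sits within sampling error of the value the fixture
was drawn around.

## Command line

`dualscreen` exposes the stages as subcommands:

```sh
dualscreen validate  --in lib.csv --schema schema.cfg --out clean.csv --log excluded.csv
dualscreen featurize --in clean.csv --schema schema.cfg --out desc.csv
dualscreen train     --attr bbb --in clean.csv --schema schema.cfg --out model.npz
dualscreen cv        --attr bbb --in clean.csv --schema schema.cfg --k 5
dualscreen screen    --in candidates.csv --schema schema.cfg --models modeldir/ \
                     --tox toxicity.csv --out hits.csv --report stages.json
dualscreen benchmark --kind tabular --out bench/ --seed 1
dualscreen meta      --in studies.csv --out meta.json
dualscreen pipeline  --schema schema.cfg --in lib.csv --out run/ --seed 0
```

Datasets are CSV with `compound_id`, `smiles`, up to 10 binary attribute
columns (blank = inconclusive/unlabeled) and an optional `toxic` column;
the schema is a small key-value file naming each attribute's display
name, model path (`tabular`/`graph`) and role (`bbb_gate`/`activity`).

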