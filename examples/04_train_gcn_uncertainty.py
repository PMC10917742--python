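"""Train the ChebConv network and quantify prediction uncertainty.

After training, 100 dropout-enabled forward passes give a distribution of
predictions per patient; the entropy of its mean (0 = certain, ln 2 ~ 0.7 =
maximally uncertain) drives selective prediction: accept only patients whose
uncertainty falls below a chosen threshold, defer the rest to human review.
"""

import numpy as np

from evtgraph import (GCNConfig, GOOD_OUTCOME_RULE, build_graph,
                      compute_metrics, default_spec, generate_cohort,
                      mc_dropout_predict, meta_from_cohort, mrmr_select,
                      predictive_uncertainty, preprocess_pipeline,
                      train_semi_supervised, uncertainty_sweep)

table = generate_cohort(default_spec(), n=220, seed=7)
fm = preprocess_pipeline(table, "good_outcome", "followup")
fm = fm.select_columns(mrmr_select(fm, k=10).selected)
graph = build_graph(meta_from_cohort(table), GOOD_OUTCOME_RULE)

rng = np.random.default_rng(0)
idx = rng.permutation(220)
test = np.zeros(220, bool); test[idx[:44]] = True
val = np.zeros(220, bool); val[idx[44:80]] = True
train = ~test & ~val

model, log = train_semi_supervised(graph, fm, GCNConfig(seed=1), train, val)
print(f"trained {len(log['train_loss'])} epochs "
      f"(best validation loss {log['best_val_loss']:.3f} "
      f"at epoch {log['best_epoch']})")

probs = model.predict_proba(model.polynomials, fm.X)[:, 1]
m = compute_metrics(probs[test], fm.y[test])
print(f"test fold: AUC {m.auc:.2f}, accuracy {m.accuracy:.2f}, "
      f"balanced accuracy {m.balanced_accuracy:.2f}")

dist = mc_dropout_predict(model, None, fm, T=100, p=0.1, seed=3)
u = predictive_uncertainty(dist)
pred = (dist.mean_probs[:, 1] >= 0.5).astype(int)
correct = pred[test] == fm.y[test]
print(f"mean uncertainty, correctly classified:  {u[test][correct].mean():.2f}")
print(f"mean uncertainty, misclassified:         {u[test][~correct].mean():.2f}")

print("\nselective prediction on the test fold (certain = u < threshold):")
sweep = uncertainty_sweep(dist.mean_probs[test, 1], u[test], fm.y[test])
print(sweep.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
# AUC improves as the acceptance threshold tightens, at the cost of
# deferring more patients
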