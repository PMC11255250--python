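"""Train the full model on an easy synthetic corpus and evaluate it.

The easy corpus emits one distinct residue per secondary-structure state,
so the labels are a lookup function of the sequence and a converged model
should approach 100% accuracy.  Runs in about a minute on one CPU.
"""

from tcnss import synthetic
from tcnss.featurize import PhysChemTable
from tcnss.metrics import evaluate
from tcnss.seqdata import Q3
from tcnss.workflow import desk_scale_config, predict, train

train_recs = synthetic.generate(synthetic.easy_preset(n_records=20,
                                                      length=40, seed=7))
test_recs = synthetic.generate(synthetic.easy_preset(n_records=10,
                                                     length=40, seed=8))

cfg = desk_scale_config(epochs=200, target_train_acc=0.95,
                        learning_rate=3e-3, tcn_channels=8, tcn_width=16,
                        lstm_hidden=12, classifier_width=16, seed=1)
model, emb, report = train(train_recs, [], cfg)
print(f"trained {len(report.history)} epochs; "
      f"final train token accuracy {100 * report.final_train_accuracy:.1f}%")

probs, labels = predict(test_recs, model, PhysChemTable.default(), emb, Q3)
rep = evaluate(test_recs, probs, Q3)
print(f"held-out: Q3 accuracy {rep.pooled['accuracy']:.1f}%, "
      f"SOV99 {rep.pooled['sov99']:.1f}, MiAUC {rep.pooled['miauc']:.4f}")
print("example prediction:", labels[test_recs[0].id][:40])
print("         observed :", test_recs[0].labels(Q3)[:40])
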