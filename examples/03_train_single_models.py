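"""Train single regressors on a synthetic quantum-yield table.

Generates a feature table with the production column layout, splits it
90:10, trains SVR and KRR with seeded random hyperparameter search, and
applies the QSPR acceptability gate (LOO Q^2 >= 0.6 and external R^2 >= 0.6).
"""

from soqy import (
    ALL_DESCRIPTOR_COLUMNS,
    ModelSpec,
    evaluate,
    loo_q2,
    qspr_gate,
    split_dataset,
    synthetic_qspr_table,
    train_single_model,
)

table = synthetic_qspr_table(n=136, seed=7)
train, test = split_dataset(table.frame, ratio=0.9, seed=7)
cols = list(ALL_DESCRIPTOR_COLUMNS)
print(f"{len(train)} training rows, {len(test)} test rows, {len(cols)} descriptors")

for family in ("SVR", "KRR"):
    spec = ModelSpec(family, budget=30, seed=7)
    model = train_single_model(spec, train[cols], train["phi_delta"])
    train_r2 = evaluate(train["phi_delta"], model.predict(train)).r2
    test_m = evaluate(test["phi_delta"], model.predict(test))
    q2 = loo_q2(spec, train[cols], train["phi_delta"], params=model.params)
    ok, reasons = qspr_gate(q2, test_m.r2)
    print(f"\n{family}: train R2 {train_r2:.3f} | test R2 {test_m.r2:.3f} "
          f"MAE {test_m.mae:.3f} | LOO Q2 {q2:.3f}")
    print(f"  QSPR gate: {'PASS' if ok else 'FAIL ' + '; '.join(reasons)}")

# Q2 is the stability measure: it refits the model n times leaving one
# training point out each time, so it punishes memorization.
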