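"""Delta-learning and mixture-of-experts hybrids.

The delta-learning model corrects an SVR base with a KRR layer fitted to
the base's training residuals; the mixture-of-experts averages SVR and KRR
with convex weights chosen on out-of-fold training predictions.
"""

import numpy as np

from soqy import (
    ALL_DESCRIPTOR_COLUMNS,
    ModelSpec,
    evaluate,
    fit_dlm,
    fit_moe,
    predict_dlm,
    predict_moe,
    split_dataset,
    synthetic_qspr_table,
)

table = synthetic_qspr_table(n=336, seed=11)
train, held = split_dataset(table.frame, ratio=122 / 336, seed=11)
cols = list(ALL_DESCRIPTOR_COLUMNS)
x, y = train[cols], train["phi_delta"]

base = ModelSpec("SVR", budget=30, seed=11)
delta = ModelSpec("KRR", budget=30, seed=11)

dlm = fit_dlm(base, delta, x, y)
base_train_mse = float(np.mean((dlm.layers[0].predict(x) - y) ** 2))
dlm_train_mse = float(np.mean((predict_dlm(dlm, x) - y) ** 2))
print(f"DLM: base train MSE {base_train_mse:.5f} -> stacked {dlm_train_mse:.6f}")
print(f"DLM held-out R2: {evaluate(held['phi_delta'], predict_dlm(dlm, held[cols])).r2:.3f}")

moe = fit_moe([base, delta], x, y, seed=11)
print(f"\nMoE weights (SVR, KRR): {np.round(moe.weights, 3)}")
print(f"MoE held-out R2: {evaluate(held['phi_delta'], predict_moe(moe, held[cols])).r2:.3f}")
# the delta layer drives training error toward zero (residual interpolation);
# the mixture trades expert errors against each other on held-out data
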