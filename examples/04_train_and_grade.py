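"""Train the fully connected regressor on a synthetic affine task and grade
it against the AAMI and BHS standards.

The generator draws 32 correlated Gaussian features and maps them affinely
to (SBP, DBP) with 3 mmHg of label noise, so the best achievable validation
RMSE is ~3 mmHg.  A reduced-width network (32/32 hidden units instead of
2048/4096/8192/2048) is enough for this task and trains in seconds.
"""

from ppgbp.evaluation import evaluate
from ppgbp.regressor import RegressorConfig, predict, split_dataset, train
from ppgbp.synthetic import generate_feature_dataset

x, y = generate_feature_dataset(10_000, label_noise_sd_mmHg=3.0, seed=11)
config = RegressorConfig(input_dim=32, hidden_widths=(32, 32), max_epochs=200, seed=5)
(x_tr, y_tr), (x_te, y_te), (x_va, y_va) = split_dataset(
    x, y, config.split_fractions, seed=5
)
print(f"split {len(x)} cycles -> train {len(x_tr)}, test {len(x_te)}, val {len(x_va)}")

model = train(config, x_tr, y_tr, x_va, y_va)
print(f"trained {len(model.history)} epochs; "
      f"best validation RMSE {model.history.val_rmse.min():.2f} mmHg "
      f"(label-noise floor is 3 mmHg)")

pred = predict(model, x_te)
report = evaluate(y_te[:, 0], y_te[:, 1], pred[:, 0], pred[:, 1])
for name, tgt in (("SBP", report.sbp), ("DBP", report.dbp)):
    print(f"{name}: RMSE {tgt.rmse_mmHg:.2f} mmHg, MAE {tgt.mae_mmHg:.2f} mmHg, "
          f"ME {tgt.mean_error_mmHg:+.2f} +- {tgt.sd_error_mmHg:.2f} mmHg")
    print(f"     AAMI {'pass' if tgt.aami_pass else 'FAIL'} "
          f"(|ME| <= 5, SD <= 8); BHS grade {tgt.bhs_grade} "
          f"({tgt.cum_pct_5:.1f}% / {tgt.cum_pct_10:.1f}% / {tgt.cum_pct_15:.1f}% "
          f"of |err| <= 5/10/15 mmHg)")
    print(f"     Pearson r {tgt.pearson_r:.3f}, "
          f"LOA ({tgt.loa_low_mmHg:.2f}, {tgt.loa_high_mmHg:.2f}) mmHg")
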