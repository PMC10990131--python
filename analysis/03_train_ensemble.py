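"""Fit and cross-validate the two-layer stacked ensemble.

Builds the [G | W | GxW] design matrix, reduces it with standardized PCA,
and evaluates the ten-learner stack with a single seeded 75/25
development/test split. Writes per-learner and ensemble skill metrics
(NSE, r, RMSE) to metrics.csv, the NNLS stacking weights, and the fitted
model bundle for the later stages.
"""

from ricegxw.pipeline import run_train

OUTDIR = "results/run"

if __name__ == "__main__":
    summary = run_train(OUTDIR, n_components=85, split=0.75, n_folds=5, seed=1)
    print(
        f"ensemble skill on {summary['rows']} county-year rows "
        f"({summary['train_n']} train / {summary['test_n']} test):"
    )
    print(f"  train NSE {summary['train_nse']:.3f}")
    print(f"  test  NSE {summary['test_nse']:.3f}, RMSE {summary['test_rmse']:.0f} kg/ha")
    print("wrote metrics.csv, stacking_weights.csv, model_bundle.joblib")
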