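"""Train the NARX forecaster with all three algorithms and rank them.

The network (8 channels in/out, 10 tanh hidden units, delays {1,2}) is
trained in open loop on the typical ABEXYOZ0 complexes only, under
Levenberg-Marquardt, scaled conjugate gradient and Bayesian regularization,
then scored on the held-out test split.  Higher VEcv (variance explained)
is better; ties break on lower RMSE.
"""

from icgnarx import preprocess as pp
from icgnarx.icg_data import SubtypeLabel, build_interval_matrix
from icgnarx.narx import NarxConfig, NarxModel, init_weights
from icgnarx.synthgen import generate_study
from icgnarx.train import TrainOptions, TrainingData, compare_algorithms

beats, _ = generate_study(seed=1)
matrix = build_interval_matrix(beats)
imputed, _mask = pp.impute_nan_with_available_mean(matrix)
norm = pp.sum_of_squares_normalize(pp.normalize_by_rr(imputed))

cfg = NarxConfig()
typical = [
    s for s in pp.to_sequences(norm) if s.subtype == SubtypeLabel.ABEXYOZ0.value
]
data = TrainingData.from_series(cfg, [s.series for s in typical], seed=1)
model = NarxModel(cfg, init_weights(cfg, seed=1), ss_scale=norm.ss_scale)

table = compare_algorithms(
    model, data, [TrainOptions(algorithm=a, max_epochs=150, seed=1) for a in ("LM", "SCG", "BR")]
)
cols = ["rank", "algorithm", "vecv", "rmse", "mae", "r", "stop_reason"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("\nVEcv is the percent of test-set variance the one-step forecast explains;")
print("R is the Pearson correlation between forecast and target.")
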