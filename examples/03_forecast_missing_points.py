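"""Impute the missing characteristic points of a synthetic study and score
the result against the hidden ground truth.

Runs the whole chain: interval matrix, mean imputation, RR and
sum-of-squares normalization, open-loop training on typical complexes,
delay removal, hybrid closed-loop forecasting, and denormalization back to
seconds.  Because the cohort is synthetic, every masked cell has a known
true value to compare against.
"""

import numpy as np

from icgnarx import synthgen
from icgnarx.forecast import IMPUTED
from icgnarx.icg_data import POINT_COLUMNS
from icgnarx.metrics import pearson_r
from icgnarx.pipeline import run_pipeline

beats, truth = synthgen.generate_study(seed=1)
result = run_pipeline(beats=beats, seed=1, max_epochs=150)

prov = result.imputation.provenance.to_numpy()
imputed = prov == IMPUTED
truth_vals = synthgen.align_truth(truth, result.completed_raw.row_meta)
completed = result.completed_raw.values[POINT_COLUMNS].to_numpy()

r = pearson_r(truth_vals[imputed], completed[imputed])
rmse = float(np.sqrt(np.mean((truth_vals[imputed] - completed[imputed]) ** 2)))
print(f"imputed {imputed.sum()} cells; agreement with hidden truth:")
print(f"  Pearson R = {r:.3f}, RMSE = {rmse * 1000:.1f} ms")

print("\ndetection percentage per point (before -> after imputation):")
for col, row in result.detection.per_point.iterrows():
    print(f"  {col:<4} {row['before']:5.1f}% -> {row['after']:5.1f}%")
print(
    f"\neffective detection rate (ABEXYOZu complexes excluded): "
    f"{result.detection.effective_rate:.1f}%"
)
print("A complex counts as detected when no forecastable point is left missing.")
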