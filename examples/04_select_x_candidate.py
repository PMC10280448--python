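"""Decide which X candidate (X1 or X2) is the true X, per dataset.

Some dZ/dt subtypes carry two plausible X points.  The selector measures,
for each candidate, the RMS deviation of its RR-ratio from the typical-beat
reference ratio of the same dataset and picks the candidate that deviates
least.  The two synthetic devices are constructed with opposite true
candidates, so the selection should flip between datasets.
"""

from icgnarx.forecast import select_x
from icgnarx.icg_data import build_interval_matrix
from icgnarx.synthgen import generate_study

beats, _ = generate_study(seed=1)
matrix = build_interval_matrix(beats)

# restrict to rows where both candidates were annotated
both = ~matrix.values[["RX1", "RX2"]].isna().any(axis=1).to_numpy()
from icgnarx.icg_data import IntervalMatrix

m = IntervalMatrix(
    values=matrix.values[both].reset_index(drop=True),
    row_meta=matrix.row_meta[both].reset_index(drop=True),
    state="raw",
)
selection = select_x(m)
print(selection.per_scope.round(4))
print("\nsd_x1/sd_x2: RMS deviation of the candidate's RR-ratio from the")
print("typical-beat reference; the smaller deviation names the true X.")
print("(The generator used X2 as the true X for dataset V and X1 for S.)")
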