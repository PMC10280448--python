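import numpy as np
import pandas as pd
import pytest

from icgnarx import preprocess as pp
from icgnarx import synthgen
from icgnarx.forecast import (
    IMPUTED,
    OBSERVED,
    UNFORECASTABLE,
    denormalize,
    impute_missing_points,
    select_x,
)
from icgnarx.icg_data import (
    POINT_COLUMNS,
    IntervalMatrix,
    PointLabel,
    SubtypeLabel,
    ValidationError,
    build_interval_matrix,
)
from icgnarx.narx import NarxConfig, NarxModel, init_weights
from icgnarx.pipeline import run_pipeline
from icgnarx.preprocess import StateError
from icgnarx.train import TrainOptions, TrainingData, fit


def prepared_matrix(beats):
    m = build_interval_matrix(beats)
    imputed, mask = pp.impute_nan_with_available_mean(m)
    norm = pp.sum_of_squares_normalize(pp.normalize_by_rr(imputed))
    return norm, mask


def untrained_model(norm, seed=0):
    cfg = NarxConfig()
    return NarxModel(cfg, init_weights(cfg, seed), ss_scale=norm.ss_scale, fitted=True)


@pytest.fixture(scope="module")
def fully_observed():
    cfg = synthgen.CohortConfig(n_subjects=2, beats_per_subject=30, seed=3)
    beats, _ = synthgen.generate_cohort(cfg)
    return prepared_matrix(beats)


class TestImputation:
    def test_fully_observed_stream_is_identity(self, fully_observed):
        norm, mask = fully_observed
        assert not mask.to_numpy().any()
        res = impute_missing_points(untrained_model(norm), norm, mask)
        assert (res.provenance.to_numpy() == OBSERVED).all()
        pd.testing.assert_frame_equal(res.completed.values, norm.values)

    def test_predictions_equal_open_loop_when_all_observed(self, fully_observed):
        # with every feedback value observed the hybrid closed loop reads the
        # true history at each step, i.e. it must reproduce the open-loop pass
        norm, mask = fully_observed
        model = untrained_model(norm)
        res = impute_missing_points(model, norm, mask)
        for stream in pp.to_sequences(norm):
            expected = model.predict_open(stream.series)
            got = res.predictions.to_numpy()[stream.row_indices]
            assert np.allclose(got[2:], expected[2:], equal_nan=True)
            assert np.isnan(got[:2]).all()

    def test_single_missing_cell_imputes_exactly_one(self, fully_observed):
        norm, _ = fully_observed
        mask = pd.DataFrame(
            False, index=norm.values.index, columns=POINT_COLUMNS
        )
        mask.iloc[5, POINT_COLUMNS.index("RX2")] = True
        res = impute_missing_points(untrained_model(norm), norm, mask)
        assert res.n_imputed == 1
        assert res.provenance.iloc[5]["RX2"] == IMPUTED

    def test_observed_cells_never_modified(self):
        beats, _ = synthgen.generate_study(seed=5)
        norm, mask = prepared_matrix(beats)
        res = impute_missing_points(untrained_model(norm), norm, mask)
        obs = ~mask.to_numpy()
        a = norm.values[POINT_COLUMNS].to_numpy()[obs]
        b = res.completed.values[POINT_COLUMNS].to_numpy()[obs]
        assert (a == b).all()  # bit-level

    def test_unforecastable_rows_flagged_and_u_skipped(self):
        beats, _ = synthgen.generate_study(seed=5)
        norm, mask = prepared_matrix(beats)
        res = impute_missing_points(untrained_model(norm), norm, mask)
        prov = res.provenance.to_numpy()
        is_u = (norm.row_meta["subtype"] == SubtypeLabel.ABEXYOZu.value).to_numpy()
        # every ABEXYOZu cell is unforecastable, none imputed
        assert (prov[is_u] == UNFORECASTABLE).all()
        # forecastable rows (non-u, past the delay horizon) have no gap left
        horizon = np.zeros(len(norm), dtype=bool)
        for s in pp.to_sequences(norm):
            if s.subtype != SubtypeLabel.ABEXYOZu.value and len(s.row_indices) > 2:
                horizon[s.row_indices[2:]] = True
        assert not (prov[horizon] == UNFORECASTABLE).any()

    def test_scale_mismatch_rejected(self, fully_observed):
        norm, mask = fully_observed
        model = untrained_model(norm)
        model.ss_scale = model.ss_scale * 2.0
        with pytest.raises(ValidationError, match="scale"):
            impute_missing_points(model, norm, mask)

    def test_raw_matrix_rejected(self, fully_observed):
        norm, mask = fully_observed
        raw = pp.denormalize_rr(pp.invert_sum_of_squares(norm))
        with pytest.raises(StateError):
            impute_missing_points(untrained_model(norm), raw, mask)

    @pytest.mark.parametrize("scale", [0.5, 1.0, 2.0])
    def test_heldout_error_tracks_generator_noise(self, scale, _noise_results={}):
        """Imputation error on masked-but-known cells falls as the
        generator's latency noise falls (monotone over three levels scaling
        both the beat-to-beat variability and the annotation jitter)."""
        cfgs = [
            synthgen.CohortConfig(
                dataset_id=ds,
                n_subjects=3,
                beats_per_subject=80,
                latency_sds={p: 0.012 * scale for p in PointLabel},
                noise_sd=0.004 * scale,
                subtype_probs=synthgen.DEFAULT_SUBTYPE_PROBS,
                missing_map=synthgen.DEFAULT_MISSING_MAP,
                seed=s,
            )
            for s, ds in ((21, "V"), (22, "S"))
        ]
        beats, truth = synthgen.generate_study(cfgs)
        res = run_pipeline(beats=beats, seed=2, max_epochs=60)
        tv = synthgen.align_truth(truth, res.completed_raw.row_meta)
        cv = res.completed_raw.values[POINT_COLUMNS].to_numpy()
        imp = res.imputation.provenance.to_numpy() == IMPUTED
        rmse = float(np.sqrt(np.mean((tv[imp] - cv[imp]) ** 2)))
        _noise_results[scale] = rmse
        if len(_noise_results) == 3:
            levels = sorted(_noise_results)
            errs = [_noise_results[k] for k in levels]
            assert errs[0] < errs[1] < errs[2]


class TestSelectX:
    def _ratio_matrix(self, x1, x2, subtypes=None, datasets=None):
        n = len(x1)
        vals = pd.DataFrame(
            {
                "RR": 1.0,
                "RA": 0.05,
                "RB": 0.10,
                "RE": 0.18,
                "RX1": x1,
                "RX2": x2,
                "RY": 0.50,
                "RO": 0.62,
                "RZ": 0.75,
            },
            index=range(n),
        )[["RR"] + POINT_COLUMNS]
        meta = pd.DataFrame(
            {
                "subject_id": ["s"] * n,
                "dataset_id": datasets or ["D"] * n,
                "subtype": subtypes or ["ABEXYOZ0"] * n,
                "beat_index": range(n),
            }
        )
        return IntervalMatrix(values=vals, row_meta=meta, state="raw")

    def test_argmin_wins(self):
        rng = np.random.default_rng(0)
        x1 = 0.30 + rng.normal(0, 0.005, 50)
        x2 = 0.38 + rng.normal(0, 0.02, 50)
        sel = select_x(self._ratio_matrix(x1, x2))
        assert sel.chosen("D") == "X1"
        assert sel.per_scope.loc["D", "sd_x1"] < sel.per_scope.loc["D", "sd_x2"]

    def test_tie_goes_to_x2(self):
        # exactly representable values with identical deviation patterns
        x = np.array([0.25, 0.75] * 10)
        sel = select_x(self._ratio_matrix(x, x + 0.5))
        assert sel.chosen("D") == "X2"

    def test_small_scope_rejected(self):
        with pytest.raises(ValidationError, match="sd undefined"):
            select_x(self._ratio_matrix([0.3], [0.38]))

    @pytest.mark.parametrize("true_x", [PointLabel.X1, PointLabel.X2])
    def test_recovers_designated_true_x(self, true_x):
        cfg = synthgen.CohortConfig(
            n_subjects=4, beats_per_subject=80, true_x=true_x, seed=13
        )
        beats, _ = synthgen.generate_cohort(cfg)
        m = build_interval_matrix(beats)
        sel = select_x(m)
        assert sel.chosen(cfg.dataset_id) == true_x.value


class TestDenormalize:
    def test_round_trip(self, fully_observed):
        norm, _ = fully_observed
        raw = denormalize(norm)
        renorm = pp.sum_of_squares_normalize(pp.normalize_by_rr(raw), scale=norm.ss_scale)
        assert np.allclose(
            renorm.values.to_numpy(), norm.values.to_numpy(), atol=1e-12, rtol=0
        )

    def test_arithmetic_example(self):
        vals = pd.DataFrame(
            [[0.8, 0.0625, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]],
            columns=["RR"] + POINT_COLUMNS,
        )
        meta = pd.DataFrame(
            {"subject_id": ["s"], "dataset_id": ["D"], "subtype": ["ABEXYOZ0"], "beat_index": [0]}
        )
        m = IntervalMatrix(
            values=vals,
            row_meta=meta,
            state="ss_normalized",
            ss_scale=pd.Series(1.0, index=POINT_COLUMNS),
        )
        raw = denormalize(m)
        assert raw.values.loc[0, "RA"] == pytest.approx(0.05)

    def test_zero_scale_rejected(self, fully_observed):
        norm, _ = fully_observed
        bad = norm.ss_scale.copy()
        bad.iloc[0] = 0.0
        with pytest.raises(ValidationError):
            denormalize(norm, ss_scale=bad)

    def test_missing_scale_rejected(self, fully_observed):
        norm, _ = fully_observed
        m = norm.copy()
        m.state = "rr_normalized"
        m.ss_scale = None
        with pytest.raises(StateError):
            denormalize(m)
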