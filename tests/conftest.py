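import numpy as np
import pytest

from icgnarx import pipeline, synthgen
from icgnarx.icg_data import AnnotatedComplex, PointLabel, SubtypeLabel


@pytest.fixture
def small_beats() -> list[AnnotatedComplex]:
    """Two subjects, three beats each, hand-built with known latencies."""

    def beat(subj, i, r, missing=(), subtype=SubtypeLabel.ABEXYOZ0):
        latencies = {
            PointLabel.A: 0.05,
            PointLabel.B: 0.10,
            PointLabel.E: 0.18,
            PointLabel.X1: 0.30,
            PointLabel.X2: 0.38,
            PointLabel.Y: 0.50,
            PointLabel.O: 0.62,
            PointLabel.Z: 0.75,
        }
        return AnnotatedComplex(
            subject_id=subj,
            dataset_id="D1",
            beat_index=i,
            r_time=r,
            point_times={p: r + v for p, v in latencies.items() if p not in missing},
            subtype=subtype,
        )

    return [
        beat("s1", 0, 0.0),
        beat("s1", 1, 0.8, missing=(PointLabel.X2,)),
        beat("s1", 2, 1.6),
        beat("s2", 0, 0.0),
        beat("s2", 1, 0.9),
        beat("s2", 2, 1.85),
    ]


@pytest.fixture(scope="session")
def study():
    """The default two-device synthetic study (8 subjects x 100 beats)."""
    return synthgen.generate_study(seed=1)


@pytest.fixture(scope="session")
def pipeline_result(study):
    """One full end-to-end run shared across tests (seeded)."""
    beats, _truth = study
    return pipeline.run_pipeline(beats=beats, seed=1, max_epochs=100)
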