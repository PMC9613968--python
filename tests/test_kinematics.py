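import numpy as np
import pandas as pd
import pytest

from gaitcomplexity import (
    FootContactSeries,
    GaitGenConfig,
    KinematicsTrial,
    generate_gait,
    load_trial,
    save_trial,
    segment_cycles,
    time_normalize,
)
from gaitcomplexity.kinematics import canonical_order, load_cycles, save_cycles


def _trial(samples, fs=60.0):
    p = samples.shape[1]
    chans = ["hip_L_sagittal", "knee_L_sagittal", "ankle_L_sagittal"][:p]
    return KinematicsTrial(samples=samples, fs=fs, channels=chans)


class TestLoadTrial:
    def test_roundtrip_small_fixture(self, tmp_path):
        path = tmp_path / "t.csv"
        pd.DataFrame(
            {
                "time": [0.0, 1 / 60, 2 / 60],
                "knee_L_sagittal": [1.0, 2.0, 3.0],
                "hip_L_sagittal": [4.0, 5.0, 6.0],
            }
        ).to_csv(path, index=False)
        trial = load_trial(path)
        assert trial.samples.shape == (3, 2)
        # canonical order puts hip before knee
        assert trial.channels == ("hip_L_sagittal", "knee_L_sagittal")
        assert trial.samples[0].tolist() == [4.0, 1.0]

    def test_nan_cell_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {"time": [0.0, 0.1, 0.2], "hip_L_sagittal": [1.0, np.nan, 3.0]}
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match=r"row 1.*hip_L_sagittal"):
            load_trial(path)

    def test_unknown_label_lists_valid(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"time": [0.0, 0.1], "elbow_L_sagittal": [1.0, 2.0]}).to_csv(
            path, index=False
        )
        with pytest.raises(ValueError, match="valid labels"):
            load_trial(path)

    def test_synthetic_write_read_bitwise(self, tmp_path):
        trial, _, _ = generate_gait(GaitGenConfig(seed=5, n_strides=10))
        path = tmp_path / "syn.csv"
        save_trial(trial, path)
        back = load_trial(path)
        # CSV round-trip via repr-exact float formatting
        np.testing.assert_array_equal(back.samples, trial.samples)
        assert back.channels == trial.channels


class TestSegmentCycles:
    def test_event_counts(self):
        trial = _trial(np.zeros((180, 2)) + np.arange(180)[:, None])
        cycles = segment_cycles(trial, FootContactSeries(events=[0, 60, 120]))
        assert len(cycles) == 2
        assert all(len(c) == 60 for c in cycles)
        assert len(segment_cycles(trial, FootContactSeries(events=[0, 60]))) == 1

    def test_too_few_events(self):
        trial = _trial(np.zeros((100, 1)))
        with pytest.raises(ValueError, match="cannot segment"):
            segment_cycles(trial, FootContactSeries(events=[10]))

    def test_short_cycles_dropped_with_warning(self):
        trial = _trial(np.zeros((200, 1)))
        with pytest.warns(UserWarning, match="dropped 1 cycle"):
            cycles = segment_cycles(
                trial, FootContactSeries(events=[0, 5, 100]), min_duration_s=0.4
            )
        assert len(cycles) == 1

    def test_generator_bookkeeping(self):
        cfg = GaitGenConfig(seed=21, n_strides=50, stride_duration_cv=0.05)
        trial, contacts, gt = generate_gait(cfg)
        cycles = segment_cycles(trial, contacts)
        assert len(cycles) == 50
        assert [len(c) for c in cycles] == gt["stride_frames"]


class TestTimeNormalize:
    def test_identity_grid(self):
        cyc = np.arange(101 * 2, dtype=float).reshape(101, 2)
        out = time_normalize([cyc]).cycles[0]
        np.testing.assert_allclose(out, cyc, atol=1e-12)

    def test_linear_ramp_preserved(self):
        ramp = np.linspace(0, 10, 34)[:, None]
        out = time_normalize([ramp]).cycles[0, :, 0]
        np.testing.assert_allclose(out, np.linspace(0, 10, 101), atol=1e-12)

    def test_endpoints_exact(self, rng):
        cyc = rng.normal(size=(37, 3))
        out = time_normalize([cyc]).cycles[0]
        np.testing.assert_array_equal(out[0], cyc[0])
        np.testing.assert_array_equal(out[-1], cyc[-1])

    def test_sine_against_analytic(self):
        t = np.arange(60) / 60.0
        cyc = np.sin(2 * np.pi * t)[:, None]
        out = time_normalize([cyc]).cycles[0, :, 0]
        # the normalized curve interpolates x(phase * (59/60)) on the 101-grid
        phase = np.linspace(0, t[-1], 101)
        assert np.abs(out - np.sin(2 * np.pi * phase)).max() < 0.01

    def test_idempotent(self, rng):
        cyc = rng.normal(size=(50, 2))
        once = time_normalize([cyc]).cycles[0]
        twice = time_normalize([once]).cycles[0]
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_too_short_cycle(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            time_normalize([np.zeros((1, 2))])


def test_segment_then_normalize_shape():
    cfg = GaitGenConfig(seed=3, n_strides=20, p=6)
    trial, contacts, _ = generate_gait(cfg)
    cycles = time_normalize(segment_cycles(trial, contacts))
    assert cycles.cycles.shape == (20, 101, 6)


def test_canonical_order_stable():
    labels = ["ankle_R_frontal", "hip_L_sagittal", "knee_L_transverse"]
    assert canonical_order(labels) == [
        "hip_L_sagittal",
        "knee_L_transverse",
        "ankle_R_frontal",
    ]


def test_cycles_csv_roundtrip(tmp_path, rng):
    from gaitcomplexity import NormalizedCycleSet

    cyc = NormalizedCycleSet(
        cycles=rng.normal(size=(3, 101, 2)), channels=("hip_L_sagittal", "knee_L_sagittal")
    )
    path = tmp_path / "cycles.csv"
    save_cycles(cyc, path)
    back = load_cycles(path)
    np.testing.assert_array_equal(back.cycles, cyc.cycles)
    assert back.channels == cyc.channels
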