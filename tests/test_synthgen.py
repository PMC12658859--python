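import math

import numpy as np
import pandas as pd
import pytest

import scquant as sq
from scquant.synthgen import _gaussian_pulse_weights


class TestSimulateScTrace:
    def test_no_signal_sources_gives_all_zero_trace(self, sc_acq, sc_calib):
        sim = sq.SimConfig(seed=0, background_lambda=0.0, event_rate=0.0)
        res = sq.simulate_sc_trace(sim, sc_acq, sc_calib)
        assert not res.trace.intensities.any()
        assert res.truth.empty

    def test_identical_seeds_are_bit_identical(self, sc_acq, sc_calib):
        sim = sq.SimConfig(seed=7, event_rate=2.0, doublet_fraction=0.1)
        a = sq.simulate_sc_trace(sim, sc_acq, sc_calib)
        b = sq.simulate_sc_trace(sim, sc_acq, sc_calib)
        np.testing.assert_array_equal(a.trace.intensities, b.trace.intensities)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_event_count_follows_poisson_rate_law(self, sc_acq, sc_calib):
        # rate 2/s for 180 s -> 360 expected; a single draw stays within
        # 3*sqrt(360), and the mean over seeds much closer
        counts = [
            len(sq.simulate_sc_trace(sq.SimConfig(seed=s, event_rate=2.0),
                                     sc_acq, sc_calib).truth)
            for s in range(15)
        ]
        assert all(abs(c - 360) < 3 * math.sqrt(360) for c in counts)
        assert abs(np.mean(counts) - 360) < 3 * math.sqrt(360 / len(counts))

    def test_trace_length_and_metadata(self, sc_acq, sc_calib):
        res = sq.simulate_sc_trace(sq.SimConfig(seed=1), sc_acq, sc_calib)
        assert res.trace.intensities.size == 36_000
        assert res.config["seed"] == 1

    def test_sedimentation_halves_late_rate(self, sc_calib):
        # with halflife = duration/2, the first half holds more events than
        # the second in expectation
        first, second = [], []
        acq = sq.AcquisitionConfig(flow_rate_ul_min=10, dwell_time_s=5e-3,
                                   duration_s=120, transport_efficiency=0.48)
        for seed in range(25):
            sim = sq.SimConfig(seed=seed, event_rate=3.0, sedimentation_halflife_s=60.0)
            truth = sq.simulate_sc_trace(sim, acq, sc_calib).truth
            t = truth["dwell_index"].to_numpy() * acq.dwell_time_s
            first.append(int((t < 60).sum()))
            second.append(int((t >= 60).sum()))
        assert np.mean(first) > np.mean(second)

    def test_rejects_bad_inputs(self, sc_acq, sc_calib):
        with pytest.raises(ValueError):
            sq.AcquisitionConfig(flow_rate_ul_min=10, dwell_time_s=5e-3, duration_s=0)
        with pytest.raises(ValueError):
            sq.CalibrationModel(element="Lu175", slope=-1.0, intercept=0.0,
                                intercept_sd=0.0, r_squared=1.0)

    def test_sidecar_files_written(self, tmp_path, sc_acq, sc_calib):
        res = sq.simulate_sc_trace(sq.SimConfig(seed=3, event_rate=1.0), sc_acq, sc_calib)
        res.write(tmp_path / "run1")
        assert (tmp_path / "run1.trace.csv").exists()
        assert (tmp_path / "run1.truth.csv").exists()
        assert "seed" in (tmp_path / "run1.config.json").read_text()


class TestSimulateCytofStream:
    def test_requires_channels(self, cytof_acq):
        sim = sq.SimConfig(seed=0)
        with pytest.raises(ValueError):
            sq.simulate_cytof_stream(sim, cytof_acq, [])

    def test_all_cells_when_no_beads_or_doublets(self, cytof_calibs):
        sim = sq.SimConfig(seed=2, background_lambda=0.02, event_rate=100.0)
        acq = sq.AcquisitionConfig(flow_rate_ul_min=30, dwell_time_s=13e-6,
                                   duration_s=5, transport_efficiency=0.15)
        res = sq.simulate_cytof_stream(sim, acq, cytof_calibs)
        assert set(res.truth["label"]) == {"cell"}

    def test_determinism(self, cytof_calibs):
        sim = sq.SimConfig(seed=9, background_lambda=0.02, event_rate=100.0,
                           bead_fraction=0.1, doublet_fraction=0.05)
        acq = sq.AcquisitionConfig(flow_rate_ul_min=30, dwell_time_s=13e-6,
                                   duration_s=3, transport_efficiency=0.15)
        calibs = sq.default_cytof_calibrations(
            ["Ir191", "Ir193", "Lu175", "Y89", "In115", "Ce140", "Tb159", "Bi209"])
        a = sq.simulate_cytof_stream(sim, acq, calibs)
        b = sq.simulate_cytof_stream(sim, acq, calibs)
        np.testing.assert_array_equal(a.stream.counts, b.stream.counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_pulse_counts_conserved_per_event(self, cytof_calibs):
        # with zero background every count in an event window was injected
        # by that cell: stream slice sum equals integrated ground truth
        sim = sq.SimConfig(seed=4, background_lambda=0.0, event_rate=50.0)
        acq = sq.AcquisitionConfig(flow_rate_ul_min=30, dwell_time_s=13e-6,
                                   duration_s=2, transport_efficiency=0.15)
        res = sq.simulate_cytof_stream(sim, acq, cytof_calibs)
        total_in_windows = 0
        for _, row in res.truth.iterrows():
            s, d = int(row.start_index), int(row.duration_points)
            total_in_windows += res.stream.counts[s:s + d].sum()
        assert total_in_windows == res.stream.counts.sum()

    def test_bead_fraction_binomial(self, cytof_acq):
        calibs = sq.default_cytof_calibrations(
            ["Ir191", "Ir193", "Lu175", "Y89", "In115", "Ce140", "Tb159", "Bi209"])
        sim = sq.SimConfig(seed=31, background_lambda=0.02, event_rate=100.0,
                           bead_fraction=0.1)
        acq = sq.AcquisitionConfig(flow_rate_ul_min=30, dwell_time_s=13e-6,
                                   duration_s=75, transport_efficiency=0.15)
        truth = sq.simulate_cytof_stream(sim, acq, calibs).truth
        n = len(truth)
        n_beads = int((truth["label"] == "bead").sum())
        sigma = math.sqrt(n * 0.1 * 0.9)
        assert abs(n_beads - 0.1 * n) <= 3 * sigma

    def test_pulse_weights_normalised_and_symmetric(self):
        for d in (10, 41, 150):
            w = _gaussian_pulse_weights(d)
            assert w.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(w, w[::-1])


class TestSimulateNpRun:
    def test_completeness_one_recovers_introduced(self):
        acq = sq.AcquisitionConfig(flow_rate_ul_min=10, dwell_time_s=5e-3, duration_s=180)
        # conc * F * duration = 300 introduced
        counts = [len(sq.simulate_np_counting_run(1e4, acq, 1.0, seed=s).truth)
                  for s in range(10)]
        assert all(abs(c - 300) <= 3 * math.sqrt(300) for c in counts)

    def test_expected_introduced_arithmetic(self):
        acq = sq.AcquisitionConfig(flow_rate_ul_min=10, dwell_time_s=5e-3, duration_s=180)
        run = sq.simulate_np_counting_run(1e4, acq, 0.5, seed=0)
        assert run.config["introduced"] == pytest.approx(300.0)

    def test_zero_completeness_or_concentration_gives_no_spikes(self):
        acq = sq.AcquisitionConfig(flow_rate_ul_min=10, dwell_time_s=5e-3, duration_s=60)
        assert sq.simulate_np_counting_run(0.0, acq, 0.5, seed=1).truth.empty
        assert sq.simulate_np_counting_run(1e4, acq, 0.0, seed=1).truth.empty

    def test_invalid_inputs(self):
        acq = sq.AcquisitionConfig(flow_rate_ul_min=10, dwell_time_s=5e-3, duration_s=60)
        with pytest.raises(ValueError):
            sq.simulate_np_counting_run(-1.0, acq, 0.5)
        with pytest.raises(ValueError):
            sq.simulate_np_counting_run(1e4, acq, 1.5)
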