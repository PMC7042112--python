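"""Generator correctness: cell fields, transient kernel, hierarchical
trace simulation and the forward imaging model."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import ndimage

from endoca.presets import preset
from endoca.synthetic import (NoiseModel, apex_offset_s, generate_cell_map,
                              render_movie, sample_roi_counts,
                              simulate_patch, simulate_traces,
                              transient_kernel)


class TestCellMap:
    def test_single_cell(self):
        cm = generate_cell_map(256, 256, 1, 0.4, seed=1)
        ids = np.unique(cm.labels)
        assert list(ids) == [0, 1]
        assert (cm.labels == 1).sum() >= 20

    def test_field_of_100_cells(self):
        cm = generate_cell_map(512, 512, 100, 0.4, seed=7)
        ids = np.unique(cm.labels)
        assert list(ids) == list(range(101))  # consecutive 1..100
        counts = cm.pixel_counts()
        assert counts.min() >= 20
        # each cell one 4-connected component
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        for i in (1, 37, 100):
            _, n = ndimage.label(cm.labels == i, structure=structure)
            assert n == 1

    def test_deterministic(self):
        a = generate_cell_map(512, 512, 100, 0.4, seed=7)
        b = generate_cell_map(512, 512, 100, 0.4, seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_overdense_raises(self):
        with pytest.raises(ValueError, match="dense"):
            generate_cell_map(64, 64, 500, 0.4, seed=0)


class TestTransientKernel:
    def test_causal_before_onset(self):
        assert transient_kernel(np.array([14.0]), 15.0, 1.0)[0] == 0.0

    def test_peak_normalization(self):
        t = np.arange(0, 40, 0.001)
        k = transient_kernel(t, 5.0, 1.41, 0.3, 3.0)
        assert k.max() == pytest.approx(1.41, abs=1e-6)
        assert k.min() >= 0

    def test_argmax_matches_closed_form(self):
        # dense grid search against the analytic apex time
        rise, decay = 0.2, 2.0
        t = np.arange(0, 20, 1e-4)
        k = transient_kernel(t, 3.0, 1.0, rise, decay)
        t_grid_max = t[np.argmax(k)]
        t_closed = 3.0 + rise * decay / (decay - rise) * math.log(decay / rise)
        assert t_grid_max == pytest.approx(t_closed, abs=1e-3)
        assert apex_offset_s(rise, decay) == pytest.approx(t_closed - 3.0)

    def test_unimodal(self):
        t = np.arange(0, 30, 0.01)
        k = transient_kernel(t, 2.0, 1.0)
        d = np.diff(k[(t > 2.01)])
        sign_changes = np.sum(np.diff(np.sign(d[d != 0])) != 0)
        assert sign_changes <= 1

    @pytest.mark.parametrize("rise,decay", [(0.0, 3.0), (-1.0, 3.0),
                                            (3.0, 0.3), (2.0, 2.0)])
    def test_invalid_taus_rejected(self, rise, decay):
        with pytest.raises(ValueError):
            transient_kernel(np.zeros(3), 0.0, 1.0, rise, decay)


class TestSimulateTraces:
    def test_null_arm_traces_identically_one(self, small_arm):
        arm = dataclasses.replace(small_arm, responder_fraction=0.0,
                                  spontaneous_fraction=0.0)
        sim = simulate_traces(arm, seed=3)
        for rec in sim.recordings:
            assert np.all(rec.traces == 1.0)

    def test_baseline_exactly_one_before_first_event(self, small_arm):
        sim = simulate_traces(small_arm, seed=5)
        ev = sim.ground_truth.events
        for rec in sim.recordings:
            sel = ev[(ev.animal == rec.animal) & (ev.tech_rep == rec.tech_rep)]
            for c in range(rec.traces.shape[0]):
                cell_ev = sel[sel.cell_id == c + 1]
                first = (int(cell_ev.frame.min()) - 15 if len(cell_ev)
                         else rec.traces.shape[1])
                assert np.all(rec.traces[c, :max(first, 0)] == 1.0)

    def test_deterministic_for_fixed_seed(self, small_arm):
        a = simulate_traces(small_arm, seed=42)
        b = simulate_traces(small_arm, seed=42)
        for ra, rb in zip(a.recordings, b.recordings):
            assert np.array_equal(ra.traces, rb.traces)
        assert a.ground_truth.events.equals(b.ground_truth.events)

    def test_caffeine_like_arm_event_fraction(self, small_arm):
        # stimulus-free arm: only the spontaneous fraction of cells is active
        arm = dataclasses.replace(small_arm, stimulus="none",
                                  responder_fraction=0.0,
                                  spontaneous_fraction=0.16,
                                  n_animals=1, n_cells=50)
        active = []
        for seed in range(30):
            sim = simulate_traces(arm, seed=seed)
            for rec in sim.recordings:
                active.extend((rec.traces > 1.0).any(axis=1))
        frac = np.mean(active)
        n = len(active)
        assert abs(frac - 0.16) < 3 * math.sqrt(0.16 * 0.84 / n)

    def test_grand_mean_recovers_preset_mean(self, small_arm):
        # law of large numbers over replicate seeds for the hierarchy
        arm = dataclasses.replace(small_arm, n_cells=10)
        means = [simulate_traces(arm, seed=s).ground_truth.per_animal_mean.mean()
                 for s in range(120)]
        mc_sem = np.std(means, ddof=1) / math.sqrt(len(means))
        assert np.mean(means) == pytest.approx(arm.mean_peak_amp,
                                               abs=4 * mc_sem + 0.01)

    def test_per_animal_mean_matches_event_table(self, small_arm):
        sim = simulate_traces(small_arm, seed=9)
        ev = sim.ground_truth.events
        stim = ev[ev.kind == "stimulus"]
        for a in range(small_arm.n_animals):
            amps = stim[stim.animal == a].amplitude
            if len(amps):
                assert sim.ground_truth.per_animal_mean[a] == pytest.approx(
                    amps.mean())


class TestRenderMovie:
    def test_high_photon_limit(self, tiny_cell_map):
        traces = np.ones((tiny_cell_map.n_cells, 3))
        movie = render_movie(traces, tiny_cell_map, baseline_counts=1e6,
                             read_noise_sd=0.0, bleach_rate_per_frame=0.0,
                             seed=0)
        for i in range(1, tiny_cell_map.n_cells + 1):
            mean = movie.frames[0][tiny_cell_map.labels == i].mean()
            assert abs(mean - 1e6) / 1e6 < 0.005

    def test_deterministic(self, tiny_cell_map):
        traces = 1 + 0.5 * np.random.default_rng(0).random(
            (tiny_cell_map.n_cells, 4))
        a = render_movie(traces, tiny_cell_map, seed=5)
        b = render_movie(traces, tiny_cell_map, seed=5)
        assert np.array_equal(a.frames, b.frames)

    def test_bleaching_decays_signal_geometrically(self, tiny_cell_map):
        traces = np.ones((tiny_cell_map.n_cells, 50))
        movie = render_movie(traces, tiny_cell_map, baseline_counts=1000.0,
                             read_noise_sd=0.0, bleach_rate_per_frame=0.01,
                             shot_noise=False, seed=0)
        cell = tiny_cell_map.labels == 1
        means = movie.frames[:, cell].mean(axis=1)
        expected = 1000.0 * (1 - 0.01) ** np.arange(50)
        np.testing.assert_allclose(means, expected, rtol=1e-4)  # float32

    def test_negative_noise_rejected(self, tiny_cell_map):
        traces = np.ones((tiny_cell_map.n_cells, 2))
        with pytest.raises(ValueError):
            render_movie(traces, tiny_cell_map, read_noise_sd=-1.0)
        with pytest.raises(ValueError):
            render_movie(traces, tiny_cell_map, baseline_counts=0.0)

    def test_roi_sampler_matches_render_extract_distribution(
            self, tiny_cell_map):
        """The direct ROI-mean sampler must agree with rendering a movie and
        averaging pixels, in mean and variance."""
        from endoca.roi import extract_traces
        T = 400
        traces = np.ones((tiny_cell_map.n_cells, T)) * 1.2
        noise = NoiseModel(baseline_counts=150.0, read_noise_sd=2.0,
                           bleach_rate_per_frame=0.0)
        movie = render_movie(traces, tiny_cell_map, 150.0, 2.0, 0.0, seed=1)
        extracted = extract_traces(movie, tiny_cell_map).traces
        fast = sample_roi_counts(traces, tiny_cell_map.pixel_counts(),
                                 noise, 2)
        n_px = tiny_cell_map.pixel_counts()
        for i in range(tiny_cell_map.n_cells):
            lam = 150.0 * 1.2
            exp_var = lam / n_px[i] + 4.0 / n_px[i]
            assert extracted[i].mean() == pytest.approx(lam, rel=0.02)
            assert fast[i].mean() == pytest.approx(lam, rel=0.02)
            # variances agree with theory within Monte-Carlo slack
            assert extracted[i].var() == pytest.approx(exp_var, rel=0.45)
            assert fast[i].var() == pytest.approx(exp_var, rel=0.45)


class TestPatchProtocol:
    def test_windows_partition_record(self):
        sim = simulate_patch(preset("patch_ach_caffeine"), seed=0)
        spans = sorted(sim.windows.values())
        assert spans[0][0] == 0
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 == b0
        assert spans[-1][1] == sim.recordings[0].traces.shape[1]

    def test_active_cells_have_events_in_their_window(self):
        sim = simulate_patch(preset("patch_ach_caffeine"), seed=2)
        rec = sim.recordings[0]
        for name, (w0, w1) in sim.windows.items():
            flags = sim.active[name][0]
            seg = rec.traces[:, w0:w1]
            bumped = (seg > 1.001).any(axis=1)
            # every planted-active cell shows signal in its own window
            assert np.all(bumped[flags])
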