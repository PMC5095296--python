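import numpy as np
import pytest

from orthospace.population import (
    MOVEMENT_EPOCH,
    PREPARATORY_EPOCH,
    EpochDef,
    PopulationResponse,
    SchemaError,
    SpikeTrains,
    extract_epoch,
    mean_center,
    preprocess,
    read_dataset,
    smooth_and_average,
    soft_normalize,
    write_dataset,
)


def toy_response(rates, normalized=False, centered=False):
    rates = np.asarray(rates, float)
    t = rates.shape[2]
    return PopulationResponse(
        rates=rates,
        time_ms=np.arange(t) * 10.0,
        events={"target_onset_ms": 0.0, "go_cue_ms": 0.0, "move_onset_ms": 0.0},
        normalized=normalized,
        centered=centered,
    )


class TestPopulationResponse:
    def test_rejects_irregular_time_grid(self):
        with pytest.raises(ValueError, match="10 ms"):
            PopulationResponse(
                rates=np.zeros((1, 1, 3)),
                time_ms=np.array([0.0, 10.0, 25.0]),
                events={"target_onset_ms": 0, "go_cue_ms": 0, "move_onset_ms": 0},
            )

    def test_rejects_negative_raw_rates_and_events_outside_range(self):
        with pytest.raises(ValueError, match="non-negative"):
            toy_response(-np.ones((1, 1, 3)))
        with pytest.raises(ValueError, match="outside recorded range"):
            PopulationResponse(
                rates=np.zeros((1, 1, 3)),
                time_ms=np.arange(3) * 10.0,
                events={"target_onset_ms": 0, "go_cue_ms": 500, "move_onset_ms": 0},
            )

    def test_missing_event_is_schema_error(self):
        with pytest.raises(SchemaError, match="go_cue_ms"):
            PopulationResponse(
                rates=np.zeros((1, 1, 3)),
                time_ms=np.arange(3) * 10.0,
                events={"target_onset_ms": 0, "move_onset_ms": 0},
            )


class TestSmoothing:
    def test_single_spike_gives_unit_area_gaussian_bump(self):
        sd = 20.0
        grid = np.arange(-200.0, 201.0, 10.0)
        spikes = SpikeTrains(
            trials={(0, 0): [np.array([0.0])]},
            window_ms=(-200.0, 200.0), n_neurons=1, n_conditions=1,
        )
        resp = smooth_and_average(spikes, kernel_sd_ms=sd, grid=grid)
        expected = 1000.0 * np.exp(-0.5 * (grid / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        # away from the window edges the renormalization factor is ~1
        interior = np.abs(grid) < 100
        np.testing.assert_allclose(resp.rates[0, 0][interior], expected[interior], rtol=1e-6)

    def test_no_spikes_gives_zero_rates(self):
        spikes = SpikeTrains(
            trials={(0, 0): [np.array([])]}, window_ms=(0.0, 100.0),
            n_neurons=1, n_conditions=1,
        )
        resp = smooth_and_average(spikes)
        assert np.all(resp.rates == 0.0)

    def test_poisson_rate_recovered_within_sem(self):
        # constant 50 spikes/s over 1 s, 200 trials
        rng = np.random.default_rng(5)
        trials = []
        for _ in range(200):
            n = rng.poisson(50.0)
            trials.append(np.sort(rng.random(n) * 1000.0))
        spikes = SpikeTrains(
            trials={(0, 0): trials}, window_ms=(0.0, 1000.0),
            n_neurons=1, n_conditions=1,
        )
        resp = smooth_and_average(spikes)
        interior = (resp.time_ms > 100) & (resp.time_ms < 900)
        mean_rate = resp.rates[0, 0][interior].mean()
        sem = np.sqrt(50.0 / (200 * 1.0))  # Poisson rate sem over the window
        assert abs(mean_rate - 50.0) < 3 * sem

    def test_missing_trials_error_names_pair(self):
        spikes = SpikeTrains(
            trials={(0, 0): [np.array([1.0])]}, window_ms=(0.0, 10.0),
            n_neurons=2, n_conditions=1,
        )
        with pytest.raises(ValueError, match="neuron 1, condition 0"):
            smooth_and_average(spikes)


class TestSoftNormalize:
    def test_divides_by_range_plus_offset(self):
        rates = np.zeros((1, 2, 4))
        rates[0, 0] = [0, 15, 45, 30]  # range 45 -> factor 50
        resp = soft_normalize(toy_response(rates))
        np.testing.assert_allclose(resp.rates[0, 0], np.array([0, 15, 45, 30]) / 50.0)
        assert resp.normalized

    def test_constant_neuron_divided_by_offset_only(self):
        resp = soft_normalize(toy_response(7.0 * np.ones((1, 1, 4))))
        np.testing.assert_allclose(resp.rates, 7.0 / 5.0)

    def test_range_95_gives_postnorm_range_095(self):
        rates = np.zeros((1, 1, 3))
        rates[0, 0] = [0, 95, 20]
        resp = soft_normalize(toy_response(rates))
        assert np.isclose(resp.rates.max() - resp.rates.min(), 0.95)

    def test_negative_offset_and_double_application_raise(self):
        resp = toy_response(np.ones((1, 1, 3)))
        with pytest.raises(ValueError, match="offset"):
            soft_normalize(resp, offset=-1.0)
        once = soft_normalize(resp)
        with pytest.raises(ValueError, match="already"):
            soft_normalize(once)


class TestMeanCenter:
    def test_identical_conditions_center_to_zero(self):
        rates = np.tile(np.arange(4.0), (2, 3, 1))
        resp = mean_center(toy_response(rates))
        assert np.all(resp.rates == 0.0)

    def test_two_conditions_become_symmetric_contrast(self):
        rates = np.zeros((1, 2, 1))
        rates[0, 0, 0], rates[0, 1, 0] = 8.0, 2.0
        resp = mean_center(toy_response(rates))
        np.testing.assert_allclose(resp.rates[0, :, 0], [3.0, -3.0])

    def test_random_tensor_mean_below_1e12(self):
        rng = np.random.default_rng(0)
        resp = mean_center(toy_response(rng.random((5, 8, 12)) * 40))
        assert np.abs(resp.rates.mean(axis=1)).max() <= 1e-12


class TestExtractEpoch:
    def make_resp(self):
        rng = np.random.default_rng(1)
        rates = rng.random((6, 8, 100)) * 30
        resp = PopulationResponse(
            rates=rates, time_ms=np.arange(100) * 10.0,
            events={"target_onset_ms": 0.0, "go_cue_ms": 500.0, "move_onset_ms": 650.0},
        )
        return preprocess(resp)

    def test_300ms_epoch_8_conditions_gives_240_columns(self):
        m = extract_epoch(self.make_resp(), PREPARATORY_EPOCH)
        assert m.data.shape[1] == 240
        assert m.n_times == 30

    def test_zero_duration_epoch_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            EpochDef("bad", "target_onset_ms", 0, 0)

    def test_constant_zero_response_has_zero_covariance(self):
        resp = toy_response(np.zeros((3, 2, 40)), normalized=True, centered=True)
        m = extract_epoch(resp, EpochDef("p", "target_onset_ms", 0, 100))
        assert np.all(m.covariance == 0.0)
        assert list(m.zero_rate_neurons) == [0, 1, 2]

    def test_window_outside_range_reports_bounds(self):
        with pytest.raises(ValueError, match="not fully covered"):
            extract_epoch(self.make_resp(), EpochDef("late", "move_onset_ms", 300, 300))

    def test_requires_preprocessed_input(self):
        resp = toy_response(np.ones((1, 1, 40)))
        with pytest.raises(ValueError, match="normalized"):
            extract_epoch(resp, EpochDef("p", "target_onset_ms", 0, 100))

    def test_covariance_matches_brute_force_on_toy(self):
        resp = self.make_resp()
        m = extract_epoch(resp, MOVEMENT_EPOCH)
        brute = np.cov(m.data)
        np.testing.assert_allclose(m.covariance, brute, atol=1e-12)

    def test_column_order_is_condition_major(self):
        resp = self.make_resp()
        m = extract_epoch(resp, PREPARATORY_EPOCH)
        # column c*T + t must equal rates[:, c, idx[t]]
        np.testing.assert_array_equal(m.data[:, 1 * 30 + 3], resp.rates[:, 1, 15 + 3])


class TestPermutationEquivariance:
    def test_preprocessing_commutes_with_condition_relabeling(self):
        rng = np.random.default_rng(2)
        rates = rng.random((4, 6, 20)) * 25
        perm = rng.permutation(6)
        a = preprocess(toy_response(rates)).rates[:, perm]
        b = preprocess(toy_response(rates[:, perm])).rates
        np.testing.assert_allclose(a, b, atol=1e-14)


class TestIO:
    def base_resp(self):
        rng = np.random.default_rng(3)
        return PopulationResponse(
            rates=rng.random((4, 3, 50)) * 60,
            time_ms=np.arange(50) * 10.0,
            events={"target_onset_ms": 0.0, "go_cue_ms": 250.0, "move_onset_ms": 400.0},
            neuron_ids=["a", "b", "c", "d"],
        )

    @pytest.mark.parametrize("suffix", ["h5", "csv"])
    def test_round_trip_lossless(self, tmp_path, suffix):
        resp = self.base_resp()
        path = tmp_path / f"data.{suffix}"
        write_dataset(resp, path)
        back = read_dataset(path)
        np.testing.assert_array_equal(back.rates, resp.rates)
        assert back.events == resp.events
        assert back.neuron_ids == resp.neuron_ids

    def test_csv_and_hdf5_agree(self, tmp_path):
        resp = self.base_resp()
        write_dataset(resp, tmp_path / "d.h5")
        write_dataset(resp, tmp_path / "d.csv")
        a, b = read_dataset(tmp_path / "d.h5"), read_dataset(tmp_path / "d.csv")
        np.testing.assert_array_equal(a.rates, b.rates)

    def test_missing_event_field_is_schema_error(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        resp = self.base_resp()
        write_dataset(resp, path)
        with h5py.File(path, "a") as f:
            del f["events"].attrs["go_cue_ms"]
        with pytest.raises(SchemaError, match="go_cue_ms"):
            read_dataset(path)
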