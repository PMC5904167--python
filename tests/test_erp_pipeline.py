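"""Pipeline tests: filter contracts, epoching/baseline mechanics, artifact
screening, condition binning, inclusion rule and component measurement."""

import logging

import numpy as np
import pandas as pd
import pytest

from infoseek import erp_pipeline as erp
from infoseek import synthetic_eeg as seeg
from infoseek import task_simulator as sim


def sine_recording(freq, fs=512.0, seconds=20.0, channels=("Cz", "M1", "M2")):
    t = np.arange(int(fs * seconds)) / fs
    wave = np.sin(2 * np.pi * freq * t)
    data = np.tile(wave, (len(channels), 1))
    events = pd.DataFrame({"sample": [int(fs * seconds / 2)]})
    return seeg.Recording(fs, tuple(channels), data, events)


def tone_amplitude(x, freq, fs):
    """Amplitude of the ``freq`` Fourier component in the signal interior."""
    mid = x[int(2 * fs) : -int(2 * fs)]
    t = np.arange(mid.size) / fs
    return 2 * np.abs(np.mean(mid * np.exp(-2j * np.pi * freq * t)))


class TestPreprocess:
    def test_50hz_attenuated_at_least_20db(self):
        rec = sine_recording(50.0)
        out = erp.preprocess(rec, rereference=False)
        fs = rec.sample_rate
        ratio = tone_amplitude(out.data[0], 50.0, fs) / tone_amplitude(
            rec.data[0], 50.0, fs
        )
        assert 20 * np.log10(ratio) <= -20.0

    def test_passband_frequency_preserved(self):
        rec = sine_recording(10.0)
        out = erp.preprocess(rec, rereference=False)
        fs = rec.sample_rate
        ratio = tone_amplitude(out.data[0], 10.0, fs) / tone_amplitude(
            rec.data[0], 10.0, fs
        )
        assert ratio > 0.9

    def test_dc_offset_removed(self):
        rec = sine_recording(10.0)
        rec = seeg.Recording(
            rec.sample_rate, rec.channels,
            np.full_like(rec.data, 37.0), rec.events,
        )
        out = erp.preprocess(rec, rereference=False)
        assert np.abs(out.data).max() < 1e-6

    def test_rereference_idempotent(self, noisy_recording):
        once = erp.preprocess(noisy_recording)
        twice = erp.preprocess(
            once, detrend=False, l_freq=0.1, h_freq=70.0,
        )
        # mastoid mean is already zero, so only the (tiny) repeated filter
        # response differs; re-referencing itself changes nothing
        ref = once.data[[once.channel_index(m) for m in seeg.MASTOIDS]].mean(0)
        assert np.abs(ref).max() < 1e-9
        assert twice.data.shape == once.data.shape

    def test_missing_mastoid_is_configuration_error(self):
        rec = sine_recording(10.0, channels=("Cz", "Fz"))
        with pytest.raises(ValueError, match="mastoid"):
            erp.preprocess(rec)

    def test_low_sample_rate_rejected(self):
        rec = sine_recording(10.0, fs=128.0)
        with pytest.raises(ValueError, match="sample rate"):
            erp.preprocess(rec, rereference=False)


class TestEpoching:
    def test_epoch_count_matches_events(self, quiet_recording):
        epochs = erp.epoch_and_baseline(quiet_recording)
        assert epochs.n_epochs == len(quiet_recording.events)

    def test_baseline_mean_is_zero(self, noisy_recording):
        epochs = erp.epoch_and_baseline(noisy_recording)
        b = epochs.time_mask(*epochs.baseline)
        assert np.abs(epochs.data[:, :, b].mean(axis=2)).max() < 1e-10

    def test_constant_channel_epochs_are_zero(self):
        fs = 200.0
        data = np.full((3, 4000), 11.0)
        events = pd.DataFrame({"sample": [1000, 2500]})
        rec = seeg.Recording(fs, ("Cz", "M1", "M2"), data, events)
        epochs = erp.epoch_and_baseline(rec)
        assert np.abs(epochs.data).max() == 0.0

    def test_out_of_bounds_event_skipped_with_warning(self, caplog):
        fs = 200.0
        events = pd.DataFrame({"sample": [10, 1000]})
        rec = seeg.Recording(fs, ("Cz",), np.zeros((1, 2000)), events)
        with caplog.at_level(logging.WARNING):
            epochs = erp.epoch_and_baseline(rec)
        assert epochs.n_epochs == 1
        assert "skipped" in caplog.text

    def test_frn_peak_lands_in_measurement_window(
        self, small_session, no_noise, reduced_montage
    ):
        rec = seeg.synthesize_recording(
            small_session, specs=seeg.default_component_specs(),
            noise=no_noise, montage=reduced_montage, sample_rate=200.0, seed=0,
        )
        epochs = erp.epoch_and_baseline(rec)
        fcz = epochs.channel_index("FCz")
        card = epochs.labels["event_class"] == "card"
        wave = epochs.data[card.to_numpy()][:, fcz, :].mean(axis=0)
        peak_time = epochs.times[np.argmax(np.abs(wave))]
        assert 0.2 <= peak_time < 0.35

    def test_time_zero_on_post_stimulus_side(self, quiet_recording):
        epochs = erp.epoch_and_baseline(quiet_recording)
        assert 0.0 in epochs.times
        assert not epochs.time_mask(*epochs.baseline)[epochs.times == 0.0]


class TestRejection:
    def test_clean_epochs_retained(self, noisy_recording):
        epochs = erp.reject_artifacts(erp.epoch_and_baseline(noisy_recording))
        assert not epochs.rejected.any()

    def test_infinite_threshold_rejects_nothing(self, quiet_recording):
        rec, _ = seeg.inject_artifacts(quiet_recording, rate=1.0, seed=0)
        epochs = erp.reject_artifacts(
            erp.epoch_and_baseline(rec), threshold=np.inf
        )
        assert not epochs.rejected.any()

    def test_rejection_rate_tracks_injection_rate(
        self, small_session, no_noise, reduced_montage
    ):
        hits = total = 0
        for seed in range(5):
            rec = seeg.synthesize_recording(
                small_session, specs=seeg.default_component_specs(),
                noise=no_noise, montage=reduced_montage,
                sample_rate=200.0, seed=seed,
            )
            rec, _ = seeg.inject_artifacts(
                rec, rate=0.1, amplitude=400.0, seed=seed
            )
            epochs = erp.reject_artifacts(erp.epoch_and_baseline(rec))
            hits += int(epochs.rejected.sum())
            total += epochs.n_epochs
        assert hits / total == pytest.approx(0.1, abs=0.05)


@pytest.fixture(scope="module")
def epochs(quiet_recording):
    return erp.reject_artifacts(erp.epoch_and_baseline(quiet_recording))


class TestBinning:
    def test_first_cards_fall_in_zero_ipe_bin(self, epochs):
        bins = erp.bin_epochs(epochs, "ipe_sign_with_zero")
        first = np.flatnonzero(
            ((epochs.labels["card_index"] == 0)
             & (epochs.labels["event_class"] == "card")).to_numpy()
        )
        assert set(first) <= set(bins["zero"])

    def test_bins_disjoint_and_zero_scheme_exhaustive(self, epochs):
        bins = erp.bin_epochs(epochs, "ipe_sign_with_zero")
        all_idx = np.concatenate(list(bins.values()))
        assert len(all_idx) == len(set(all_idx))
        informative_cards = (
            (epochs.labels["event_class"] == "card")
            & (epochs.labels["stimulus_kind"] == "informative")
        ).sum()
        assert len(all_idx) == informative_cards

    def test_positive_information_commoner_than_negative(self, epochs):
        # the outcome is always known by card five, so certainty-increasing
        # cards outnumber certainty-decreasing ones
        bins = erp.bin_epochs(epochs, "info_sign")
        assert len(bins["pos"]) > len(bins["neg"])

    def test_outcome_scheme_selects_outcome_screens(self, epochs):
        bins = erp.bin_epochs(epochs, "outcome")
        idx = np.concatenate(list(bins.values()))
        assert (
            epochs.labels.loc[idx, "event_class"] == "outcome_screen"
        ).all()

    def test_unknown_scheme_rejected(self, epochs):
        with pytest.raises(ValueError, match="unknown binning scheme"):
            erp.bin_epochs(epochs, "no_such_scheme")

    def test_pseudo_bins_for_non_informative_stimuli(
        self, no_noise, reduced_montage
    ):
        task = sim.TaskParams(n_blocks=1, trials_per_block=10, catch_rate=0.0)
        session = sim.simulate_session(
            "p", agent=sim.AgentParams(info_value=-100.0), task=task, seed=2
        )
        rec = seeg.synthesize_recording(
            session, specs=seeg.default_component_specs(), noise=no_noise,
            montage=reduced_montage, sample_rate=200.0, seed=0,
        )
        epochs = erp.epoch_and_baseline(rec)
        assert all(
            len(v) == 0 for v in erp.bin_epochs(epochs, "ipe_sign").values()
        )
        pseudo = erp.bin_epochs(epochs, "pseudo_ipe_sign")
        assert len(pseudo["pos"]) > 0 and len(pseudo["neg"]) > 0


class TestInclusionRule:
    def test_counts_frame_boundary(self):
        counts = pd.DataFrame(
            {
                "participant": ["a", "a", "b", "b"],
                "condition": ["pos", "neg", "pos", "neg"],
                "n": [25, 25, 25, 19],
            }
        )
        assert erp.include_by_epoch_count(counts, min_epochs=20) == ["a"]

    def test_epochset_interface(self, quiet_recording):
        epochs = erp.epoch_and_baseline(quiet_recording)
        included = erp.include_by_epoch_count(
            epochs, scheme="ipe_sign", min_epochs=1
        )
        assert included == ["sub-01"]
        assert (
            erp.include_by_epoch_count(epochs, scheme="ipe_sign", min_epochs=10**6)
            == []
        )


class TestMeasurement:
    def test_single_sample_window_equals_that_sample(self, quiet_recording):
        epochs = erp.epoch_and_baseline(quiet_recording)
        fs = epochs.sample_rate
        mask = epochs.time_mask(0.25, 0.25 + 1.0 / fs)
        assert mask.sum() == 1
        cz = epochs.channel_index("Cz")
        sample = epochs.data[0, cz, mask][0]
        assert epochs.data[0, cz, :][mask][0] == sample

    def test_pipeline_linearity(self, quiet_recording):
        epochs1 = erp.epoch_and_baseline(quiet_recording)
        scaled = seeg.Recording(
            quiet_recording.sample_rate, quiet_recording.channels,
            3.0 * quiet_recording.data, quiet_recording.events.copy(),
        )
        epochs3 = erp.epoch_and_baseline(scaled)
        bins1 = erp.bin_epochs(epochs1, "ipe_sign")
        bins3 = erp.bin_epochs(epochs3, "ipe_sign")
        t1 = erp.measure_component(epochs1, "FRN", bins1)
        t3 = erp.measure_component(epochs3, "FRN", bins3)
        assert np.allclose(
            3.0 * t1["mean_amplitude"], t3["mean_amplitude"], atol=1e-9
        )

    def test_missing_channel_is_configuration_error(self, quiet_recording):
        epochs = erp.epoch_and_baseline(quiet_recording)
        bins = erp.bin_epochs(epochs, "ipe_sign")
        with pytest.raises(ValueError, match="channels missing"):
            erp.measure_component(epochs, "LPP", bins)  # montage is FRN-only

    def test_unknown_component_rejected(self, quiet_recording):
        epochs = erp.epoch_and_baseline(quiet_recording)
        with pytest.raises(ValueError, match="unknown component"):
            erp.measure_component(epochs, "P300", {})


def test_difference_wave_and_plot(quiet_recording, tmp_path):
    epochs = erp.epoch_and_baseline(quiet_recording)
    bins = erp.bin_epochs(epochs, "ipe_sign")
    diff = erp.difference_wave(epochs, bins)
    assert diff.shape == (len(epochs.channels), epochs.data.shape[2])
    out = tmp_path / "frn.png"
    erp.plot_difference_wave(epochs, bins, "FCz", out)
    assert out.stat().st_size > 0


def test_epochs_container_roundtrip(noisy_recording, tmp_path):
    epochs = erp.reject_artifacts(erp.epoch_and_baseline(noisy_recording))
    erp.save_epochs(epochs, tmp_path / "ep")
    back = erp.load_epochs(tmp_path / "ep")
    assert back.n_epochs == epochs.n_epochs
    assert back.window == epochs.window
    assert np.allclose(back.data, epochs.data, atol=1e-3)
    assert np.array_equal(back.rejected, epochs.rejected)
    bins_a = erp.bin_epochs(epochs, "ipe_sign")
    bins_b = erp.bin_epochs(back, "ipe_sign")
    for k in bins_a:
        assert np.array_equal(bins_a[k], bins_b[k])
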