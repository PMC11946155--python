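"""Filtering, validity rules, artifact rejection and epoch-count matching."""

import numpy as np
import pandas as pd
import pytest

from pawnpipe import (EpochSet, Recording, bandpass_filter, classify_trials,
                      extract_epochs, match_epoch_counts, reject_artifacts,
                      rereference)


def _rec(data, fs=1000.0):
    data = np.atleast_2d(data)
    return Recording(data=data, fs=fs,
                     channel_names=[f"ch{i}" for i in range(data.shape[0])])


class TestBandpass:
    def test_stopband_50hz(self):
        t = np.arange(10000) / 1000.0
        x = np.sin(2 * np.pi * 50 * t)
        y = bandpass_filter(_rec(x)).data[0]
        mid = slice(3000, 7000)  # avoid the long 0.1 Hz high-pass edge transients
        assert np.sqrt(np.mean(y[mid]**2)) < 0.05 * np.sqrt(np.mean(x[mid]**2))

    def test_passband_10hz_amplitude_and_zero_lag(self):
        t = np.arange(20000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t)
        y = bandpass_filter(_rec(x)).data[0]
        mid = slice(5000, 15000)  # steady state
        assert abs(np.sqrt(np.mean(y[mid]**2)) / np.sqrt(np.mean(x[mid]**2)) - 1) < 0.05
        lags = np.arange(-5, 6)
        xc = [np.dot(x[mid], np.roll(y, l)[mid]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_dc_removed(self):
        x = np.full(8000, 5.0)
        y = bandpass_filter(_rec(x)).data[0]
        assert np.abs(y[2000:6000]).max() < 0.05

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            bandpass_filter(_rec(np.zeros(100)), lo=0.1, hi=600.0)


def test_rereference_subtracts_channel_mean():
    data = np.vstack([np.ones(10), 3 * np.ones(10), np.zeros(10)])
    rec = rereference(_rec(data), ["ch0", "ch1"])
    assert np.allclose(rec.data[2], -2.0)


class TestClassifyTrials:
    def _events(self, rows):
        return pd.DataFrame(rows, columns=["onset_sample", "code", "rt_ms"])

    def test_valid_go(self):
        ev = self._events([(1000, "go", 340.0), (2100, "nogo", np.nan)])
        out = classify_trials(ev, 1100.0, 1000.0)
        assert out.valid.tolist() == [True, True]

    @pytest.mark.parametrize("rt", [100.0, 500.0])
    def test_rt_window_is_closed(self, rt):
        ev = self._events([(1000, "go", rt)])
        assert classify_trials(ev, 1100.0, 1000.0).valid.all()

    def test_late_press_invalidates_self_and_next_prestim(self):
        # press at 1000 + 700 = 1700 falls inside [1600, 2100) prestim of trial 2
        ev = self._events([(1000, "go", 700.0), (2100, "go", 340.0),
                           (3200, "go", 340.0)])
        out = classify_trials(ev, 1100.0, 1000.0)
        assert out.valid.tolist() == [False, False, True]
        assert out.invalid_reason.tolist()[:2] == ["rt_outside_window",
                                                   "prestimulus_response"]

    def test_late_press_outside_next_prestim_window(self):
        # press at 520 ms post-onset lands before the next prestim window opens
        ev = self._events([(1000, "go", 520.0), (2100, "go", 340.0)])
        out = classify_trials(ev, 1100.0, 1000.0)
        assert out.valid.tolist() == [False, True]

    def test_nogo_commission(self):
        # press at 300 ms: a commission, and early enough not to contaminate
        # the next trial's prestimulus window
        ev = self._events([(1000, "nogo", 300.0), (2100, "nogo", np.nan)])
        out = classify_trials(ev, 1100.0, 1000.0)
        assert out.valid.tolist() == [False, True]
        assert out.invalid_reason[0] == "commission"

    def test_late_nogo_commission_invalidates_next_prestim(self):
        ev = self._events([(1000, "nogo", 700.0), (2100, "nogo", np.nan)])
        out = classify_trials(ev, 1100.0, 1000.0)
        assert out.valid.tolist() == [False, False]
        assert out.invalid_reason.tolist() == ["commission", "prestimulus_response"]

    def test_go_omission(self):
        ev = self._events([(1000, "go", np.nan)])
        out = classify_trials(ev, 1100.0, 1000.0)
        assert not out.valid[0] and out.invalid_reason[0] == "omission"

    def test_duplicate_onsets_rejected(self):
        ev = self._events([(1000, "go", 340.0), (1000, "go", 340.0)])
        with pytest.raises(ValueError):
            classify_trials(ev, 1100.0, 1000.0)


def _epochs(data):
    n, c, t = data.shape
    return EpochSet(data=data, times_ms=np.arange(-t // 2, t - t // 2, dtype=float),
                    fs=1000.0, condition=np.array(["go"] * n, dtype=object),
                    reason=np.array(["none"] * n, dtype=object),
                    trial_index=np.arange(n))


class TestArtifactRejection:
    def test_constructed_oracle_exact_counts(self, rng):
        """100 epochs with planted violations are rejected for exactly the
        planted reason, honouring the extreme > jump > flat precedence."""
        n, c, t = 100, 3, 1000
        data = rng.normal(0.0, 5.0, (n, c, t))
        data = np.clip(data, -40, 40)
        planted = {"extreme": range(0, 10), "jump": range(10, 25),
                   "flat": range(25, 32), "both": range(32, 36)}
        for i in planted["extreme"]:
            data[i, 1, 400] = 130.0
        for i in planted["jump"]:
            data[i, 2, 500] = data[i, 2, 499] + 60.0
        for i in planted["flat"]:
            data[i, 0, :] = 0.001
        for i in planted["both"]:  # extreme AND jump -> counted extreme
            data[i, 0, 100] = 200.0
        out = reject_artifacts(_epochs(data))
        counts = out.rejection_counts()
        assert counts["extreme"] == 14  # 10 pure + 4 with secondary jump
        assert counts["jump"] == 15
        assert counts["flat"] == 7
        assert counts["none"] == 64

    def test_single_sample_above_threshold(self, rng):
        data = rng.normal(0, 1, (1, 2, 1000))
        data[0, 0, 10] = 130.0
        out = reject_artifacts(_epochs(data))
        assert out.reason[0] == "extreme"

    def test_zero_epoch_is_flat(self):
        out = reject_artifacts(_epochs(np.zeros((1, 2, 1000))))
        assert out.reason[0] == "flat"

    def test_flat_window_longer_than_epoch(self):
        with pytest.raises(ValueError):
            reject_artifacts(_epochs(np.zeros((1, 1, 50))), flat_win_ms=100.0)

    def test_invalid_trials_keep_their_reason(self, rng):
        ep = _epochs(np.zeros((2, 1, 1000)))
        ep.reason[0] = "invalid_trial"
        out = reject_artifacts(ep)
        assert out.reason.tolist() == ["invalid_trial", "flat"]


class TestMatchCounts:
    def _set(self, n, accepted=None):
        ep = _epochs(np.random.default_rng(0).normal(0, 1, (n, 1, 10)))
        if accepted is not None:
            ep.reason[accepted:] = "extreme"
        return ep

    def test_larger_set_subsampled(self):
        go, nogo, excl = match_epoch_counts(self._set(120), self._set(98),
                                            min_trials=50, seed=1)
        assert not excl
        assert go.accepted.sum() == 98 and nogo.accepted.sum() == 98

    def test_below_minimum_excludes(self):
        go, nogo, excl = match_epoch_counts(self._set(49), self._set(120),
                                            min_trials=50, seed=1)
        assert excl

    def test_equal_counts_unchanged(self):
        a, b = self._set(60), self._set(60)
        go, nogo, excl = match_epoch_counts(a, b, min_trials=50, seed=1)
        assert go.n_trials == 60 and nogo.n_trials == 60 and not excl

    def test_deterministic_and_duplicate_free(self):
        a1, b1, _ = match_epoch_counts(self._set(120), self._set(98), 50, seed=7)
        a2, b2, _ = match_epoch_counts(self._set(120), self._set(98), 50, seed=7)
        assert np.array_equal(a1.trial_index, a2.trial_index)
        assert len(np.unique(a1.trial_index)) == a1.n_trials


def test_extract_epochs_window_and_counts():
    rng = np.random.default_rng(0)
    rec = _rec(rng.normal(0, 1, (2, 10000)))
    ev = pd.DataFrame({"onset_sample": [2000, 3100, 4200],
                       "code": ["go", "nogo", "go"],
                       "rt_ms": [340.0, np.nan, 340.0]})
    ev = classify_trials(ev, 1100.0, 1000.0)
    ep = extract_epochs(rec, ev)
    assert ep.data.shape == (3, 2, 1000)
    assert ep.times_ms[0] == -500.0 and ep.times_ms[-1] == 499.0
    # prestimulus slice has exactly 500 samples
    assert int((ep.times_ms < 0).sum()) == 500
    assert np.allclose(ep.data[0, :, 0], rec.data[:, 1500])
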