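"""The eight-step cleaning chain, step by step and end to end."""

import numpy as np
import pytest

from restingnorm.preprocessing import (
    apply_filters,
    detect_flat_channels,
    epoch_signal,
    epoch_series,
    interpolate_bad_channels_per_epoch,
    make_bipolar_eog,
    preprocess,
    reject_epochs_adaptive,
    remove_eog_ica,
    rereference_average,
)
from restingnorm.spectral import welch_psd
from restingnorm.synthetic import synthesize_recording, _blink_template
from restingnorm.types import Epochs, Recording, default_montage
from conftest import make_truth


def _noise_recording(montage, rate=250.0, seconds=30, seed=0, scale=30.0):
    rng = np.random.default_rng(seed)
    data = scale * rng.standard_normal((montage.n_channels, int(rate * seconds)))
    return Recording(data=data, rate=rate, montage=montage, subject_id="T")


class TestFlatChannels:
    def test_zero_variance_channel_flagged(self, montage32):
        rec = _noise_recording(montage32)
        rec.data[4] = 0.0
        assert detect_flat_channels(rec) == [montage32.labels[4]]

    def test_homogeneous_channels_clean(self, montage32):
        assert detect_flat_channels(_noise_recording(montage32)) == []

    def test_tiny_sd_channel_flagged(self):
        m = default_montage(100, 0)
        rec = _noise_recording(m, seconds=10)
        rec.data[37] *= 1e-4
        assert detect_flat_channels(rec) == [m.labels[37]]


class TestFilters:
    def test_dc_removed(self, montage32):
        rec = _noise_recording(montage32, seconds=60, scale=1.0)
        rec.data += 500.0
        out = apply_filters(rec)
        trimmed = out.data[:, 2500:-2500]
        assert np.abs(trimmed.mean()) < 5.0  # within 1% of the 500 uV offset

    def test_line_noise_suppressed(self, montage32):
        t = np.arange(int(250 * 30)) / 250.0
        rec = Recording(
            np.tile(np.sin(2 * np.pi * 60 * t) * 100, (32, 1)),
            250.0, montage32,
        )
        out = apply_filters(rec)
        rms_in = np.sqrt((rec.data**2).mean())
        rms_out = np.sqrt((out.data[:, 1000:-1000] ** 2).mean())
        assert rms_out <= 0.1 * rms_in

    def test_passband_untouched(self, montage32):
        t = np.arange(int(250 * 30)) / 250.0
        rec = Recording(
            np.tile(np.sin(2 * np.pi * 10 * t) * 100, (32, 1)), 250.0, montage32
        )
        out = apply_filters(rec)
        amp = np.abs(out.data[:, 1000:-1000]).max()
        assert abs(amp - 100.0) / 100.0 < 0.05

    def test_harmonics_above_nyquist_skipped(self, montage32):
        report_rec = _noise_recording(montage32, rate=250.0)
        from restingnorm.preprocessing import PreprocReport

        rep = PreprocReport()
        apply_filters(report_rec, report=rep)
        assert rep.filter_settings["notch_hz"] == [60.0, 120.0]


class TestBipolarEog:
    def test_identical_channels_zero(self, montage32):
        rec = _noise_recording(montage32)
        rec.data[1] = rec.data[0]
        pair = montage32.labels[:2]
        assert np.allclose(make_bipolar_eog(rec, *pair), 0.0)

    def test_blink_template_isolated(self, montage32):
        rec = _noise_recording(montage32, seed=2)
        template = _blink_template(250.0)
        rec.data[1] = rec.data[0] + np.resize(template, rec.data.shape[1])
        series = make_bipolar_eog(rec, montage32.labels[1], montage32.labels[0])
        assert np.allclose(series, np.resize(template, rec.data.shape[1]))

    def test_arbitrary_pair_is_difference(self, montage32):
        rec = _noise_recording(montage32, seed=3)
        a, c = montage32.labels[7], montage32.labels[20]
        assert np.array_equal(
            make_bipolar_eog(rec, a, c), rec.data[7] - rec.data[20]
        )

    def test_missing_label_raises(self, montage32):
        with pytest.raises(KeyError):
            make_bipolar_eog(_noise_recording(montage32), "nope", "E1")


class TestEpoching:
    @pytest.mark.parametrize(
        "seconds,expected", [(240, 120), (5, 2), (2, 1)]
    )
    def test_epoch_counts(self, montage32, seconds, expected):
        rec = _noise_recording(montage32, seconds=seconds)
        ep = epoch_signal(rec, 2.0)
        assert ep.n_epochs == expected
        if seconds == 2:
            assert np.array_equal(ep.data[0], rec.data)

    def test_trailing_partial_dropped(self, montage32):
        rec = _noise_recording(montage32, seconds=5)
        ep = epoch_signal(rec, 2.0)
        assert np.array_equal(
            ep.data.transpose(1, 0, 2).reshape(32, -1), rec.data[:, :1000]
        )

    def test_series_epoching_matches(self, montage32):
        rec = _noise_recording(montage32, seconds=5)
        ep = epoch_signal(rec, 2.0)
        se = epoch_series(rec.data[3], rec.rate, 2.0)
        assert np.array_equal(se, ep.data[:, 3, :])


class TestAdaptiveRejection:
    def test_homogeneous_noise_mostly_kept(self, montage32):
        ep = epoch_signal(_noise_recording(montage32, seconds=200), 2.0)
        out = reject_epochs_adaptive(ep, k=5.0)
        assert out.quality_ratio <= 0.05

    def test_burst_epoch_rejected(self, montage32):
        rec = _noise_recording(montage32, seconds=40)
        rec.data[:, 5000:5500] *= 10
        out = reject_epochs_adaptive(epoch_signal(rec, 2.0))
        assert not out.kept_mask[10]
        assert out.kept_mask.sum() >= 18

    def test_zero_mad_keeps_all(self, montage32):
        one = np.random.default_rng(0).standard_normal((32, 500))
        data = np.tile(one, (12, 1, 1))
        ep = Epochs(data, 250.0, 2.0, montage32)
        out = reject_epochs_adaptive(ep)
        assert out.kept_mask.all()


class TestAverageReference:
    def test_channel_mean_zero(self, montage32):
        ep = epoch_signal(_noise_recording(montage32), 2.0)
        out = rereference_average(ep)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-10

    def test_idempotent(self, montage32):
        ep = epoch_signal(_noise_recording(montage32), 2.0)
        once = rereference_average(ep)
        twice = rereference_average(once)
        assert np.allclose(once.data, twice.data)

    def test_balanced_pair_unchanged(self):
        m = default_montage(16, 0).subset(["E1", "E2"])
        data = np.stack([np.ones((2, 500)) * np.array([[1.0], [-1.0]])])
        ep = Epochs(data, 250.0, 2.0, m)
        assert np.allclose(rereference_average(ep).data, data)


class TestEogIca:
    def _epochs_with_blinks(self, montage32, blink=True, seed=4):
        rng = np.random.default_rng(seed)
        n_ep, n_ch, n_s = 30, 32, 500
        data = rng.standard_normal((n_ep, n_ch, n_s)) * 20
        template = _blink_template(250.0)
        eog = np.zeros(n_ep * n_s)
        if blink:
            for e in range(0, n_ep, 3):
                start = e * n_s + 100
                eog[start : start + len(template)] += template
            blink_sig = eog.reshape(n_ep, n_s)
            for ch, w in [(0, 1.0), (1, 0.7), (2, 0.4)]:
                data[:, ch, :] += w * blink_sig
        ep = Epochs(data, 250.0, 2.0, montage32)
        return ep, eog

    def test_no_blink_content_passthrough(self, montage32):
        ep, _ = self._epochs_with_blinks(montage32, blink=False)
        rng = np.random.default_rng(99)
        eog = rng.standard_normal(ep.n_epochs * 500) * 1e-3
        out, n = remove_eog_ica(ep, eog, seed=0)
        assert n == 0
        assert np.allclose(out.data, ep.data, atol=1e-6)

    def test_blinks_removed_from_frontal_channels(self, montage32):
        ep, eog = self._epochs_with_blinks(montage32)
        out, n = remove_eog_ica(ep, eog, seed=0)
        assert n >= 1
        front = out.data[:, 0, :].reshape(-1)
        corr = np.corrcoef(front, eog)[0, 1]
        assert abs(corr) < 0.2

    def test_variance_not_increased(self, montage32):
        ep, eog = self._epochs_with_blinks(montage32)
        out, n = remove_eog_ica(ep, eog, seed=0)
        assert n >= 1
        assert out.data.var() <= ep.data.var() + 1e-12


class TestPerEpochInterpolation:
    def test_clean_epochs_identity(self, montage32):
        ep = epoch_signal(_noise_recording(montage32), 2.0)
        out = interpolate_bad_channels_per_epoch(ep)
        assert np.allclose(out.data, ep.data)

    def test_corrupted_channel_restored(self):
        # spatially smooth field: channels see correlated sources
        m = default_montage(32, 0)
        rng = np.random.default_rng(5)
        sources = rng.standard_normal((3, 20, 500))
        mix = np.array(
            [
                [1 + p[0], 1 + p[1], 1 + p[2]]
                for p in m.positions
            ]
        )
        data = np.einsum("cs,set->ect", mix, sources) * 10
        ep = Epochs(np.array(data), 250.0, 2.0, m)
        original = ep.data[3, 10, :].copy()
        ep.data[3, 10, :] = rng.standard_normal(500) * 300
        out = interpolate_bad_channels_per_epoch(ep, m, k=8.0)
        corr = np.corrcoef(out.data[3, 10, :], original)[0, 1]
        assert corr >= 0.8

    def test_epoch_dropped_when_too_many_bad(self, montage32):
        ep = epoch_signal(_noise_recording(montage32), 2.0)
        ep.data[2, :15, :] *= 50  # 15/32 channels bad
        out = interpolate_bad_channels_per_epoch(ep, montage32, k=8.0)
        assert not out.kept_mask[2]


class TestFullChain:
    def test_clean_subject_spectra_preserved(self, montage32):
        truth = make_truth(seed=21)
        rec = synthesize_recording(truth, montage32, duration_s=60, rate=250)
        epochs, report = preprocess(rec, seed=0)
        assert report.quality_ratio <= 0.2
        raw_spec = welch_psd(rereference_average(epoch_signal(rec)))
        clean_spec = welch_psd(epochs)
        delta = np.abs(
            raw_spec.log_power.mean(axis=0) - clean_spec.log_power.mean(axis=0)
        )
        assert delta.max() < 0.05

    def test_chain_deterministic(self, montage32):
        from restingnorm.synthetic import ArtifactSpec

        truth = make_truth(artifacts=ArtifactSpec(1, 10.0, 0.2), seed=22)
        rec = synthesize_recording(truth, montage32, duration_s=60, rate=250)
        e1, r1 = preprocess(rec, seed=3)
        e2, r2 = preprocess(rec, seed=3)
        assert np.array_equal(e1.data, e2.data)
        assert r1.as_dict() == r2.as_dict()

    def test_artifacted_subject_cleaned(self, montage32):
        from restingnorm.synthetic import ArtifactSpec

        truth = make_truth(artifacts=ArtifactSpec(1, 10.0, 0.2), seed=23)
        rec = synthesize_recording(truth, montage32, duration_s=60, rate=250)
        epochs, report = preprocess(rec, seed=0)
        assert len(report.flat_channels) == 1
        assert 0.05 <= report.quality_ratio <= 0.5
        assert report.ica_components_removed >= 1
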