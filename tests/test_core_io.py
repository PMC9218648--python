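"""Recording I/O, montage, filtering, segment selection and epoching."""

import numpy as np
import pandas as pd
import pytest

from seegflow import core_io
from seegflow._edf import write_edf
from conftest import make_recording


def _write_fixture(tmp_path, sig, labels, fs=500, table_rows=None):
    edf = tmp_path / "rec.edf"
    tsv = tmp_path / "rec.tsv"
    write_edf(edf, sig, labels, fs)
    rows = table_rows if table_rows is not None else labels
    pd.DataFrame(
        {
            "label": rows,
            "x": np.arange(len(rows), dtype=float),
            "y": 0.0,
            "z": 0.0,
            "white_matter": 0,
            "soz": [1] + [0] * (len(rows) - 1),
            "region": "",
        }
    ).to_csv(tsv, sep="\t", index=False)
    return edf, tsv


class TestReadRecording:
    def test_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        sig = 80 * rng.standard_normal((4, 2500))
        edf, tsv = _write_fixture(tmp_path, sig, ["A1", "A2", "B1", "B2"])
        rec = core_io.read_recording(edf, tsv)
        assert rec.montage == "referential"
        assert rec.labels == ["A1", "A2", "B1", "B2"]
        assert rec.fs == 500.0
        assert rec.channels[0].soz and not rec.channels[1].soz
        # 16-bit quantization bounds the round-trip error
        assert np.max(np.abs(rec.signal - sig)) < 0.01

    def test_untabled_channel_dropped_with_warning(self, tmp_path, caplog):
        sig = np.random.default_rng(1).standard_normal((3, 1000))
        edf, tsv = _write_fixture(tmp_path, sig, ["A1", "A2", "XX"], table_rows=["A1", "A2"])
        # table only lists A1, A2 -> XX dropped
        import logging

        with caplog.at_level(logging.WARNING, logger="seegflow.core_io"):
            rec = core_io.read_recording(edf, tsv)
        assert rec.labels == ["A1", "A2"]
        assert any("XX" in r.message for r in caplog.records)

    def test_fs_mismatch_fatal(self, tmp_path):
        sig = np.random.default_rng(2).standard_normal((2, 1000))
        edf, tsv = _write_fixture(tmp_path, sig, ["A1", "A2"], fs=500)
        with pytest.raises(ValueError, match="mismatch"):
            core_io.read_recording(edf, tsv, expected_fs=1000.0)

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            core_io.read_recording(tmp_path / "nope.edf", tmp_path / "nope.tsv")


class TestBipolarMontage:
    def test_identical_contacts_cancel(self):
        s = np.sin(np.linspace(0, 10, 1000))
        rec = make_recording(np.stack([s, s]), labels=["A1", "A2"])
        out = core_io.apply_bipolar_montage(rec, [("A1", "A2")])
        assert np.allclose(out.signal, 0.0)
        assert out.montage == "bipolar"

    def test_zero_cathode_passthrough_and_midpoint(self):
        s = np.sin(np.linspace(0, 10, 1000))
        rec = make_recording(
            np.stack([s, np.zeros_like(s)]),
            labels=["A1", "A2"],
            positions=[(0, 0, 0), (0, 0, 3.5)],
        )
        out = core_io.apply_bipolar_montage(rec, [("A1", "A2")])
        assert np.allclose(out.signal[0], s)
        assert out.channels[0].position == (0.0, 0.0, 1.75)

    def test_label_flags(self):
        rec = make_recording(np.zeros((2, 100)), labels=["A1", "A2"], soz=[True, False])
        out = core_io.apply_bipolar_montage(rec, [("A1", "A2")])
        assert out.channels[0].soz  # OR of contact SOZ flags
        assert not out.channels[0].white_matter  # AND of contact WM flags

    def test_unknown_label_fatal(self):
        rec = make_recording(np.zeros((2, 100)), labels=["A1", "A2"])
        with pytest.raises(KeyError):
            core_io.apply_bipolar_montage(rec, [("A1", "ZZ")])

    def test_linearity(self):
        rng = np.random.default_rng(5)
        sig = rng.standard_normal((2, 500))
        rec1 = make_recording(sig, labels=["A1", "A2"])
        rec2 = make_recording(3.5 * sig, labels=["A1", "A2"])
        out1 = core_io.apply_bipolar_montage(rec1, [("A1", "A2")])
        out2 = core_io.apply_bipolar_montage(rec2, [("A1", "A2")])
        assert np.allclose(out2.signal, 3.5 * out1.signal)


class TestNotchFilter:
    def test_line_frequency_attenuated(self):
        fs, t = 500.0, np.arange(0, 20, 1 / 500.0)
        rec = make_recording(np.sin(2 * np.pi * 60 * t)[None, :], fs=fs)
        out = core_io.notch_filter(rec)
        ratio = np.sqrt(np.mean(out.signal**2) / np.mean(rec.signal**2))
        assert ratio < 0.04  # >= 30 dB amplitude attenuation

    def test_passband_preserved(self):
        fs, t = 500.0, np.arange(0, 20, 1 / 500.0)
        rec = make_recording(np.sin(2 * np.pi * 10 * t)[None, :], fs=fs)
        out = core_io.notch_filter(rec)
        ratio = np.sqrt(np.mean(out.signal**2) / np.mean(rec.signal**2))
        assert abs(ratio - 1) < 0.06

    def test_dc_unchanged(self):
        rec = make_recording(np.full((1, 5000), 7.0))
        out = core_io.notch_filter(rec)
        mid = slice(1000, 4000)  # ignore filter transients
        assert np.allclose(out.signal[0, mid], 7.0, atol=1e-6)

    def test_idempotent_on_broadband_noise(self):
        rng = np.random.default_rng(7)
        rec = make_recording(rng.standard_normal((2, 20000)))
        once = core_io.notch_filter(rec)
        twice = core_io.notch_filter(once)
        r1 = np.sqrt(np.mean(once.signal**2))
        r2 = np.sqrt(np.mean(twice.signal**2))
        assert abs(r2 - r1) / r1 < 0.01

    def test_above_nyquist_fatal(self):
        rec = make_recording(np.zeros((1, 1000)), fs=100.0)
        with pytest.raises(ValueError):
            core_io.notch_filter(rec, line_freq=60.0)


class TestSegmentSelection:
    def test_clean_recording_trimmed_to_total(self):
        rng = np.random.default_rng(11)
        rec = make_recording(rng.standard_normal((2, int(900 * 500))))
        out = core_io.select_interictal_segments(rec, total_length=600.0)
        assert out.duration == pytest.approx(600.0)

    def test_artifact_burst_excluded(self):
        rng = np.random.default_rng(12)
        fs = 500.0
        sig = rng.standard_normal((1, int(900 * fs)))
        burst = slice(int(400 * fs), int(410 * fs))
        sig[0, burst] *= 20.0
        rec = make_recording(sig, fs=fs)
        out = core_io.select_interictal_segments(
            rec, segment_length=60.0, total_length=600.0, artifact_z=6.0
        )
        # oracle: the samples marked |z| > 6 must not appear in the output
        med = np.median(sig)
        mad = 1.4826 * np.median(np.abs(sig - med))
        bad_vals = sig[0, burst][np.abs(sig[0, burst] - med) / mad > 6.0]
        assert not np.isin(np.round(out.signal[0], 12), np.round(bad_vals, 12)).any()

    def test_insufficient_data_fatal(self):
        rec = make_recording(np.random.default_rng(1).standard_normal((1, int(300 * 500))))
        with pytest.raises(ValueError, match="clean seconds|shorter"):
            core_io.select_interictal_segments(rec, total_length=600.0)


class TestEpoch:
    def test_counts(self):
        rec = make_recording(np.random.default_rng(0).standard_normal((2, 600 * 500)))
        ep = core_io.epoch(rec)
        assert ep.n_epochs == 600 and ep.data.shape == (600, 2, 500)

    def test_trailing_remainder_discarded(self):
        rec = make_recording(np.zeros((1, int(10.7 * 500))))
        assert core_io.epoch(rec).n_epochs == 10

    def test_partition_property(self):
        rec = make_recording(np.random.default_rng(3).standard_normal((2, 2750)))
        ep = core_io.epoch(rec)
        rebuilt = ep.data.transpose(1, 0, 2).reshape(2, -1)
        assert np.array_equal(rebuilt, rec.signal[:, : ep.n_epochs * 500])


def test_resample_preserves_sine():
    fs, t = 1000.0, np.arange(0, 10, 1 / 1000.0)
    rec = make_recording(np.sin(2 * np.pi * 10 * t)[None, :], fs=fs)
    out = core_io.resample_recording(rec, 500.0)
    assert out.fs == 500.0 and out.n_samples == 5000
    t2 = np.arange(out.n_samples) / 500.0
    mid = slice(500, 4500)
    assert np.max(np.abs(out.signal[0, mid] - np.sin(2 * np.pi * 10 * t2)[mid])) < 0.01


def test_manifest_roundtrip_and_consistency(tmp_path):
    m = core_io.CohortManifest(
        [core_io.PatientEntry("P01", ["P01.edf"], "P01.tsv", "I", 500.0)]
    )
    m.save(tmp_path / "m.json")
    loaded = core_io.CohortManifest.load(tmp_path / "m.json")
    assert loaded.patients[0].seizure_free
    bad = (tmp_path / "m.json").read_text().replace('"seizure_free": true', '"seizure_free": false')
    (tmp_path / "bad.json").write_text(bad)
    with pytest.raises(ValueError, match="seizure_free"):
        core_io.CohortManifest.load(tmp_path / "bad.json")
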