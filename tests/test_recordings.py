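"""Session containers, grid layouts, block extraction, and rest sampling."""

import json

import numpy as np
import pytest
import scipy.stats

import sozloc as sz
from sozloc.recordings import admissible_rest_intervals, sample_rest_starts


class TestGridLayout:
    def test_digit_letter_labelling(self):
        grid = sz.GridLayout(6, 8)
        assert grid.label_of(0, 0) == "1A"
        assert grid.label_of(5, 7) == "6H"
        assert grid.position_of("5A") == (4, 0)

    def test_label_bijection(self):
        grid = sz.GridLayout(4, 6)
        seen = {grid.label_of(r, c) for r in range(4) for c in range(6)}
        assert len(seen) == 24
        for lab in seen:
            r, c = grid.position_of(lab)
            assert grid.label_of(r, c) == lab

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sz.GridLayout(1, 2, labels=("A", "A"))


class TestSessionValidation:
    def test_channel_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="grid"):
            sz.RecordingSession(
                signal=rng.normal(size=(100, 5)),
                fs=100.0,
                channel_labels=[f"1{c}" for c in "ABCDE"],
                grid=sz.GridLayout(2, 3),
            )

    def test_out_of_range_interval_rejected(self, rng):
        with pytest.raises(ValueError, match="seizure"):
            sz.RecordingSession(
                signal=rng.normal(size=(100, 4)),
                fs=10.0,
                channel_labels=list(sz.GridLayout(2, 2).labels),
                grid=sz.GridLayout(2, 2),
                seizure_intervals=[(5.0, 20.0)],
            )


class TestContainerRoundTrip:
    def test_npy_round_trip(self, small_session, tmp_path):
        path = sz.save_session(small_session, tmp_path / "ses")
        loaded = sz.load_session(path)
        assert np.array_equal(loaded.signal, small_session.signal)
        assert loaded.fs == small_session.fs
        assert loaded.seizure_intervals == small_session.seizure_intervals
        assert loaded.eoi == small_session.eoi
        assert loaded.grid.labels == small_session.grid.labels

    def test_missing_annotations_rejected(self, small_session, tmp_path):
        path = sz.save_session(small_session, tmp_path / "ses")
        path.with_suffix(".json").unlink()
        with pytest.raises(FileNotFoundError, match="annotation"):
            sz.load_session(path)

    def test_annotated_channel_absent_from_file_rejected(self, tmp_path, rng):
        """An annotation naming a channel the file lacks is an error."""
        pytest.importorskip("mne")
        grid = sz.GridLayout(2, 2)
        session = sz.RecordingSession(
            signal=rng.normal(scale=20.0, size=(256 * 4, 4)),
            fs=256.0,
            channel_labels=list(grid.labels),
            grid=grid,
        )
        edf = tmp_path / "ses.edf"
        sz.write_edf(session, edf)
        meta = session.annotations_dict()
        meta["channel_labels"][0] = "9Z"
        meta["grid"]["labels"][0] = "9Z"
        edf.with_suffix(".json").write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="absent"):
            sz.load_session(edf)

    def test_edf_round_trip(self, tmp_path, rng):
        """Write a 64-channel 512 Hz EDF and read it back through mne."""
        pytest.importorskip("mne")
        grid = sz.GridLayout(8, 8)
        session = sz.RecordingSession(
            signal=rng.normal(scale=50.0, size=(512 * 4, 64)),
            fs=512.0,
            channel_labels=list(grid.labels),
            grid=grid,
            seizure_intervals=[(1.0, 2.0)],
        )
        edf = tmp_path / "ses.edf"
        sz.write_edf(session, edf)
        edf.with_suffix(".json").write_text(json.dumps(session.annotations_dict()))
        loaded = sz.load_session(edf)
        assert loaded.n_channels == 64
        assert loaded.fs == 512.0
        # 16-bit quantization: relative error bounded by the amplitude span
        err = np.abs(loaded.signal - session.signal).max()
        span = session.signal.max() - session.signal.min()
        assert err < span / 2**15


class TestIctalBlocks:
    def test_one_block_per_seizure_at_annotated_starts(self, rng):
        grid = sz.GridLayout(2, 2)
        session = sz.RecordingSession(
            signal=rng.normal(size=(500 * 200, 4)),
            fs=500.0,
            channel_labels=list(grid.labels),
            grid=grid,
            seizure_intervals=[(20.0, 50.0), (100.0, 130.0), (170.0, 185.0)],
        )
        blocks = sz.extract_ictal_blocks(session)
        assert [b.start_time for b in blocks] == [20.0, 100.0, 170.0]
        assert all(b.label == "ictal" for b in blocks)
        assert all(b.n_samples == 5000 for b in blocks)

    def test_sample_index_arithmetic(self, rng):
        """Seizure at t = 100 s at 500 Hz maps to rows 50000..54999."""
        grid = sz.GridLayout(1, 2)
        sig = np.arange(500 * 120 * 2, dtype=float).reshape(-1, 2)
        session = sz.RecordingSession(
            signal=sig, fs=500.0, channel_labels=list(grid.labels), grid=grid,
            seizure_intervals=[(100.0, 115.0)],
        )
        (block,) = sz.extract_ictal_blocks(session)
        assert np.array_equal(block.data, sig[50_000:55_000])

    def test_seizure_near_recording_end_skipped(self, rng):
        grid = sz.GridLayout(1, 2)
        session = sz.RecordingSession(
            signal=rng.normal(size=(1000, 2)), fs=50.0,
            channel_labels=list(grid.labels), grid=grid,
            seizure_intervals=[(15.0, 20.0)],
        )
        with pytest.warns(UserWarning, match="skipped"):
            assert sz.extract_ictal_blocks(session) == []

    def test_short_seizure_still_yields_full_block(self, rng):
        grid = sz.GridLayout(1, 2)
        session = sz.RecordingSession(
            signal=rng.normal(size=(5000, 2)), fs=50.0,
            channel_labels=list(grid.labels), grid=grid,
            seizure_intervals=[(10.0, 14.0)],
        )
        with pytest.warns(UserWarning, match="extends past"):
            (block,) = sz.extract_ictal_blocks(session)
        assert block.n_samples == 500


class TestRestSampling:
    def _session(self, rng, duration=400.0, seizures=((100.0, 160.0),)):
        grid = sz.GridLayout(1, 2)
        return sz.RecordingSession(
            signal=rng.normal(size=(int(50 * duration), 2)), fs=50.0,
            channel_labels=list(grid.labels), grid=grid,
            seizure_intervals=list(seizures),
        )

    def test_guard_band_interval_arithmetic(self, rng):
        """Guard 60 s around a (100, 160) seizure forbids starts in (30, 220)."""
        session = self._session(rng)
        starts = sample_rest_starts(session, 1000, 10.0, rng, guard=60.0)
        assert not np.any((starts > 30.0) & (starts < 220.0))
        assert np.all((starts >= 0) & (starts <= 390.0))

    def test_blocks_avoid_seizures_and_exclusions(self, rng):
        session = self._session(rng)
        session.exclusion_intervals = [(300.0, 320.0)]
        blocks = sz.sample_rest_blocks(session, 500, 10.0, rng, guard=30.0)
        for b in blocks:
            s, e = b.start_time, b.start_time + 10.0
            for fs_, fe in [(100.0 - 30.0, 160.0 + 30.0), (300.0, 320.0)]:
                assert e <= fs_ or s >= fe
            assert b.label == "rest"
            assert b.n_samples == 500

    def test_deterministic_under_fixed_seed(self, rng):
        session = self._session(rng)
        s1 = sample_rest_starts(session, 50, 10.0, np.random.default_rng(42), guard=60.0)
        s2 = sample_rest_starts(session, 50, 10.0, np.random.default_rng(42), guard=60.0)
        assert np.array_equal(s1, s2)

    def test_insufficient_region_reports_deficit(self, rng):
        session = self._session(rng, duration=100.0, seizures=((10.0, 90.0),))
        with pytest.raises(ValueError, match="admissible rest region"):
            sz.sample_rest_blocks(session, 5, 10.0, rng, guard=30.0)

    def test_start_times_uniform_over_admissible_region(self, rng):
        """Chi-square goodness of fit over equal-measure bins, 10000 draws."""
        session = self._session(rng)
        guard = 60.0
        allowed = admissible_rest_intervals(session, 10.0, guard)
        lengths = np.array([b - a for a, b in allowed])
        edges = np.concatenate([[0.0], np.cumsum(lengths)])
        starts = sample_rest_starts(session, 10_000, 10.0, rng, guard=guard)
        # map each start to its coordinate along the concatenated region
        coord = np.empty_like(starts)
        for i, (a, b) in enumerate(allowed):
            inside = (starts >= a) & (starts <= b)
            coord[inside] = edges[i] + starts[inside] - a
        counts, _ = np.histogram(coord, bins=20, range=(0.0, edges[-1]))
        stat, p = scipy.stats.chisquare(counts)
        assert p > 0.01
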