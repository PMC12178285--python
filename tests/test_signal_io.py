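"""Container and CSV side-table round trips and validation."""

import numpy as np
import pandas as pd
import pytest

from neocoupling.errors import (
    CorruptionError,
    FormatError,
    ParameterError,
    ValidationError,
)
from neocoupling.signal_io import (
    ChannelMeta,
    Recording,
    read_csv_table,
    read_recording,
    write_recording,
)

from conftest import make_recording


class TestRecordingContainer:
    def test_round_trip_is_bit_identical(self, rng, tmp_path):
        samples = rng.standard_normal((16, 2000)).astype(np.float32).astype(np.float64)
        rec = make_recording(samples)
        write_recording(rec, tmp_path / "rec.bin")
        back = read_recording(tmp_path / "rec.bin")
        assert np.array_equal(back.samples, samples)
        assert back.fs == rec.fs and back.t0 == rec.t0

    def test_round_trip_preserves_channel_metadata(self, rng, tmp_path):
        rec = make_recording(rng.standard_normal((3, 100)).astype(np.float32))
        write_recording(rec, tmp_path / "rec.bin")
        back = read_recording(tmp_path / "rec.bin")
        assert back.channels == rec.channels

    def test_duration_from_declared_sizes(self, rng, tmp_path):
        rec = make_recording(rng.standard_normal((2, 1000)).astype(np.float32), fs=1000.0)
        write_recording(rec, tmp_path / "r.bin")
        assert read_recording(tmp_path / "r.bin").duration == pytest.approx(1.0)

    def test_file_size_arithmetic(self, rng, tmp_path):
        n = 321
        rec = make_recording(rng.standard_normal((16, n)).astype(np.float32))
        write_recording(rec, tmp_path / "r.bin")
        assert (tmp_path / "r.bin").stat().st_size == 4 * 16 * n

    def test_zero_length_recording(self, tmp_path):
        rec = make_recording(np.empty((2, 0)))
        write_recording(rec, tmp_path / "empty.bin")
        back = read_recording(tmp_path / "empty.bin")
        assert back.n_samples == 0 and back.n_channels == 2

    def test_missing_sidecar_is_format_error(self, rng, tmp_path):
        rec = make_recording(rng.standard_normal((2, 10)).astype(np.float32))
        write_recording(rec, tmp_path / "r.bin")
        (tmp_path / "r.json").unlink()
        with pytest.raises(FormatError):
            read_recording(tmp_path / "r.bin")

    def test_channel_count_mismatch_is_corruption_error(self, rng, tmp_path):
        rec = make_recording(rng.standard_normal((2, 11)).astype(np.float32))
        write_recording(rec, tmp_path / "r.bin")
        sidecar = (tmp_path / "r.json").read_text()
        (tmp_path / "r.json").write_text(
            sidecar.replace('"index": 1', '"index": 1}, {"area": "OB", "depth_um": 600.0, "index": 2')
        )
        with pytest.raises(CorruptionError):
            read_recording(tmp_path / "r.bin")

    def test_nan_samples_rejected(self):
        bad = np.zeros((1, 10))
        bad[0, 3] = np.nan
        with pytest.raises(ValidationError):
            make_recording(bad)

    def test_depth_must_increase_with_index(self):
        channels = [
            ChannelMeta("OB", 500.0, 0),
            ChannelMeta("OB", 450.0, 1),  # shallower than its predecessor
        ]
        with pytest.raises(ValidationError):
            Recording(samples=np.zeros((2, 10)), fs=1000.0, channels=channels)


class TestCsvTables:
    def _write(self, tmp_path, name, df):
        p = tmp_path / name
        df.to_csv(p, index=False)
        return p

    def test_empty_csv_with_header_is_valid(self, tmp_path):
        p = self._write(
            tmp_path, "e.csv", pd.DataFrame(columns=["kind", "t", "label"])
        )
        assert len(read_csv_table(p, "event").df) == 0

    def test_unknown_columns_rejected(self, tmp_path):
        p = self._write(tmp_path, "e.csv", pd.DataFrame({"when": [1.0], "what": ["x"]}))
        with pytest.raises(FormatError):
            read_csv_table(p, "event")

    def test_track_likelihood_range_names_row(self, tmp_path):
        p = self._write(
            tmp_path,
            "t.csv",
            pd.DataFrame(
                {"frame": [0, 1, 2], "x_cm": [1.0, 2.0, 3.0], "y_cm": [0.0] * 3,
                 "likelihood": [0.9, 1.2, 0.8]}
            ),
        )
        with pytest.raises(ValidationError, match="row 1"):
            read_csv_table(p, "track", fps=30.0)

    def test_track_requires_fps(self, tmp_path):
        p = self._write(
            tmp_path,
            "t.csv",
            pd.DataFrame({"frame": [0], "x_cm": [1.0], "y_cm": [0.0], "likelihood": [1.0]}),
        )
        with pytest.raises(ParameterError):
            read_csv_table(p, "track")

    def test_call_off_before_on_rejected(self, tmp_path):
        p = self._write(
            tmp_path,
            "c.csv",
            pd.DataFrame({"t_on": [1.0], "t_off": [0.5], "peak_freq_khz": [60.0]}),
        )
        with pytest.raises(ValidationError):
            read_csv_table(p, "call")

    def test_unsorted_event_times_name_first_offender(self, tmp_path):
        p = self._write(
            tmp_path,
            "e.csv",
            pd.DataFrame(
                {"kind": ["odor_on", "odor_off"], "t": [5.0, 3.0], "label": ["a", "a"]}
            ),
        )
        with pytest.raises(ValidationError, match="row 1"):
            read_csv_table(p, "event")

    def test_odor_events_must_alternate(self, tmp_path):
        p = self._write(
            tmp_path,
            "e.csv",
            pd.DataFrame(
                {"kind": ["odor_on", "odor_on"], "t": [1.0, 2.0], "label": ["a", "a"]}
            ),
        )
        with pytest.raises(ValidationError):
            read_csv_table(p, "event")

    def test_spike_table_validates_against_recording(self, rng, tmp_path):
        rec = make_recording(rng.standard_normal((2, 1000)).astype(np.float32))
        p = self._write(
            tmp_path, "s.csv",
            pd.DataFrame({"unit_id": [0], "channel": [5], "t": [0.5]}),
        )
        table = read_csv_table(p, "spike")
        with pytest.raises(ValidationError):
            table.validate_against(rec)
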