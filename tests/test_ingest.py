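import numpy as np
import pytest

from anesgc import (Recording, RegionSignals, average_regions,
                    detect_bad_channels, extract_state_segments, notch_50hz,
                    read_recording)
from anesgc.ingest import ANESTH, AWAKE
from anesgc.montage import CHANNELS_1020


def toy_recording(n=4096, fs=256.0, seed=0, markers=None):
    rng = np.random.default_rng(seed)
    sig = rng.normal(size=(19, n))
    return Recording(signal=sig, labels=CHANNELS_1020, fs=fs,
                     markers=markers or {})


class TestReading:
    def test_case_insensitive_labels(self, tmp_path, short_recording):
        from anesgc import write_matrix

        path = tmp_path / "rec.tsv"
        write_matrix(short_recording, path)
        text = path.read_text()
        path.write_text(text.replace("Fp1", "FP1", 1))
        rec = read_recording(path)
        assert rec.labels[0] == "Fp1"

    def test_unknown_label_listed_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("Fp1\tNOPE\n0.0\t0.0\n")
        with pytest.raises(ValueError, match="NOPE"):
            read_recording(path)

    def test_missing_channel_is_absent_not_error(self, tmp_path, short_recording):
        import pandas as pd

        from anesgc import write_matrix

        path = tmp_path / "rec.tsv"
        sidecar = write_matrix(short_recording, path)
        df = pd.read_csv(path, sep="\t")
        df.drop(columns=["O1"]).to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        (tmp_path / "m.tsv.json").write_text(sidecar.read_text())
        rec = read_recording(tmp_path / "m.tsv")
        assert "O1" not in rec.labels and len(rec.labels) == 18
        rs = average_regions(rec)
        assert rs.membership["LP"] == ["T5", "P3"]

    def test_missing_fs_errors(self, tmp_path):
        path = tmp_path / "nofs.tsv"
        path.write_text("Fp1\tFp2\n0.0\t0.0\n1.0\t1.0\n")
        with pytest.raises(ValueError, match="sampling rate"):
            read_recording(path)


class TestBadChannels:
    def test_flat_channel_detected(self):
        rec = toy_recording()
        rec.signal[CHANNELS_1020.index("T5")] = 3.7
        assert detect_bad_channels(rec) == ["T5"]
        assert rec.excluded_channels == ["T5"]

    def test_clipped_channel_detected(self):
        rec = toy_recording()
        i = CHANNELS_1020.index("O2")
        rec.signal[i] = np.clip(rec.signal[i] * 100, -1.0, 1.0)
        assert "O2" in detect_bad_channels(rec)

    def test_clean_recording_empty(self):
        assert detect_bad_channels(toy_recording()) == []

    def test_all_constant_all_listed(self):
        rec = toy_recording()
        rec.signal[:] = 0.0
        assert detect_bad_channels(rec) == list(CHANNELS_1020)

    def test_generator_truth_recovered(self):
        from anesgc import SimConfig, generate_recording

        rec = generate_recording(
            SimConfig(durations=(10.0, 20.0, 10.0), bad_channels=("T5",)))
        r = Recording(signal=rec.signal, labels=rec.labels, fs=rec.fs)
        assert detect_bad_channels(r) == ["T5"]


class TestRegionAveraging:
    def test_arithmetic_mean(self):
        rec = toy_recording(n=16)
        lf = ["Fp1", "F7", "F3", "T3", "C3"]
        for v, lbl in zip((1.0, 2.0, 3.0, 4.0, 5.0), lf):
            rec.signal[CHANNELS_1020.index(lbl), 0] = v
        rs = average_regions(rec)
        assert rs.data["LF"][0] == pytest.approx(3.0)
        assert rs.membership["LF"] == lf

    def test_excluded_electrode_dropped_from_mean(self):
        rec = toy_recording(n=16)
        rec.excluded_channels = ["O1"]
        rs = average_regions(rec)
        assert rs.membership["LP"] == ["T5", "P3"]
        expect = rec.signal[[CHANNELS_1020.index("T5"),
                             CHANNELS_1020.index("P3")]].mean(axis=0)
        assert np.allclose(rs.data["LP"], expect)

    def test_fully_excluded_region_absent(self):
        rec = toy_recording(n=16)
        rec.excluded_channels = ["T5", "P3", "O1"]
        rs = average_regions(rec)
        assert "LP" not in rs.data
        assert rs.regions == ("LF", "RF", "RP", "Z")

    def test_commutes_with_scaling(self):
        rec = toy_recording(n=64, seed=4)
        rs1 = average_regions(rec)
        rec2 = Recording(signal=2.5 * rec.signal, labels=rec.labels, fs=rec.fs)
        rs2 = average_regions(rec2)
        for r in rs1.regions:
            assert np.allclose(2.5 * rs1.data[r], rs2.data[r])


class TestNotch:
    def region_signals(self, x, fs=256.0):
        return RegionSignals(data={"LF": x.copy()}, membership={"LF": ["F3"]},
                             fs=fs)

    def test_50hz_tone_suppressed(self):
        fs = 256.0
        t = np.arange(int(8 * fs)) / fs
        x = np.sin(2 * np.pi * 50.0 * t)
        out = notch_50hz(self.region_signals(x))
        settled = out.data["LF"][int(2 * fs):]
        assert np.sqrt(np.mean(settled ** 2)) < 0.05 * np.sqrt(np.mean(x ** 2))
        assert out.filtered

    def test_dc_preserved(self):
        x = np.full(2048, 3.0)
        out = notch_50hz(self.region_signals(x))
        # causal IIR: allow the start-up transient to settle
        assert np.allclose(out.data["LF"][1024:], 3.0, atol=1e-4)

    def test_broadband_power_kept_outside_notch(self):
        from scipy.signal import welch

        rng = np.random.default_rng(0)
        x = rng.normal(size=int(64 * 256))
        out = notch_50hz(self.region_signals(x))
        f, p_in = welch(x, fs=256.0, nperseg=4096)
        _, p_out = welch(out.data["LF"], fs=256.0, nperseg=4096)
        keep = (f < 45) | (f > 55)
        assert p_out[keep].sum() / p_in[keep].sum() >= 0.95

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            notch_50hz(self.region_signals(np.zeros(2048), fs=90.0))


class TestWindowExtraction:
    def region_signals(self, n, fs=256.0, loc=None, roc=None, seed=0):
        rng = np.random.default_rng(seed)
        data = {r: rng.normal(size=n) for r in ("LF", "RF", "LP", "RP", "Z")}
        markers = {"LOC": loc if loc is not None else n // 3,
                   "ROC": roc if roc is not None else 2 * n // 3}
        return RegionSignals(data=data, membership={}, fs=fs, markers=markers)

    def test_window_count_10s_segment(self):
        # 10-s awake span before LOC -> floor((10-4)/1)+1 = 7 windows
        fs = 256
        rs = self.region_signals(n=fs * 700, loc=fs * 10, roc=fs * 650)
        ws = extract_state_segments(rs, post_induction_skip=300.0,
                                    n_anesth_windows=10)
        t = ws.table
        assert len(t[(t.condition == "LOC") & (t.state == AWAKE)]) == 7

    def test_post_induction_skip(self):
        fs = 256
        rs = self.region_signals(n=fs * 1300, loc=fs * 600, roc=fs * 1250)
        ws = extract_state_segments(rs, post_induction_skip=300.0,
                                    n_anesth_windows=50)
        anesth_loc = ws.table[(ws.table.condition == "LOC")
                              & (ws.table.state == ANESTH)]
        assert anesth_loc["start_s"].min() >= 900.0

    def test_anesth_cap_earliest_and_latest(self):
        fs = 256
        rs = self.region_signals(n=fs * 1000, loc=fs * 100, roc=fs * 900)
        ws = extract_state_segments(rs, post_induction_skip=300.0,
                                    n_anesth_windows=30)
        t = ws.table
        loc_an = t[(t.condition == "LOC") & (t.state == ANESTH)]
        roc_an = t[(t.condition == "ROC") & (t.state == ANESTH)]
        assert len(loc_an) == 30 and len(roc_an) == 30
        assert loc_an["start_s"].min() == 400.0         # earliest eligible
        assert roc_an["start_s"].max() == 896.0         # latest fitting window

    def test_no_window_straddles_markers(self):
        fs = 256
        rs = self.region_signals(n=fs * 1000, loc=fs * 100, roc=fs * 900)
        ws = extract_state_segments(rs, n_anesth_windows=30)
        loc, roc = rs.markers["LOC"], rs.markers["ROC"]
        for _, row in ws.table.iterrows():
            s, e = row["start"], row["start"] + ws.win_samples
            assert not (s < loc < e) and not (s < roc < e)

    def test_short_segment_yields_empty_class(self):
        fs = 256
        rs = self.region_signals(n=fs * 1000, loc=fs * 2, roc=fs * 950)
        ws = extract_state_segments(rs, n_anesth_windows=10)
        t = ws.table
        assert len(t[(t.condition == "LOC") & (t.state == AWAKE)]) == 0

    def test_missing_markers_rejected(self):
        rs = self.region_signals(n=256 * 100)
        del rs.markers["ROC"]
        with pytest.raises(ValueError, match="LOC and ROC"):
            extract_state_segments(rs)

    def test_artifact_windows_flagged_by_overlap(self):
        fs = 256
        rs = self.region_signals(n=fs * 1000, loc=fs * 100, roc=fs * 900,
                                 seed=1)
        burst = (fs * 20, fs * 20 + fs // 4)         # 0.25 s in awake span
        for r in rs.data:
            rs.data[r][burst[0]:burst[1]] += 50.0
        ws = extract_state_segments(rs, n_anesth_windows=10)
        t = ws.table
        overlap = (t["start"] < burst[1]) & (t["start"] + ws.win_samples > burst[0])
        assert (~t.loc[overlap, "artifact_free"].astype(bool)).all()
        clean = t[~overlap & (t.condition == "LOC") & (t.state == AWAKE)]
        assert clean["artifact_free"].astype(bool).all()

    def test_attrition_sums_to_total(self, short_ingested):
        rs = average_regions(short_ingested)
        ws = extract_state_segments(rs, n_anesth_windows=40)
        from anesgc import run_diagnostics
        run_diagnostics(ws, order=6, seed=0)
        att = ws.attrition()
        gates = [v for k, v in att.items() if k.startswith("failed_")]
        assert att["admitted"] + sum(gates) == att["total"]
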