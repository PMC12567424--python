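"""Preprocessing protocol: segmentation, DC removal, normalisation,
SNR-exact mixing, splitting, and dataset round-trips."""

import numpy as np
import pytest

from fmha_ae.data_prep import (
    NOISE_LEVELS_DB,
    SegmentPair,
    load_pairs_csv,
    load_pairs_npz,
    make_pair,
    mix_at_snr,
    normalize,
    preprocess_segment,
    remove_dc,
    save_pairs_csv,
    save_pairs_npz,
    segment_signal,
    split_dataset,
)
from fmha_ae.metrics import snr_in_ratio
from fmha_ae.wfdb_io import read_wfdb_record


class TestSegmentation:
    @pytest.mark.parametrize(
        "length,expected",
        [(2048, 2), (2047, 1), (1024, 1), (1_048_576, 1024)],
    )
    def test_segment_counts(self, length, expected):
        segs = segment_signal(np.arange(length, dtype=float))
        assert len(segs) == expected
        assert all(s.size == 1024 for s in segs)

    def test_short_signal_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter than one segment"):
            assert segment_signal(np.zeros(100)) == []

    def test_segments_are_consecutive_non_overlapping(self):
        segs = segment_signal(np.arange(3000, dtype=float), segment_length=1000)
        np.testing.assert_array_equal(segs[1], np.arange(1000, 2000))
        np.testing.assert_array_equal(segs[2], np.arange(2000, 3000))


class TestDCAndNormalization:
    def test_constant_segment_becomes_zero(self):
        np.testing.assert_array_equal(remove_dc(np.full(10, 3.3)), np.zeros(10))

    def test_zero_mean_unchanged_and_random_mean_small(self, rng):
        x = rng.normal(size=100)
        x -= x.mean()
        np.testing.assert_allclose(remove_dc(x), x, atol=1e-15)
        assert abs(remove_dc(rng.normal(size=1000) + 5).mean()) < 1e-12

    def test_normalize_symmetric(self):
        np.testing.assert_array_equal(normalize([-2.0, 2.0]), [-1.0, 1.0])

    def test_pipeline_dc_then_normalize(self):
        out = preprocess_segment([0.0, 4.0])
        np.testing.assert_allclose(out, [-1.0, 1.0])

    def test_output_always_in_bounds(self, rng):
        for _ in range(20):
            out = preprocess_segment(rng.normal(size=64) * rng.uniform(0.1, 50))
            assert np.max(np.abs(out)) == pytest.approx(1.0)
            assert abs(out.mean()) < 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize(np.zeros(8))

    def test_preprocessing_idempotent_on_own_output(self, rng):
        once = preprocess_segment(rng.normal(size=256) * 7 + 2)
        np.testing.assert_allclose(preprocess_segment(once), once, atol=1e-12)


class TestMixing:
    def test_zero_db_equalises_energies(self, rng):
        clean = rng.normal(size=256)
        noise = rng.normal(size=256) * 3.7
        noisy = mix_at_snr(clean, noise, 0.0)
        added = noisy - clean
        assert np.sum(added**2) == pytest.approx(np.sum(clean**2), rel=1e-12)

    def test_minus6_db_noise_power(self, rng):
        clean = rng.normal(size=256)
        noisy = mix_at_snr(clean, rng.normal(size=256), -6.0)
        ratio = np.sum((noisy - clean) ** 2) / np.sum(clean**2)
        assert ratio == pytest.approx(10**0.6, rel=1e-12)

    @pytest.mark.parametrize("level", NOISE_LEVELS_DB)
    def test_realized_snr_exact_at_every_level(self, level, rng):
        clean = preprocess_segment(rng.normal(size=1024))
        noise = rng.normal(size=1024)
        noisy = mix_at_snr(clean, noise, level)
        measured_db = 10 * np.log10(snr_in_ratio(clean, noisy))
        assert measured_db == pytest.approx(level, abs=1e-9)

    def test_silent_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="silent"):
            mix_at_snr(np.zeros(8), rng.normal(size=8), 0.0)
        with pytest.raises(ValueError, match="silent"):
            mix_at_snr(rng.normal(size=8), np.zeros(8), 0.0)


class TestMakePair:
    def test_pair_invariants_and_snr_preserved(self, rng):
        clean = rng.normal(size=1024)
        noise = rng.normal(size=1024)
        pair = make_pair(clean, noise, -6.0, source_id="t")
        assert np.max(np.abs(pair.noisy)) <= 1.0 + 1e-12
        assert np.max(np.abs(pair.clean)) <= 1.0 + 1e-12
        measured = 10 * np.log10(snr_in_ratio(pair.clean, pair.noisy))
        assert measured == pytest.approx(-6.0, abs=1e-6)

    def test_segment_pair_validates_bounds(self):
        with pytest.raises(ValueError, match="within"):
            SegmentPair(noisy=np.full(8, 2.0), clean=np.zeros(8), nominal_snr_db=0)


class TestSplit:
    def test_sizes_and_disjointness(self, rng):
        pairs = [
            SegmentPair(np.zeros(4), np.zeros(4), 0.0, source_id=str(i))
            for i in range(10)
        ]
        train, test = split_dataset(pairs, seed=1)
        assert len(train) == 8 and len(test) == 2
        ids = {p.source_id for p in train} | {p.source_id for p in test}
        assert len(ids) == 10

    def test_stated_ratio_at_protocol_scale(self):
        pairs = [
            SegmentPair(np.zeros(1), np.zeros(1), 0.0, source_id=str(i))
            for i in range(6888)
        ]
        train, test = split_dataset(pairs, seed=0)
        assert (len(train), len(test)) == (5511, 1377)

    def test_deterministic_given_seed(self):
        pairs = [
            SegmentPair(np.zeros(1), np.zeros(1), 0.0, source_id=str(i))
            for i in range(20)
        ]
        a = split_dataset(pairs, seed=42)
        b = split_dataset(pairs, seed=42)
        assert [p.source_id for p in a[0]] == [p.source_id for p in b[0]]

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            split_dataset([SegmentPair(np.zeros(1), np.zeros(1), 0.0)] * 4)


class TestRoundTrips:
    def _pairs(self, rng, n=3, length=32):
        out = []
        for i in range(n):
            clean = preprocess_segment(rng.normal(size=length))
            out.append(make_pair(clean, rng.normal(size=length), 6.0, f"p{i}"))
        return out

    @pytest.mark.parametrize(
        "save,load,name",
        [
            (save_pairs_csv, load_pairs_csv, "pairs.csv"),
            (save_pairs_npz, load_pairs_npz, "pairs.npz"),
        ],
    )
    def test_dataset_round_trip(self, save, load, name, tmp_path, rng):
        pairs = self._pairs(rng)
        path = tmp_path / name
        save(pairs, path)
        loaded = load(path)
        assert len(loaded) == len(pairs)
        for a, b in zip(pairs, loaded):
            np.testing.assert_allclose(b.clean, a.clean, atol=1e-12)
            np.testing.assert_allclose(b.noisy, a.noisy, atol=1e-12)
            assert b.nominal_snr_db == a.nominal_snr_db
            assert b.source_id == a.source_id


class TestWFDBReader:
    def _write_record(self, tmp_path, samples, fmt, gain=200.0, baseline=0):
        """Write a tiny two-channel record in WFDB format 212 or 16."""
        n = samples.shape[0]
        header = [
            f"rec {samples.shape[1]} 360 {n}",
        ]
        for ch in range(samples.shape[1]):
            header.append(
                f"rec.dat {fmt} {gain}({baseline})/mV 12 0 0 0 0 ch{ch}"
            )
        (tmp_path / "rec.hea").write_text("\n".join(header) + "\n")
        flat = samples.astype(np.int32).ravel()
        if fmt == 16:
            (tmp_path / "rec.dat").write_bytes(
                flat.astype("<i2").tobytes()
            )
        else:  # 212: pack pairs of 12-bit samples into 3 bytes
            vals = np.where(flat < 0, flat + 4096, flat)
            out = bytearray()
            for i in range(0, len(vals), 2):
                a = int(vals[i])
                b = int(vals[i + 1]) if i + 1 < len(vals) else 0
                out.append(a & 0xFF)
                out.append(((a >> 8) & 0x0F) | (((b >> 8) & 0x0F) << 4))
                out.append(b & 0xFF)
            (tmp_path / "rec.dat").write_bytes(bytes(out))

    @pytest.mark.parametrize("fmt", [212, 16])
    def test_round_trip_adc_to_physical(self, fmt, tmp_path, rng):
        adc = rng.integers(-2000, 2000, size=(20, 2))
        self._write_record(tmp_path, adc, fmt, gain=200.0, baseline=10)
        rec = read_wfdb_record(tmp_path / "rec")
        assert rec.sampling_rate == 360.0
        np.testing.assert_allclose(rec.signals, (adc - 10) / 200.0, atol=1e-12)

    def test_channel_selection_by_name(self, tmp_path, rng):
        adc = rng.integers(-100, 100, size=(10, 2))
        self._write_record(tmp_path, adc, 16)
        rec = read_wfdb_record(tmp_path / "rec", channels=["ch1"])
        assert rec.signal_names == ["ch1"]
        np.testing.assert_allclose(rec.signals[:, 0], adc[:, 1] / 200.0)
        with pytest.raises(ValueError, match="not in record"):
            read_wfdb_record(tmp_path / "rec", channels=["MLII"])
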