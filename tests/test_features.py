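"""Waveform measures: limit cases, independent-formula oracles, matrix assembly."""

import math

import numpy as np
import pytest

import eegsel as es
from eegsel.features import higuchi_fd, katz_fd


# ---------------------------------------------------------------------------
# independent direct-formula oracles (deliberately naive, loop-based)

def oracle_std(x):
    m = sum(x) / len(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))


def oracle_teager(x):
    vals = [x[n] ** 2 - x[n - 1] * x[n + 1] for n in range(1, len(x) - 1)]
    return sum(vals) / len(vals)


def oracle_shannon(x):
    total = sum(v * v for v in x)
    if total == 0:
        return 0.0
    out = 0.0
    for v in x:
        p = v * v / total
        if p > 0:
            out -= p * math.log(p)
    return out


def oracle_sure(x, eps):
    return (len(x) - sum(1 for v in x if abs(v) <= eps)
            + sum(min(v * v, eps * eps) for v in x))


def oracle_threshold(x, eps):
    return sum(1 for v in x if abs(v) > eps)


def oracle_katz(x):
    n = len(x) - 1
    L = sum(math.sqrt(1 + (x[i + 1] - x[i]) ** 2) for i in range(n))
    d = max(math.sqrt(i * i + (x[i] - x[0]) ** 2) for i in range(len(x)))
    return math.log10(n) / (math.log10(n) + math.log10(d / L))


def oracle_higuchi(x, kmax):
    # straight transcription of the published construction
    N = len(x)
    logs = []
    for k in range(1, kmax + 1):
        Lk = []
        for m in range(k):
            idx = list(range(m, N, k))
            if len(idx) < 2:
                continue
            length = sum(abs(x[idx[i]] - x[idx[i - 1]]) for i in range(1, len(idx)))
            norm = (N - 1) / ((len(idx) - 1) * k)
            Lk.append(length * norm / k)
        logs.append((math.log(1.0 / k), math.log(sum(Lk) / len(Lk))))
    xs = [a for a, _ in logs]
    ys = [b for _, b in logs]
    xbar, ybar = sum(xs) / len(xs), sum(ys) / len(ys)
    return (sum((a - xbar) * (b - ybar) for a, b in logs)
            / sum((a - xbar) ** 2 for a in xs))


class TestLimitCases:
    def test_constant_signal(self):
        x = np.full(100, 3.7)
        assert es.compute_measure(x, es.MeasureSpec("STD")) == 0.0
        assert es.compute_measure(x, es.MeasureSpec("TeEng")) == pytest.approx(0.0)
        assert es.compute_measure(x, es.MeasureSpec("ThEn", epsilon=5.0)) == 0.0
        assert es.compute_measure(x, es.MeasureSpec("TShEn")) == 0.0

    def test_uniform_energy_shannon_entropy_is_log_n(self):
        x = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])  # equal squared magnitudes
        assert es.compute_measure(x, es.MeasureSpec("ShEn")) == pytest.approx(
            math.log(8), abs=1e-12)

    def test_zero_signal_shannon_entropy_is_zero(self):
        assert es.compute_measure(np.zeros(16), es.MeasureSpec("ShEn")) == 0.0

    def test_linear_ramp_katz_dimension_is_one(self):
        x = 2.5 * np.arange(100) + 1.0
        assert es.compute_measure(x, es.MeasureSpec("KFD")) == pytest.approx(1.0)

    def test_sure_entropy_large_threshold_limit(self):
        x = np.array([0.5, -0.25, 0.1, 0.3])
        got = es.compute_measure(x, es.MeasureSpec("SuEn", epsilon=10.0))
        assert got == pytest.approx(np.sum(x ** 2))

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            es.compute_measure(np.array([1.0, 2.0]), es.MeasureSpec("STD"))


class TestFractalDimensionRanges:
    def test_higuchi_white_noise_near_two(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=2560)
        assert 1.8 <= higuchi_fd(x, kmax=10) <= 2.05

    def test_higuchi_ramp_near_one(self):
        x = np.linspace(0, 1, 2560)
        assert 0.95 <= higuchi_fd(x, kmax=10) <= 1.05

    def test_katz_noise_above_ramp(self):
        rng = np.random.default_rng(13)
        assert katz_fd(rng.normal(size=1000)) > katz_fd(np.linspace(0, 1, 1000))


class TestOracleAgreement:
    @pytest.mark.parametrize("trial", range(20))
    def test_closed_form_measures_match_oracles(self, trial):
        rng = np.random.default_rng(100 + trial)
        x = rng.normal(scale=rng.uniform(0.1, 10), size=rng.integers(50, 400))
        eps = 0.2 * float(np.std(x, ddof=1))
        checks = [
            (es.MeasureSpec("STD"), oracle_std(x)),
            (es.MeasureSpec("TeEng"), oracle_teager(x)),
            (es.MeasureSpec("ShEn"), oracle_shannon(x)),
            (es.MeasureSpec("SuEn", epsilon=eps), oracle_sure(x, eps)),
            (es.MeasureSpec("ThEn", epsilon=eps), oracle_threshold(x, eps)),
            (es.MeasureSpec("KFD"), oracle_katz(x)),
        ]
        for spec, expected in checks:
            got = es.compute_measure(x, spec)
            assert got == pytest.approx(expected, rel=1e-10), spec.name

    def test_higuchi_matches_independent_transcription(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = rng.normal(size=500)
            assert higuchi_fd(x, 8) == pytest.approx(oracle_higuchi(list(x), 8),
                                                     rel=1e-10)


class TestScaleBehaviour:
    def test_dispersion_scales_linearly_entropy_invariant(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=300)
        for name in ("STD", "IQR"):
            a = es.compute_measure(x, es.MeasureSpec(name))
            b = es.compute_measure(5 * x, es.MeasureSpec(name))
            assert b == pytest.approx(5 * a, rel=1e-10)
        assert (es.compute_measure(5 * x, es.MeasureSpec("ShEn"))
                == pytest.approx(es.compute_measure(x, es.MeasureSpec("ShEn")),
                                 rel=1e-10))

    def test_threshold_measures_depend_on_epsilon(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=300)
        small = es.compute_measure(x, es.MeasureSpec("ThEn", epsilon=0.1))
        large = es.compute_measure(x, es.MeasureSpec("ThEn", epsilon=2.0))
        assert small > large


class TestFeatureMatrixAssembly:
    def test_dwt_column_count_six_per_channel(self, small_fm, small_segments):
        assert small_fm.n_features == 6 * len(small_segments.montage)
        assert small_fm.n_segments == len(small_segments)

    def test_vmd_column_count_seven_per_channel(self):
        # short low-rate segments keep the 19-channel VMD build quick
        rng = np.random.default_rng(30)
        segs = es.SegmentSet(
            segments=(rng.normal(size=(19, 128)),),
            subject_ids=("s0",), labels=(0,), fs=64.0,
            montage=es.STANDARD_1020, seg_len_s=2.0)
        fm = es.build_feature_matrix(segs, "vmd", es.VMDParams(max_iter=20),
                                     es.MeasureSpec("STD"))
        assert fm.n_features == 133  # 7 bands x 19 channels

    def test_single_channel_dwt_has_six_columns(self):
        rng = np.random.default_rng(31)
        segs = es.SegmentSet(segments=(rng.normal(size=(1, 2560)),),
                             subject_ids=("s0",), labels=(1,), fs=256.0,
                             montage=("Cz",), seg_len_s=10.0)
        fm = es.build_feature_matrix(segs, "dwt", spec=es.MeasureSpec("STD"))
        assert fm.n_features == 6
        assert all(ch == "Cz" for ch, _ in fm.columns)

    def test_columns_channel_major_in_montage_order(self, small_fm, small_segments):
        chans = [ch for ch, _ in small_fm.columns]
        expected = [ch for ch in small_segments.montage for _ in range(6)]
        assert chans == expected

    def test_row_metadata_aligns_with_segments(self, small_fm, small_segments):
        assert small_fm.subject_ids == small_segments.subject_ids
        assert small_fm.labels == small_segments.labels

    def test_csv_round_trip(self, tmp_path, small_fm):
        path = tmp_path / "fm.csv"
        small_fm.to_csv(path)
        back = es.FeatureMatrix.from_csv(path)
        assert back.columns == small_fm.columns
        assert back.subject_ids == small_fm.subject_ids
        np.testing.assert_allclose(back.values, small_fm.values, rtol=1e-12)
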