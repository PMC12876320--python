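import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hemivox.synthetic_data import (
    SyllableSpec,
    UsvSimSpec,
    simulate_usv_audio,
    usv_benchmark_spec,
    usv_two_family_contours,
)
from hemivox.usv_pipeline import (
    SpectrogramParams,
    UsvError,
    cluster_syllables,
    compare_groups,
    detect_segments,
    extract_contour,
    extract_features,
    per_animal_means,
    spectrogram,
)

SR = 250_000


def _spec_of(wave, sr=SR):
    return spectrogram(wave, SpectrogramParams(sample_rate=sr))


def _one_syllable(kind="tone", f0=50_000.0, f1=50_000.0, dur=0.020, noise=0.001,
                  sr=SR, **kw):
    syl = SyllableSpec(onset=0.05, duration=dur, kind=kind, f_start=f0, f_end=f1, **kw)
    return simulate_usv_audio(
        UsvSimSpec(sample_rate=sr, syllables=[syl], noise_floor=noise,
                   edge_fraction=0.1, seed=0)
    )


class TestSpectrogram:
    def test_pure_tone_peak_within_one_bin(self):
        wave, _ = _one_syllable()
        sp = _spec_of(wave)
        seg_frames = sp.power.sum(axis=0) > 2 * sp.power.sum(axis=0).mean()
        peak = sp.freqs[sp.power[:, seg_frames].mean(axis=1).argmax()]
        assert abs(peak - 50_000.0) <= sp.params.freq_resolution

    def test_silence_near_zero_power(self):
        wave = np.zeros(4096)
        sp = _spec_of(wave)
        assert sp.power.max() == 0.0

    def test_band_restriction(self):
        wave, _ = _one_syllable()
        sp = _spec_of(wave)
        assert sp.freqs.min() >= 25_000.0
        assert sp.freqs.max() <= 110_000.0

    def test_energy_conservation_for_in_band_tone(self):
        # a steady in-band tone's spectral power (scaling='spectrum') equals
        # the squared RMS amplitude up to window normalization
        t = np.arange(0, 0.1, 1 / SR)
        wave = 0.4 * np.sin(2 * np.pi * 50_000 * t)
        sp = _spec_of(wave)
        frame_power = sp.power.sum(axis=0)
        # per-frame spectral power = (a^2 / 2) x Hann ENBW (1.5 bins)
        assert np.median(frame_power) == pytest.approx(0.4**2 / 2 * 1.5, rel=0.01)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(UsvError, match="sample rate"):
            spectrogram(np.zeros(4096), SpectrogramParams(sample_rate=100_000))


class TestDetection:
    def test_silence_plus_noise_yields_no_segments(self):
        rng = np.random.default_rng(0)
        wave = rng.normal(0, 0.01, size=SR // 2)
        segs = detect_segments(_spec_of(wave))
        assert segs == []

    def test_single_tone_onset_and_duration(self):
        wave, truth = _one_syllable(dur=0.020)
        sp = _spec_of(wave)
        segs = detect_segments(sp)
        assert len(segs) == 1
        hop = sp.params.hop_s
        assert abs(segs[0].onset - truth["onset"].iloc[0]) <= hop
        assert abs(segs[0].duration - truth["duration"].iloc[0]) <= 2 * hop

    def test_short_call_rejected_by_duration_rule(self):
        wave, _ = _one_syllable(dur=0.004)
        segs = detect_segments(_spec_of(wave))
        assert segs == []

    def test_benchmark_recall_and_precision(self):
        spec = usv_benchmark_spec(seed=1)
        wave, truth = simulate_usv_audio(spec)
        sp = spectrogram(wave, SpectrogramParams(sample_rate=spec.sample_rate))
        segs = detect_segments(sp)
        assert len(segs) == len(truth)
        for seg, (_, row) in zip(segs, truth.iterrows()):
            assert abs(seg.onset - row["onset"]) <= sp.params.hop_s


class TestFeatures:
    def test_tone_features(self):
        wave, truth = _one_syllable()
        sp = _spec_of(wave)
        feats = extract_features(sp, detect_segments(sp))
        binw = sp.params.freq_resolution
        row = feats.iloc[0]
        for col in ("peak_freq", "avg_freq", "max_freq", "min_freq",
                    "start_freq", "end_freq", "median_freq"):
            assert abs(row[col] - 50_000.0) <= binw
        assert row["bandwidth"] <= binw
        assert row["jitter"] == pytest.approx(0.0, abs=0.01)
        assert np.isnan(row["pause_duration_ms"])

    def test_chirp_features(self):
        wave, truth = _one_syllable(kind="linear", f0=40_000.0, f1=80_000.0,
                                    dur=0.030)
        sp = _spec_of(wave)
        feats = extract_features(sp, detect_segments(sp))
        row = feats.iloc[0]
        assert row["max_freq"] == pytest.approx(80_000.0, abs=2_500)
        assert row["min_freq"] == pytest.approx(40_000.0, abs=2_500)
        assert row["bandwidth"] == pytest.approx(40_000.0, abs=4_000)
        assert row["delta_freq"] == pytest.approx(40_000.0, abs=4_000)

    def test_pause_between_two_calls(self):
        syls = [
            SyllableSpec(onset=0.05, duration=0.020, kind="tone",
                         f_start=50_000.0, f_end=50_000.0),
            SyllableSpec(onset=0.170, duration=0.020, kind="tone",
                         f_start=60_000.0, f_end=60_000.0),
        ]
        wave, _ = simulate_usv_audio(
            UsvSimSpec(sample_rate=SR, syllables=syls, noise_floor=0.001,
                       edge_fraction=0.1, seed=0)
        )
        sp = _spec_of(wave)
        feats = extract_features(sp, detect_segments(sp))
        # true pause = 0.170 - 0.070 = 100 ms; ratio 100/20 = 5
        assert feats.iloc[1]["pause_duration_ms"] == pytest.approx(100.0, abs=3.0)
        assert feats.iloc[1]["pause_to_usv_ratio"] == pytest.approx(5.0, rel=0.1)

    def test_amplitude_scaling_leaves_features_unchanged(self):
        wave, _ = _one_syllable(kind="linear", f0=45_000.0, f1=55_000.0)
        sp1 = _spec_of(wave)
        sp2 = _spec_of(wave * 3.7)
        f1 = extract_features(sp1, detect_segments(sp1))
        f2 = extract_features(sp2, detect_segments(sp2))
        pd.testing.assert_frame_equal(f1, f2, rtol=1e-9)


class TestContour:
    def test_tone_contour_flat(self):
        wave, _ = _one_syllable()
        sp = _spec_of(wave)
        seg = detect_segments(sp)[0]
        contour = extract_contour(sp, seg)
        assert contour["frequency"].std() <= sp.params.freq_resolution

    def test_chirp_contour_slope(self):
        wave, truth = _one_syllable(kind="linear", f0=40_000.0, f1=80_000.0,
                                    dur=0.030)
        sp = _spec_of(wave)
        seg = detect_segments(sp)[0]
        contour = extract_contour(sp, seg)
        slope = np.polyfit(contour["time"], contour["frequency"], 1)[0]
        true_slope = (80_000.0 - 40_000.0) / 0.030
        assert slope == pytest.approx(true_slope, rel=0.05)

    def test_sine_fm_contour_period(self):
        wave, _ = _one_syllable(kind="sine_fm", f0=50_000.0, f1=60_000.0,
                                dur=0.040, mod_rate_hz=100.0)
        sp = _spec_of(wave)
        seg = detect_segments(sp)[0]
        contour = extract_contour(sp, seg)
        f = contour["frequency"].to_numpy()
        t = contour["time"].to_numpy()
        # period from the spacing of contour minima (one per 10 ms)
        minima = t[1:-1][(f[1:-1] < f[:-2]) & (f[1:-1] <= f[2:])]
        periods = np.diff(minima)
        periods = periods[periods > 0.005]
        assert np.mean(periods) == pytest.approx(0.010, abs=sp.params.hop_s)


class TestClustering:
    def _contours(self, seed=0):
        spec, labels = usv_two_family_contours(seed=seed, n_per_family=8,
                                               sample_rate=SR)
        wave, _ = simulate_usv_audio(spec)
        sp = _spec_of(wave)
        segs = detect_segments(sp)
        assert len(segs) == len(labels)
        return [extract_contour(sp, s) for s in segs], labels

    def test_two_families_perfectly_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        contours, labels = self._contours()
        out = cluster_syllables(contours, k_select="fixed", k_fixed=2, seed=0)
        assert adjusted_rand_score(labels, out.assignments) == 1.0

    def test_silhouette_selects_two(self):
        contours, _ = self._contours(seed=1)
        out = cluster_syllables(contours, k_max=6, k_select="silhouette", seed=0)
        assert out.k == 2

    def test_identical_contours_single_flagged_cluster(self):
        c = pd.DataFrame({"frequency": np.full(10, 50_000.0)})
        out = cluster_syllables([c] * 5, k_select="silhouette", seed=0)
        assert out.k == 1
        assert out.flag == "identical-contours"

    def test_determinism(self):
        contours, _ = self._contours(seed=2)
        a = cluster_syllables(contours, k_select="fixed", k_fixed=2, seed=3)
        b = cluster_syllables(contours, k_select="fixed", k_fixed=2, seed=3)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_per_animal_proportions_sum_to_one(self):
        contours, labels = self._contours(seed=3)
        animals = ["m1", "m2"] * (len(contours) // 2)
        out = cluster_syllables(contours, k_select="fixed", k_fixed=2,
                                animals=animals, seed=0)
        np.testing.assert_allclose(out.proportions.sum(axis=1), 1.0)


def ranksum_oracle(x, y):
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


class TestCompareGroups:
    def _frame(self, a_vals, b_vals):
        return pd.DataFrame(
            {
                "animal": [f"m{i}" for i in range(len(a_vals) + len(b_vals))],
                "group": ["A"] * len(a_vals) + ["B"] * len(b_vals),
                "peak_freq": list(a_vals) + list(b_vals),
            }
        )

    def test_identical_groups_p_one(self):
        out = compare_groups(self._frame([1, 2, 3], [1, 2, 3]), "group", "A", "B")
        assert out.loc[out["feature"] == "peak_freq", "p"].iloc[0] == 1.0

    def test_separated_toy_exact_p(self):
        out = compare_groups(self._frame([1, 2, 3], [4, 5, 6]), "group", "A", "B")
        assert out["p"].iloc[0] == pytest.approx(0.1)

    def test_matches_enumeration_combined_n_le_10(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(size=5)
            out = compare_groups(self._frame(a, b), "group", "A", "B")
            assert out["p"].iloc[0] == pytest.approx(ranksum_oracle(a, b))

    def test_all_tied_flagged(self):
        out = compare_groups(self._frame([2, 2, 2], [2, 2, 2]), "group", "A", "B")
        assert out["flag"].iloc[0] == "all-tied"

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(5)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            a, b = rng.normal(size=5), rng.normal(size=5)
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            rejections += res.pvalue < 0.05
        # exact test at combined n=10: attainable level just below 0.05
        assert rejections / n_sim == pytest.approx(0.04, abs=0.025)

    def test_per_animal_means_unit_of_analysis(self):
        feats = pd.DataFrame({"peak_freq": [1.0, 3.0, 5.0, 7.0],
                              "duration_ms": [10, 10, 20, 20]})
        out = per_animal_means(feats, ["m1", "m1", "m2", "m2"],
                               {"m1": "ctl", "m2": "oe"})
        assert out.set_index("animal").loc["m1", "peak_freq"] == 2.0
        assert out.set_index("animal").loc["m2", "duration_ms"] == 20.0
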