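"""Ultrasonic vocalization detection, features, contours, clustering, stats.

Detection follows a threshold scheme on the spectrogram (512-point FFT, 50%
overlap, Hann taper, analysis band 25-110 kHz): frames whose in-band power
exceeds 1.5x the mean frame power are active; runs of active frames merged
across short gaps become candidate segments; candidates survive if their
duration exceeds 5 ms and their spectral purity (mean per-frame fraction of
power in the peak bin) exceeds 25%.

Per segment, 15 acoustic features are computed from the contour (per-frame
frequency of maximum amplitude): duration, peak/average/max/min/start/end/
median frequency, delta frequency (|start - end|), bandwidth (max - min),
frequency SD, pause duration to the previous call, pause-to-call duration
ratio, jitter and shimmer (relative mean absolute successive change of
contour frequency / amplitude).

Contours resampled to a fixed length and z-scored are clustered with k-means
(best of several seeded repetitions, k chosen by silhouette unless fixed);
per-animal syllable-type proportion vectors and per-feature Mann-Whitney U
group comparisons close the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

ANALYSIS_BAND = (25_000.0, 110_000.0)

FEATURE_COLUMNS = [
    "duration_ms",
    "peak_freq",
    "avg_freq",
    "max_freq",
    "min_freq",
    "start_freq",
    "end_freq",
    "median_freq",
    "delta_freq",
    "bandwidth",
    "stddev_freq",
    "pause_duration_ms",
    "pause_to_usv_ratio",
    "jitter",
    "shimmer",
]


class UsvError(ValueError):
    pass


@dataclass
class SpectrogramParams:
    sample_rate: int
    fft_length: int = 512
    overlap: float = 0.5
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.fft_length & (self.fft_length - 1):
            raise UsvError("fft_length must be a power of two")
        if not 0 <= self.overlap < 1:
            raise UsvError("overlap must be in [0, 1)")

    @property
    def hop_s(self) -> float:
        return self.fft_length * (1.0 - self.overlap) / self.sample_rate

    @property
    def freq_resolution(self) -> float:
        return self.sample_rate / self.fft_length


@dataclass
class Spectrogram:
    times: np.ndarray  # frame centers, s
    freqs: np.ndarray  # Hz
    power: np.ndarray  # bins x frames, non-negative
    params: SpectrogramParams


@dataclass
class UsvSegment:
    onset: float
    duration: float
    start_frame: int
    end_frame: int  # inclusive
    band: tuple
    spectral_purity: float


def spectrogram(
    waveform: np.ndarray,
    params: SpectrogramParams,
    band: tuple = ANALYSIS_BAND,
) -> Spectrogram:
    """Power spectrogram restricted to the analysis band."""
    wave = np.asarray(waveform, dtype=float)
    if wave.size < params.fft_length:
        raise UsvError("waveform shorter than one FFT window")
    if params.sample_rate / 2.0 < band[1]:
        raise UsvError(
            f"sample rate {params.sample_rate} too low for analysis band up to {band[1]} Hz"
        )
    noverlap = int(params.fft_length * params.overlap)
    freqs, times, power = signal.spectrogram(
        wave,
        fs=params.sample_rate,
        window=params.window,
        nperseg=params.fft_length,
        noverlap=noverlap,
        detrend=False,
        scaling="spectrum",
        mode="psd",
    )
    keep = (freqs >= band[0]) & (freqs <= band[1])
    return Spectrogram(times=times, freqs=freqs[keep], power=power[keep, :], params=params)


def detect_segments(
    spec: Spectrogram,
    power_mult: float = 1.5,
    min_duration_ms: float = 5.0,
    min_purity: float = 0.25,
    max_gap_ms: float = 5.0,
    extend_peak_frac: float = 0.1,
) -> list[UsvSegment]:
    """Threshold detector.

    Active frames: in-band summed power > power_mult x mean frame power.
    Runs of active frames merged across gaps <= max_gap_ms form candidates;
    a candidate is kept iff duration > min_duration_ms and spectral purity
    (mean per-frame peak-bin power fraction) > min_purity.

    Boundary refinement: the Hann taper under-weights window edges, so the
    mean-power threshold drops the onset/offset frames of a call.  Each run
    is therefore extended outward while the per-frame peak power stays above
    ``extend_peak_frac`` x the run's median frame peak (set 0 to disable).
    Onset/offset are reported as the window extent of the active frames
    (first window start to last window end), so duration =
    (n_frames + 1) * hop for 50% overlap.
    """
    frame_power = spec.power.sum(axis=0)
    if frame_power.size == 0 or frame_power.max() == 0:
        return []
    active = frame_power > power_mult * frame_power.mean()
    hop = spec.params.hop_s
    window_s = spec.params.fft_length / spec.params.sample_rate
    max_gap_frames = int(np.floor(max_gap_ms / 1000.0 / hop))

    runs = []
    start = None
    for i, a in enumerate(active):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(active) - 1))

    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= max_gap_frames:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    # the duration rule applies to the core thresholded run; boundary
    # extension below only refines the measured extent of accepted calls
    peaks = spec.power.max(axis=0)
    refined = []
    for s, e in merged:
        # core duration = span of active-frame centers; edge windows overlap
        # the call only partially, so counting them as full hops would let
        # sub-threshold calls through
        core_ms = (e - s) * hop * 1000.0
        if core_ms <= min_duration_ms:
            continue
        if extend_peak_frac > 0:
            floor = extend_peak_frac * float(np.median(peaks[s : e + 1]))
            lo = refined[-1][1] + 1 if refined else 0
            while s > lo and peaks[s - 1] > floor:
                s -= 1
            while e + 1 < len(peaks) and peaks[e + 1] > floor:
                e += 1
        refined.append((s, e))

    segments = []
    for s, e in refined:
        n_frames = e - s + 1
        duration = (n_frames - 1) * hop + window_s
        block = spec.power[:, s : e + 1]
        totals = block.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            purity = float(np.mean(block.max(axis=0) / np.where(totals > 0, totals, np.inf)))
        if purity <= min_purity:
            continue
        onset = float(spec.times[s] - window_s / 2.0)
        segments.append(
            UsvSegment(
                onset=onset,
                duration=float(duration),
                start_frame=int(s),
                end_frame=int(e),
                band=(float(spec.freqs[0]), float(spec.freqs[-1])),
                spectral_purity=purity,
            )
        )
    return segments


def extract_contour(spec: Spectrogram, seg: UsvSegment) -> pd.DataFrame:
    """Per-frame (time, frequency of maximum amplitude, amplitude)."""
    block = spec.power[:, seg.start_frame : seg.end_frame + 1]
    if block.size == 0:
        raise UsvError("segment spans no frames")
    idx = block.argmax(axis=0)
    return pd.DataFrame(
        {
            "time": spec.times[seg.start_frame : seg.end_frame + 1],
            "frequency": spec.freqs[idx],
            "amplitude": np.sqrt(block.max(axis=0)),
        }
    )


def extract_features(spec: Spectrogram, segments: list[UsvSegment]) -> pd.DataFrame:
    """The 15 acoustic features per detected segment (one row each).

    The first call's pause_duration and pause ratio are missing by definition.
    Single-frame segments get zero SD/jitter/shimmer and a degenerate flag.
    """
    rows = []
    prev_offset = None
    for seg in segments:
        contour = extract_contour(spec, seg)
        f = contour["frequency"].to_numpy()
        a = contour["amplitude"].to_numpy()
        block = spec.power[:, seg.start_frame : seg.end_frame + 1]
        peak_bin, peak_frame = np.unravel_index(block.argmax(), block.shape)
        degenerate = len(f) < 2
        if degenerate:
            std = jitter = shimmer = 0.0
        else:
            std = float(np.std(f, ddof=1))
            jitter = float(np.mean(np.abs(np.diff(f))) / np.mean(f)) if np.mean(f) else 0.0
            shimmer = float(np.mean(np.abs(np.diff(a))) / np.mean(a)) if np.mean(a) else 0.0
        pause = np.nan if prev_offset is None else (seg.onset - prev_offset) * 1000.0
        rows.append(
            {
                "duration_ms": seg.duration * 1000.0,
                "peak_freq": float(spec.freqs[peak_bin]),
                "avg_freq": float(np.mean(f)),
                "max_freq": float(np.max(f)),
                "min_freq": float(np.min(f)),
                "start_freq": float(f[0]),
                "end_freq": float(f[-1]),
                "median_freq": float(np.median(f)),
                "delta_freq": float(abs(f[0] - f[-1])),
                "bandwidth": float(np.max(f) - np.min(f)),
                "stddev_freq": std,
                "pause_duration_ms": pause,
                "pause_to_usv_ratio": pause / (seg.duration * 1000.0)
                if np.isfinite(pause)
                else np.nan,
                "jitter": jitter,
                "shimmer": shimmer,
                "flag_degenerate": degenerate,
            }
        )
        prev_offset = seg.onset + seg.duration
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["flag_degenerate"])


# ---------------------------------------------------------------------------
# syllable clustering
# ---------------------------------------------------------------------------


@dataclass
class SyllableCluster:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float
    proportions: pd.DataFrame | None = None
    flag: str | None = None


def _contour_matrix(contours, resample_len: int) -> np.ndarray:
    feats = []
    for c in contours:
        f = np.asarray(c["frequency"] if isinstance(c, pd.DataFrame) else c, dtype=float)
        if f.size == 0:
            raise UsvError("empty contour")
        x_old = np.linspace(0.0, 1.0, f.size) if f.size > 1 else np.array([0.0])
        x_new = np.linspace(0.0, 1.0, resample_len)
        feats.append(np.interp(x_new, x_old, f))
    X = np.array(feats)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd


def cluster_syllables(
    contours,
    k_max: int = 100,
    repetitions: int = 3,
    k_select: str = "silhouette",
    k_fixed: int | None = None,
    resample_len: int = 32,
    animals=None,
    seed: int = 0,
) -> SyllableCluster:
    """k-means over resampled, z-scored contours.

    ``repetitions`` seeded initializations; best inertia kept.  k by
    silhouette over 2..min(k_max, n-1) unless ``k_select="fixed"`` with
    ``k_fixed``.  Identical contours collapse to a single flagged cluster.
    Per-animal syllable-type proportion vectors are emitted when ``animals``
    labels are given (rows sum to 1).
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    n = len(contours)
    if n < 2:
        raise UsvError("need at least 2 contours")
    X = _contour_matrix(contours, resample_len)
    if np.allclose(X, X[0]):
        assignments = np.zeros(n, dtype=int)
        return SyllableCluster(
            k=1,
            assignments=assignments,
            centroids=X[:1].copy(),
            inertia=0.0,
            proportions=_proportions(assignments, 1, animals),
            flag="identical-contours",
        )

    def fit(k: int) -> KMeans:
        return KMeans(n_clusters=k, n_init=repetitions, random_state=seed).fit(X)

    if k_select == "fixed":
        if k_fixed is None:
            raise UsvError("k_select='fixed' requires k_fixed")
        km = fit(k_fixed)
    elif k_select == "silhouette":
        best = None
        for k in range(2, min(k_max, n - 1) + 1):
            km_k = fit(k)
            if len(set(km_k.labels_)) < 2:
                continue
            s = silhouette_score(X, km_k.labels_)
            if best is None or s > best[0] + 1e-12:
                best = (s, km_k)
        if best is None:
            raise UsvError("silhouette selection failed")
        km = best[1]
    else:
        raise UsvError(f"unknown k_select {k_select!r}")

    return SyllableCluster(
        k=km.n_clusters,
        assignments=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        proportions=_proportions(km.labels_, km.n_clusters, animals),
    )


def _proportions(labels, k: int, animals) -> pd.DataFrame | None:
    if animals is None:
        return None
    df = pd.DataFrame({"animal": list(animals), "label": labels})
    counts = df.groupby("animal")["label"].value_counts().unstack(fill_value=0)
    counts = counts.reindex(columns=range(k), fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def compare_groups(
    per_animal: pd.DataFrame, group_col: str, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney U between two animal groups.

    ``per_animal`` must already hold one row per animal (per-animal feature
    means).  Exact null for combined n <= 20, normal approximation with tie
    correction otherwise.  All-tied features get p = 1 and a flag.
    """
    a = per_animal.loc[per_animal[group_col] == group_a]
    b = per_animal.loc[per_animal[group_col] == group_b]
    if len(a) < 2 or len(b) < 2:
        raise UsvError("need >= 2 animals per group")
    rows = []
    features = [c for c in per_animal.columns if c != group_col and
                np.issubdtype(per_animal[c].dtype, np.number)]
    for feat in features:
        xa = a[feat].dropna().to_numpy()
        xb = b[feat].dropna().to_numpy()
        if xa.size < 2 or xb.size < 2:
            continue
        combined = np.concatenate([xa, xb])
        if np.all(combined == combined[0]):
            rows.append({"feature": feat, "U": np.nan, "p": 1.0, "flag": "all-tied"})
            continue
        method = "exact" if combined.size <= 20 else "asymptotic"
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        rows.append({"feature": feat, "U": float(res.statistic), "p": float(res.pvalue),
                     "flag": None})
    return pd.DataFrame(rows, columns=["feature", "U", "p", "flag"])


def per_animal_means(features: pd.DataFrame, animals, groups=None) -> pd.DataFrame:
    """Collapse per-call features to per-animal means (the unit of analysis
    for group comparisons)."""
    df = features.copy()
    df["animal"] = list(animals)
    numeric = [c for c in FEATURE_COLUMNS if c in df.columns]
    out = df.groupby("animal")[numeric].mean()
    if groups is not None:
        gmap = dict(zip(df["animal"], groups)) if not isinstance(groups, dict) else groups
        out["group"] = [gmap[a] for a in out.index]
    return out.reset_index()
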