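"""Scalar waveform measures and feature-matrix assembly.

Ten measures summarize each sub-signal with one number: two dispersion
statistics (STD, IQR), two energies (logarithmic band power LBP, Teager
energy TeEng), four entropies (Shannon ShEn on the normalized energy
distribution, histogram-transformation TShEn, sure SuEn and threshold ThEn
— the latter two parameterized by a magnitude threshold epsilon), and two
fractal dimensions (Katz KFD, Higuchi HFD) capturing waveform complexity.
Exactly ONE measure is used per feature matrix; measures are investigated
individually, not fused.

Definitions (x of length N):

* STD  — sample standard deviation (N-1 denominator).
* IQR  — Q3 - Q1 with linear-interpolation quantiles.
* LBP  — log(mean(x_i^2) + log_guard), a log band power.
* TeEng — mean over interior samples of the Teager-Kaiser operator
  x_n^2 - x_{n-1} x_{n+1}.
* ShEn — -sum p_i log p_i with p_i = x_i^2 / sum x_j^2 (0 log 0 := 0);
  returns 0 for an all-zero signal.
* TShEn — Shannon entropy of a 16-bin amplitude histogram over [min, max].
* SuEn — N - #{i : |x_i| <= eps} + sum_i min(x_i^2, eps^2).
* ThEn — #{i : |x_i| > eps}.
* KFD  — log10(n) / (log10(n) + log10(d/L)) on the (index, amplitude)
  curve with unit index spacing: n = N-1 steps, L = curve path length,
  d = max Euclidean distance from the first curve point.
* HFD  — Higuchi's algorithm: slope of log L(k) vs log(1/k) for k = 1..kmax,
  curve lengths averaged over offsets.

The threshold eps defaults to 0.2 x STD of the sub-signal (scale-adaptive);
a fixed absolute epsilon is also supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decompose import DWTParams, VMDParams, band_names, subsignals_for_features
from .preprocess import SegmentSet

MEASURE_NAMES = ("STD", "IQR", "LBP", "TeEng", "ShEn",
                 "TShEn", "SuEn", "ThEn", "KFD", "HFD")


@dataclass(frozen=True)
class MeasureSpec:
    """Which measure to compute and its tunables.

    ``epsilon`` is the absolute magnitude threshold for ThEn/SuEn; when None
    it is set per sub-signal to ``epsilon_rel_std * STD(x)``.  ``kmax`` is
    Higuchi's maximum delay in samples; ``log_guard`` keeps logarithms finite
    on zero-energy signals.
    """

    name: str
    epsilon: "float | None" = None
    epsilon_rel_std: float = 0.2
    kmax: int = 10
    n_bins: int = 16
    log_guard: float = 1e-12

    def __post_init__(self) -> None:
        if self.name not in MEASURE_NAMES:
            raise ValueError(f"unknown measure {self.name!r}; one of {MEASURE_NAMES}")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.kmax < 2:
            raise ValueError("kmax must be >= 2")
        if self.log_guard <= 0:
            raise ValueError("log_guard must be > 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def _epsilon(x: np.ndarray, spec: MeasureSpec) -> float:
    if spec.epsilon is not None:
        return spec.epsilon
    return spec.epsilon_rel_std * float(np.std(x, ddof=1))


def teager_energy(x: np.ndarray) -> float:
    """Mean Teager-Kaiser operator over interior samples."""
    return float(np.mean(x[1:-1] ** 2 - x[:-2] * x[2:]))


def shannon_entropy(x: np.ndarray) -> float:
    """Entropy of the normalized squared-amplitude (energy) distribution."""
    e = x.astype(float) ** 2
    total = e.sum()
    if total <= 0:
        return 0.0  # constant-zero signal: entropy defined as 0
    p = e[e > 0] / total
    return float(-(p * np.log(p)).sum())


def histogram_entropy(x: np.ndarray, n_bins: int = 16) -> float:
    """Shannon entropy of a fixed-bin amplitude histogram over [min, max]."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        return 0.0  # constant signal: all mass in one bin
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def sure_entropy(x: np.ndarray, eps: float) -> float:
    below = np.abs(x) <= eps
    return float(len(x) - below.sum() + np.minimum(x ** 2, eps ** 2).sum())


def threshold_entropy(x: np.ndarray, eps: float) -> float:
    return float((np.abs(x) > eps).sum())


def katz_fd(x: np.ndarray) -> float:
    """Katz's fractal dimension of the (index, amplitude) curve, unit spacing."""
    n = len(x) - 1
    dx = np.diff(x)
    L = float(np.sqrt(1.0 + dx ** 2).sum())  # curve path length
    idx = np.arange(len(x), dtype=float)
    d = float(np.sqrt(idx ** 2 + (x - x[0]) ** 2).max())  # farthest point
    if L <= 0 or d <= 0:
        return 1.0  # degenerate (constant) waveform: a straight line
    return float(np.log10(n) / (np.log10(n) + np.log10(d / L)))


def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi's fractal dimension: slope of log L(k) against log(1/k)."""
    N = len(x)
    if N < kmax + 1:
        raise ValueError(f"need at least kmax+1={kmax + 1} samples, got {N}")
    log_k = np.empty(kmax)
    log_L = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            sub = x[m::k]
            n_i = len(sub) - 1
            if n_i < 1:
                continue
            # normalization maps the subsampled length back to the N-grid
            lengths.append(np.abs(np.diff(sub)).sum() * (N - 1) / (n_i * k) / k)
        log_k[k - 1] = np.log(1.0 / k)
        log_L[k - 1] = np.log(max(np.mean(lengths), 1e-300))
    slope, _ = np.polyfit(log_k, log_L, 1)
    return float(slope)


def compute_measure(x: np.ndarray, spec: MeasureSpec) -> float:
    """Apply the configured measure to one sub-signal; always a finite scalar."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("compute_measure expects a 1-D signal of length >= 3")
    name = spec.name
    if name == "STD":
        return float(np.std(x, ddof=1))
    if name == "IQR":
        q1, q3 = np.percentile(x, [25, 75])
        return float(q3 - q1)
    if name == "LBP":
        return float(np.log(np.mean(x ** 2) + spec.log_guard))
    if name == "TeEng":
        return teager_energy(x)
    if name == "ShEn":
        return shannon_entropy(x)
    if name == "TShEn":
        return histogram_entropy(x, spec.n_bins)
    if name == "SuEn":
        return sure_entropy(x, _epsilon(x, spec))
    if name == "ThEn":
        return threshold_entropy(x, _epsilon(x, spec))
    if name == "KFD":
        return katz_fd(x)
    if name == "HFD":
        return higuchi_fd(x, spec.kmax)
    raise ValueError(f"unknown measure {name!r}")  # unreachable after validation


@dataclass(frozen=True)
class FeatureMatrix:
    """Segments x (channel, band) scalar features with full metadata.

    ``columns`` is an ordered tuple of (channel_name, band_name) pairs,
    channel-major in montage order, bands in sub-signal order; n_features is
    7 x ch for VMD and 6 x ch for DWT.
    """

    values: np.ndarray
    columns: "tuple[tuple[str, str], ...]"
    subject_ids: "tuple[str, ...]"
    labels: "tuple[int, ...]"
    measure: MeasureSpec
    method: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.subject_ids), len(self.columns)):
            raise ValueError("values shape does not match metadata")
        if len(self.labels) != len(self.subject_ids):
            raise ValueError("labels/subject_ids length mismatch")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate (channel, band) columns")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature matrix contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def channel_names(self) -> "tuple[str, ...]":
        seen: dict[str, None] = {}
        for ch, _ in self.columns:
            seen.setdefault(ch)
        return tuple(seen)

    def columns_for_channels(self, channels: "set[str] | list[str]") -> np.ndarray:
        """Boolean column mask selecting every band of the given channels."""
        chans = set(channels)
        return np.array([ch in chans for ch, _ in self.columns], dtype=bool)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{ch}|{band}" for ch, band in self.columns]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "label", list(self.labels))
        df.insert(0, "subject_id", list(self.subject_ids))
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, measure: "MeasureSpec | None" = None,
                 method: str = "unknown") -> "FeatureMatrix":
        df = pd.read_csv(path)
        feat_cols = [c for c in df.columns if "|" in c]
        columns = tuple(tuple(c.split("|", 1)) for c in feat_cols)
        return cls(values=df[feat_cols].to_numpy(float),
                   columns=columns,
                   subject_ids=tuple(df["subject_id"].astype(str)),
                   labels=tuple(int(v) for v in df["label"]),
                   measure=measure if measure is not None else MeasureSpec("STD"),
                   method=method)


def build_feature_matrix(segs: SegmentSet, method: str = "dwt",
                         dparams: "VMDParams | DWTParams | None" = None,
                         spec: MeasureSpec = MeasureSpec("TeEng")) -> FeatureMatrix:
    """Decompose every channel of every segment and apply one measure.

    Columns are channel-major (montage order), bands in the sub-signal order
    of the decomposition method; rows align with the SegmentSet ordering.
    """
    if len(segs) == 0:
        raise ValueError("empty segment set")
    bands = band_names(method, dparams)
    columns = tuple((ch, band) for ch in segs.montage for band in bands)
    values = np.empty((len(segs), len(columns)))
    for r, seg in enumerate(segs.segments):
        col = 0
        for ch_idx in range(len(segs.montage)):
            subs = subsignals_for_features(seg[ch_idx], method, dparams, segs.fs)
            for sub in subs:
                values[r, col] = compute_measure(sub.samples, spec)
                col += 1
    return FeatureMatrix(values=values, columns=columns,
                         subject_ids=segs.subject_ids, labels=segs.labels,
                         measure=spec, method=method.lower())
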