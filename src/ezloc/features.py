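"""The 34-feature battery computed on 2-s iEEG windows.

Four families of per-window descriptors, chosen to give a broad view of
each contact's activity:

* 5 *moment* features — mean, median, variance, skewness, kurtosis;
* 11 *complexity* features — Hjorth mobility/complexity, approximate and
  sample entropy, permutation entropy, Lempel–Ziv complexity, Higuchi and
  Katz fractal dimensions, a DFA Hurst exponent, zero-crossing rate and
  lag-1 autocorrelation;
* 12 *frequency* features — six band powers (delta through high-gamma),
  total power, mean/median frequency, 95% spectral edge, spectral
  entropy and a high-to-low energy ratio (the quantity underlying the
  Epileptogenicity Index);
* 6 *network* features — a contact's mean absolute correlation with all
  other contacts, plus its coherence node strength (mean
  magnitude-squared coherence) in five bands.

All single-channel features are computed channel-wise on 512-sample
windows (2 s at 256 Hz); network features are computed jointly on all
channels of a window and then assigned per channel.  Degenerate windows
(constant/zero) yield NaN for the features that are undefined there; NaN
is the package-wide missing-value flag.

The registry is data-driven: the default battery has exactly 34 entries,
but a reduced or extended registry can be supplied to ``extract_all``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .io_preprocess import (
    COMMON_RATE_HZ,
    ICTAL,
    Recording,
    WindowGrid,
    normalize_postonset,
    resample_feature_series,
    segment_windows,
)

# Conventional clinical band edges, half-open [lo, hi), bounded by the
# 128-Hz Nyquist of the 256-Hz common rate.
BANDS_HZ: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "lowgamma": (30.0, 60.0),
    "highgamma": (60.0, 120.0),
}
NETWORK_BANDS_HZ: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 120.0),
}
SPECTRAL_RANGE_HZ = (1.0, 120.0)

# Coherence estimator inside one 2-s window: 0.5-s Hann segments at 50%
# overlap -> 7 segments, 2-Hz resolution; E[msc] ~ 1/7 for independent
# channels.
COHERENCE_NPERSEG = 128
COHERENCE_NOVERLAP = 64

MOMENT_NAMES = ("mean", "median", "variance", "skewness", "kurtosis")
COMPLEXITY_NAMES = (
    "hjorth_mobility",
    "hjorth_complexity",
    "approximate_entropy",
    "sample_entropy",
    "permutation_entropy",
    "lempel_ziv",
    "higuchi_fd",
    "katz_fd",
    "hurst_dfa",
    "zero_crossing_rate",
    "autocorr_lag1",
)
FREQUENCY_NAMES = (
    "power_delta",
    "power_theta",
    "power_alpha",
    "power_beta",
    "power_lowgamma",
    "power_highgamma",
    "power_total",
    "mean_frequency",
    "median_frequency",
    "spectral_edge_95",
    "spectral_entropy",
    "energy_ratio",
)
NETWORK_NAMES = (
    "correlation_strength",
    "coherence_delta",
    "coherence_theta",
    "coherence_alpha",
    "coherence_beta",
    "coherence_gamma",
)


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    category: str  # moment | complexity | frequency | network
    params: dict = field(default_factory=dict)


@dataclass
class FeatureRegistry:
    """Ordered, named battery of window features."""

    descriptors: list[FeatureDescriptor]

    def __post_init__(self) -> None:
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    @property
    def categories(self) -> list[str]:
        return [d.category for d in self.descriptors]

    def __len__(self) -> int:
        return len(self.descriptors)

    def subset(self, names: list[str]) -> "FeatureRegistry":
        by_name = {d.name: d for d in self.descriptors}
        return FeatureRegistry([by_name[n] for n in names])

    def to_config(self) -> list[dict]:
        return [
            {"name": d.name, "category": d.category, "params": dict(d.params)}
            for d in self.descriptors
        ]

    @classmethod
    def from_config(cls, entries: list[dict]) -> "FeatureRegistry":
        return cls(
            [
                FeatureDescriptor(e["name"], e["category"], dict(e.get("params", {})))
                for e in entries
            ]
        )


def default_registry() -> FeatureRegistry:
    """The default 34-feature battery (5 moment + 11 complexity + 12
    frequency + 6 network)."""
    descs = (
        [FeatureDescriptor(n, "moment") for n in MOMENT_NAMES]
        + [FeatureDescriptor(n, "complexity") for n in COMPLEXITY_NAMES]
        + [FeatureDescriptor(n, "frequency") for n in FREQUENCY_NAMES]
        + [FeatureDescriptor(n, "network") for n in NETWORK_NAMES]
    )
    return FeatureRegistry(descs)


# ---------------------------------------------------------------------------
# Moment features
# ---------------------------------------------------------------------------


def moment_features(x: np.ndarray) -> dict[str, float]:
    """Sample moments of one window.

    Variance uses the n-1 denominator; skewness and kurtosis are the
    standardized central moments m3/m2^1.5 and m4/m2^2 (kurtosis is not
    excess: Gaussian -> 3).  Zero-variance windows leave skewness and
    kurtosis undefined.
    """
    x = np.asarray(x, dtype=float)
    var = x.var(ddof=1) if x.size > 1 else 0.0
    out = {
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "variance": float(var),
    }
    m2 = x.var(ddof=0)
    if m2 <= 0:
        out["skewness"] = np.nan
        out["kurtosis"] = np.nan
    else:
        xc = x - x.mean()
        out["skewness"] = float(np.mean(xc**3) / m2**1.5)
        out["kurtosis"] = float(np.mean(xc**4) / m2**2)
    return out


# ---------------------------------------------------------------------------
# Complexity features
# ---------------------------------------------------------------------------


def hjorth(x: np.ndarray) -> tuple[float, float]:
    """Hjorth mobility and complexity.

    mobility(x) = sqrt(var(dx)/var(x)); complexity = mobility(dx)/mobility(x).
    """
    x = np.asarray(x, dtype=float)
    v0 = x.var()
    if v0 <= 0:
        return np.nan, np.nan
    dx = np.diff(x)
    v1 = dx.var()
    mobility = np.sqrt(v1 / v0)
    if v1 <= 0:
        return float(mobility), np.nan
    ddx = np.diff(dx)
    v2 = ddx.var()
    complexity = np.sqrt(v2 / v1) / mobility
    return float(mobility), float(complexity)


def _chebyshev_count_matrix(x: np.ndarray, m: int) -> np.ndarray:
    """Pairwise Chebyshev distances between all length-m templates of x."""
    d1 = np.abs(x[:, None] - x[None, :])
    n = x.size
    dm = d1[: n - m + 1, : n - m + 1].copy()
    for k in range(1, m):
        np.maximum(dm, d1[k : n - m + 1 + k, k : n - m + 1 + k], out=dm)
    return dm


def _apen_sampen(x: np.ndarray, m: int = 2, r: float | None = None
                 ) -> tuple[float, float]:
    """ApEn and SampEn from shared template-distance matrices."""
    sd = x.std()
    if r is None:
        r = 0.2 * sd
    if sd == 0:
        return 0.0, np.nan
    n = x.size
    d1 = np.abs(x[:, None] - x[None, :])
    dm = np.maximum(d1[: n - m + 1, : n - m + 1], d1[1:, 1:]) if m == 2 else \
        _chebyshev_count_matrix(x, m)
    dm1 = np.maximum(dm[: n - m, : n - m], d1[m:, m:])
    hit_m = dm <= r
    hit_m1 = dm1 <= r
    apen = float(np.mean(np.log(hit_m.mean(axis=1)))
                 - np.mean(np.log(hit_m1.mean(axis=1))))
    n_templ = n - m
    b = int((hit_m[:n_templ, :n_templ].sum() - n_templ) // 2)
    a = int((hit_m1.sum() - hit_m1.shape[0]) // 2)
    sampen = float(-np.log(a / b)) if a > 0 and b > 0 else np.nan
    return apen, sampen


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Pincus approximate entropy (self-matches included, Chebyshev metric).

    ``r`` defaults to 0.2 x sd(x).  A constant window has ApEn 0: every
    template matches every other.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if r is None:
        r = 0.2 * sd
    if sd == 0:
        return 0.0

    def phi(mm: int) -> float:
        dm = _chebyshev_count_matrix(x, mm)
        c = (dm <= r).mean(axis=1)  # includes self-match
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Richman–Moorman sample entropy (self-matches excluded).

    -log(A/B) with B/A the m-/(m+1)-template match counts over the first
    N-m templates.  Undefined (NaN) when either count is zero.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = x.std()
    if r is None:
        r = 0.2 * sd
    if sd == 0:
        return np.nan
    n_templ = n - m  # common template count for both lengths
    dm = _chebyshev_count_matrix(x, m)[:n_templ, :n_templ]
    dm1 = _chebyshev_count_matrix(x, m + 1)
    b = int(((dm <= r).sum() - n_templ) // 2)
    a = int(((dm1 <= r).sum() - dm1.shape[0]) // 2)
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Bandt–Pompe permutation entropy, normalised by log(order!).

    Constant windows produce a single ordinal pattern -> 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.size - (order - 1) * delay
    if n < 1:
        raise ValueError("window too short for the requested order/delay")
    emb = np.empty((n, order))
    for k in range(order):
        emb[:, k] = x[k * delay : k * delay + n]
    # stable argsort -> ties broken by time index, so constants give one pattern
    patterns = np.argsort(emb, axis=1, kind="stable")
    base = order + 1
    codes = patterns @ (base ** np.arange(order))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(h / np.log(float(math.factorial(order))))


def lempel_ziv(x: np.ndarray) -> float:
    """LZ76 complexity of the median-binarised window.

    The raw new-phrase count c is normalised by n/log2(n), the asymptotic
    complexity of a random binary sequence.
    """
    x = np.asarray(x, dtype=float)
    s = (x > np.median(x)).astype(np.uint8)
    n = s.size
    if n < 2:
        return 0.0
    c = _lz76_count(s)
    return float(c / (n / np.log2(n)))


def _lz76_count_py(s) -> int:
    """LZ76 exhaustive-history phrase count (Kaspar & Schuster parsing)."""
    n = s.size
    c = 1
    l, i, k = 1, 0, 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k_max, k)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


try:  # optional JIT of the phrase-count loop; results are identical
    from numba import njit as _njit

    _lz76_count = _njit(cache=False)(_lz76_count_py)
    _lz76_count(np.zeros(4, dtype=np.uint8))  # compile eagerly
except Exception:  # pragma: no cover - numba absent or JIT failure
    _lz76_count = _lz76_count_py


def higuchi_fd(x: np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal dimension via curve-length regression over k=1..kmax."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if x.std() == 0:
        return np.nan
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (k * (idx.size - 1))
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    valid = lk > 0
    if valid.sum() < 2:
        return np.nan
    ks = np.arange(1, kmax + 1)[valid]
    slope = np.polyfit(np.log(1.0 / ks), np.log(lk[valid]), 1)[0]
    return float(slope)


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension: log10(n)/(log10(n) + log10(d/L)).

    n is the number of steps (N-1), L the total amplitude path length and
    d the maximum amplitude excursion from the first sample.  A monotone
    straight line has d = L, hence KFD = 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size - 1
    dx = np.abs(np.diff(x))
    length = dx.sum()
    d = np.abs(x - x[0]).max()
    if length == 0 or d == 0:
        return np.nan
    return float(np.log10(n) / (np.log10(n) + np.log10(d / length)))


def hurst_dfa(x: np.ndarray, scales: tuple[int, ...] = (4, 8, 16, 32, 64)) -> float:
    """Hurst exponent from first-order detrended fluctuation analysis.

    The demeaned window is integrated, split into non-overlapping boxes
    of each scale, linearly detrended per box; the exponent is the slope
    of log F(s) against log s.
    """
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        return np.nan
    y = np.cumsum(x - x.mean())
    fs = []
    used = []
    for s in scales:
        n_boxes = y.size // s
        if n_boxes < 2:
            continue
        boxes = y[: n_boxes * s].reshape(n_boxes, s)
        t = np.arange(s)
        t_mean = t.mean()
        t_c = t - t_mean
        denom = (t_c**2).sum()
        slopes = boxes @ t_c / denom
        inter = boxes.mean(axis=1)
        resid = boxes - (inter[:, None] + slopes[:, None] * t_c[None, :])
        f = np.sqrt((resid**2).mean())
        if f > 0:
            fs.append(f)
            used.append(s)
    if len(fs) < 2:
        return np.nan
    return float(np.polyfit(np.log(used), np.log(fs), 1)[0])


def zero_crossing_rate(x: np.ndarray) -> float:
    """Fraction of consecutive sample pairs with a sign change."""
    x = np.asarray(x, dtype=float)
    signs = np.signbit(x)
    return float(np.mean(signs[1:] != signs[:-1]))


def autocorr_lag1(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = (xc**2).sum()
    if denom == 0:
        return np.nan
    return float((xc[:-1] * xc[1:]).sum() / denom)


def complexity_rest(x: np.ndarray) -> dict[str, float]:
    """The complexity features beyond Hjorth and approximate entropy."""
    return {
        "sample_entropy": sample_entropy(x),
        "permutation_entropy": permutation_entropy(x)
        if np.std(x) > 0
        else 0.0,
        "lempel_ziv": lempel_ziv(x),
        "higuchi_fd": higuchi_fd(x),
        "katz_fd": katz_fd(x),
        "hurst_dfa": hurst_dfa(x),
        "zero_crossing_rate": zero_crossing_rate(x),
        "autocorr_lag1": autocorr_lag1(x),
    }


def complexity_features(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    mob, comp = hjorth(x)
    apen, sampen = _apen_sampen(x)  # shared distance matrices
    return {
        "hjorth_mobility": mob,
        "hjorth_complexity": comp,
        "approximate_entropy": apen,
        "sample_entropy": sampen,
        "permutation_entropy": permutation_entropy(x) if np.std(x) > 0 else 0.0,
        "lempel_ziv": lempel_ziv(x),
        "higuchi_fd": higuchi_fd(x),
        "katz_fd": katz_fd(x),
        "hurst_dfa": hurst_dfa(x),
        "zero_crossing_rate": zero_crossing_rate(x),
        "autocorr_lag1": autocorr_lag1(x),
    }


# ---------------------------------------------------------------------------
# Frequency features
# ---------------------------------------------------------------------------


def _periodogram(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    return sp_signal.periodogram(x, fs=fs, window="hann", detrend=False, axis=-1)


def frequency_features(x: np.ndarray, fs: float = COMMON_RATE_HZ) -> dict[str, float]:
    """Hann-periodogram spectral descriptors of one window.

    Band powers are sums of periodogram bins within half-open bands; the
    spectral summaries (mean/median frequency, 95% edge) are restricted
    to 1-120 Hz at the 0.5-Hz periodogram resolution.  Spectral entropy
    is computed on the segment-averaged (Welch) spectrum of the window
    instead, whose reduced bin variance keeps the flat-spectrum value
    near 1 (a raw periodogram's exponential bins bias it down by
    (1-gamma)/ln(nbins) ~ 0.08).  An all-zero window has zero powers and
    undefined frequency summaries.
    """
    x = np.asarray(x, dtype=float)
    freqs, psd = _periodogram(x, fs)
    out: dict[str, float] = {}
    for band, (lo, hi) in BANDS_HZ.items():
        sel = (freqs >= lo) & (freqs < hi)
        out[f"power_{band}"] = float(psd[sel].sum())
    lo, hi = SPECTRAL_RANGE_HZ
    sel = (freqs >= lo) & (freqs < hi)
    p = psd[sel]
    f = freqs[sel]
    total = p.sum()
    out["power_total"] = float(total)
    if total <= 0:
        out.update(
            mean_frequency=np.nan,
            median_frequency=np.nan,
            spectral_edge_95=np.nan,
            spectral_entropy=np.nan,
            energy_ratio=np.nan,
        )
        return out
    out["mean_frequency"] = float((f * p).sum() / total)
    cum = np.cumsum(p) / total
    out["median_frequency"] = float(f[np.searchsorted(cum, 0.5)])
    out["spectral_edge_95"] = float(f[np.searchsorted(cum, 0.95)])
    wf, wp = sp_signal.welch(
        x, fs=fs, window="hann", nperseg=COHERENCE_NPERSEG,
        noverlap=COHERENCE_NOVERLAP, detrend=False,
    )
    wsel = (wf >= lo) & (wf < hi)
    pn = wp[wsel] / wp[wsel].sum()
    pn = pn[pn > 0]
    out["spectral_entropy"] = float(-(pn * np.log(pn)).sum() / np.log(wsel.sum()))
    low = out["power_delta"] + out["power_theta"] + out["power_alpha"]
    high = out["power_beta"] + out["power_lowgamma"] + out["power_highgamma"]
    out["energy_ratio"] = float(high / low) if low > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# Network features
# ---------------------------------------------------------------------------


def _segment_fft(win: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Windowed segment FFTs for the coherence estimator.

    Returns (freqs, Z) with Z of shape channels x segments x freq bins.
    """
    c, n = win.shape
    step = COHERENCE_NPERSEG - COHERENCE_NOVERLAP
    starts = np.arange(0, n - COHERENCE_NPERSEG + 1, step)
    taper = sp_signal.get_window("hann", COHERENCE_NPERSEG)
    segs = np.stack([win[:, s : s + COHERENCE_NPERSEG] for s in starts], axis=1)
    segs = segs - segs.mean(axis=2, keepdims=True)
    z = np.fft.rfft(segs * taper, axis=2)
    freqs = np.fft.rfftfreq(COHERENCE_NPERSEG, d=1.0 / COMMON_RATE_HZ)
    return freqs, z


def pairwise_msc(win: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence between every channel pair of a window.

    Welch-style estimate from 0.5-s Hann segments at 50% overlap (7
    segments in a 2-s window).  Returns (freqs, msc) with msc of shape
    channels x channels x freq bins; the diagonal is 1 by construction.
    """
    freqs, z = _segment_fft(np.asarray(win, dtype=float))
    sxy = np.einsum("csf,dsf->cdf", z, np.conj(z)) / z.shape[1]
    sxx = np.real(np.einsum("ccf->cf", sxy))
    with np.errstate(invalid="ignore", divide="ignore"):
        msc = np.abs(sxy) ** 2 / (sxx[:, None, :] * sxx[None, :, :])
    return freqs, msc


def network_features(win: np.ndarray) -> dict[str, np.ndarray]:
    """Per-channel cross-channel descriptors of one multichannel window.

    correlation_strength is the mean absolute Pearson correlation with
    every other channel; coherence_<band> is the channel's node strength
    (mean msc with every other channel) averaged over in-band bins.
    """
    win = np.asarray(win, dtype=float)
    c = win.shape[0]
    if c < 2:
        warnings.warn("network features need >=2 channels; emitting NaN")
        nan = np.full(max(c, 1), np.nan)
        return {name: nan.copy() for name in NETWORK_NAMES}
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(win)
    np.fill_diagonal(corr, np.nan)
    out = {
        "correlation_strength": np.nanmean(np.abs(corr), axis=1)
        if not np.isnan(corr).all()
        else np.full(c, np.nan)
    }
    freqs, msc = pairwise_msc(win)
    for band, (lo, hi) in NETWORK_BANDS_HZ.items():
        sel = (freqs >= lo) & (freqs < hi)
        band_msc = msc[:, :, sel].mean(axis=2)
        np.fill_diagonal(band_msc, np.nan)
        out[f"coherence_{band}"] = np.nanmean(band_msc, axis=1)
    return out


# ---------------------------------------------------------------------------
# Tensor extraction
# ---------------------------------------------------------------------------


@dataclass
class FeatureTensor:
    """channels x windows x features values for one recording."""

    values: np.ndarray
    registry: FeatureRegistry
    epoch_type: str
    channel_names: list[str]
    patient_id: str
    recording_id: str
    window_tags: list[str]

    def __post_init__(self) -> None:
        if self.values.shape[2] != len(self.registry):
            raise ValueError("third tensor dimension must equal registry length")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


def _window_features_single(x: np.ndarray, fs: float) -> dict[str, float]:
    out = {}
    out.update(moment_features(x))
    out.update(complexity_features(x))
    out.update(frequency_features(x, fs))
    return out


def extract_all(
    rec: Recording,
    registry: FeatureRegistry | None = None,
    grid: WindowGrid | None = None,
    drop_edge: str = "earliest",
) -> FeatureTensor:
    """Compute the feature battery for every (channel, retained window).

    The recording must already be at the 256-Hz common rate.  Network
    features (if present in the registry) are computed jointly across
    channels per window; everything else channel-wise.  Deterministic:
    identical input yields an identical tensor.
    """
    if rec.rate_hz != COMMON_RATE_HZ:
        raise ValueError("extract_all expects a recording at the common rate")
    registry = registry or default_registry()
    grid = grid or segment_windows(rec, drop_edge=drop_edge)
    names = registry.names
    need_network = any(d.category == "network" for d in registry.descriptors)
    need_single = any(d.category != "network" for d in registry.descriptors)
    c = rec.n_channels
    w = grid.n_windows
    values = np.full((c, w, len(names)), np.nan)
    col = {n: j for j, n in enumerate(names)}

    for wi, (start, end) in enumerate(grid.windows):
        win = rec.signal[:, start:end]
        if need_single:
            for ci in range(c):
                feats = _window_features_single(win[ci], rec.rate_hz)
                for n, v in feats.items():
                    if n in col:
                        values[ci, wi, col[n]] = v
        if need_network:
            net = network_features(win)
            for n, v in net.items():
                if n in col:
                    values[:, wi, col[n]] = v

    return FeatureTensor(
        values=values,
        registry=registry,
        epoch_type=rec.epoch_type,
        channel_names=list(rec.channel_names),
        patient_id=rec.patient_id,
        recording_id=rec.recording_id,
        window_tags=list(grid.tags),
    )


def resample_interictal_tensor(tensor: FeatureTensor, target_len: int = 28) -> FeatureTensor:
    """Downsample every (channel, feature) interictal series to ``target_len``."""
    if tensor.epoch_type == ICTAL:
        raise ValueError("temporal resampling applies to interictal tensors")
    c, _, f = tensor.values.shape
    out = np.empty((c, target_len, f))
    for ci in range(c):
        for fi in range(f):
            out[ci, :, fi] = resample_feature_series(tensor.values[ci, :, fi], target_len)
    return FeatureTensor(
        values=out,
        registry=tensor.registry,
        epoch_type=tensor.epoch_type,
        channel_names=tensor.channel_names,
        patient_id=tensor.patient_id,
        recording_id=tensor.recording_id,
        window_tags=["base"] * target_len,
    )


def normalize_ictal_tensor(tensor: FeatureTensor) -> FeatureTensor:
    """Apply the pre/post baseline normalisation per (channel, feature).

    Keeps only the 14 normalised post-onset values; pre-onset windows are
    consumed as the baseline and dropped.
    """
    if tensor.epoch_type != ICTAL:
        raise ValueError("post-onset normalisation applies to ictal tensors")
    pre_idx = [i for i, t in enumerate(tensor.window_tags) if t == "pre"]
    post_idx = [i for i, t in enumerate(tensor.window_tags) if t == "post"]
    c, _, f = tensor.values.shape
    out = np.empty((c, len(post_idx), f))
    for ci in range(c):
        for fi in range(f):
            out[ci, :, fi] = normalize_postonset(
                tensor.values[ci, pre_idx, fi], tensor.values[ci, post_idx, fi]
            )
    return FeatureTensor(
        values=out,
        registry=tensor.registry,
        epoch_type=tensor.epoch_type,
        channel_names=tensor.channel_names,
        patient_id=tensor.patient_id,
        recording_id=tensor.recording_id,
        window_tags=["post"] * len(post_idx),
    )


def tensor_to_long(tensor: FeatureTensor):
    """Long-format table: patient, recording, epoch_type, channel,
    window_index, feature_name, value."""
    import pandas as pd

    c, w, f = tensor.values.shape
    ch = np.repeat(tensor.channel_names, w * f)
    wi = np.tile(np.repeat(np.arange(w), f), c)
    fn = np.tile(tensor.registry.names, c * w)
    return pd.DataFrame(
        {
            "patient": tensor.patient_id,
            "recording": tensor.recording_id,
            "epoch_type": tensor.epoch_type,
            "channel": ch,
            "window_index": wi,
            "feature_name": fn,
            "value": tensor.values.reshape(-1),
        }
    )


__all__ = [
    "BANDS_HZ",
    "NETWORK_BANDS_HZ",
    "MOMENT_NAMES",
    "COMPLEXITY_NAMES",
    "FREQUENCY_NAMES",
    "NETWORK_NAMES",
    "FeatureDescriptor",
    "FeatureRegistry",
    "FeatureTensor",
    "default_registry",
    "moment_features",
    "hjorth",
    "approximate_entropy",
    "sample_entropy",
    "permutation_entropy",
    "lempel_ziv",
    "higuchi_fd",
    "katz_fd",
    "hurst_dfa",
    "zero_crossing_rate",
    "autocorr_lag1",
    "complexity_rest",
    "complexity_features",
    "frequency_features",
    "network_features",
    "pairwise_msc",
    "extract_all",
    "resample_interictal_tensor",
    "normalize_ictal_tensor",
    "tensor_to_long",
]
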