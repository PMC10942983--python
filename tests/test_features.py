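"""Feature battery: closed-form cases, brute-force oracles and invariances."""

import math

import numpy as np
import pytest

from ezloc.features import (
    FeatureRegistry,
    approximate_entropy,
    autocorr_lag1,
    complexity_features,
    default_registry,
    extract_all,
    frequency_features,
    higuchi_fd,
    hjorth,
    katz_fd,
    lempel_ziv,
    moment_features,
    network_features,
    normalize_ictal_tensor,
    pairwise_msc,
    permutation_entropy,
    resample_interictal_tensor,
    sample_entropy,
    zero_crossing_rate,
)
from ezloc.features import _lz76_count_py
from ezloc.io_preprocess import Recording, segment_windows

RNG = np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation paths)
# ---------------------------------------------------------------------------


def apen_oracle(x, m=2, r=None):
    x = np.asarray(x, float)
    n = len(x)
    if r is None:
        r = 0.2 * np.std(x)

    def phi(mm):
        templ = [x[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for a in templ:
            count = sum(1 for b in templ if np.max(np.abs(a - b)) <= r)
            total += math.log(count / len(templ))
        return total / len(templ)

    return phi(m) - phi(m + 1)


def sampen_oracle(x, m=2, r=None):
    x = np.asarray(x, float)
    n = len(x)
    if r is None:
        r = 0.2 * np.std(x)

    def count(mm):
        templ = [x[i : i + mm] for i in range(n - m)]
        c = 0
        for i in range(len(templ)):
            for j in range(i + 1, len(templ)):
                if np.max(np.abs(templ[i] - templ[j])) <= r:
                    c += 1
        return c

    a, b = count(m + 1), count(m)
    return -math.log(a / b) if a and b else float("nan")


def lz76_oracle(bits):
    """Exhaustive-history phrase count by direct substring search."""
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    i, c = 0, 0
    while i < n:
        k = 1
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        c += 1
        i += min(k, n - i)
    return c


def katz_oracle(x):
    x = np.asarray(x, float)
    length = sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))
    d = max(abs(v - x[0]) for v in x)
    n = len(x) - 1
    return math.log10(n) / (math.log10(n) + math.log10(d / length))


# ---------------------------------------------------------------------------
# Moment features
# ---------------------------------------------------------------------------


def test_constant_window_moments():
    out = moment_features(np.full(512, 5.0))
    assert out["mean"] == 5 and out["median"] == 5 and out["variance"] == 0
    assert np.isnan(out["skewness"]) and np.isnan(out["kurtosis"])


def test_arithmetic_sequence_moments_match_brute_force():
    x = np.arange(1, 513, dtype=float)
    out = moment_features(x)
    assert out["mean"] == pytest.approx(256.5)
    # brute-force n-1 variance of 1..512
    expected_var = np.sum((x - x.mean()) ** 2) / 511
    assert out["variance"] == pytest.approx(expected_var)
    assert out["skewness"] == pytest.approx(0.0, abs=1e-12)


def test_gaussian_kurtosis_near_three():
    kurts = [moment_features(RNG.standard_normal(512))["kurtosis"]
             for _ in range(150)]
    assert np.mean(kurts) == pytest.approx(3.0, abs=0.1)


# ---------------------------------------------------------------------------
# Hjorth parameters
# ---------------------------------------------------------------------------


def test_hjorth_white_noise_mobility():
    mobs = [hjorth(RNG.standard_normal(512))[0] for _ in range(200)]
    assert np.mean(mobs) == pytest.approx(np.sqrt(2), abs=0.02)


def test_hjorth_sinusoid_mobility_closed_form():
    f, fs = 8.0, 256.0
    t = np.arange(512) / fs
    mob, _ = hjorth(np.sin(2 * np.pi * f * t))
    assert mob == pytest.approx(2 * np.sin(np.pi * f / fs), rel=1e-2)


def test_hjorth_scale_invariance():
    x = RNG.standard_normal(512)
    for k in (0.1, 3.0, -7.0):
        assert hjorth(k * x)[0] == pytest.approx(hjorth(x)[0], rel=1e-12)


# ---------------------------------------------------------------------------
# Entropies, LZ, fractal dimensions vs oracles
# ---------------------------------------------------------------------------


def test_apen_constant_is_zero():
    assert approximate_entropy(np.full(512, 2.0)) == 0.0


def test_apen_periodic_near_zero_and_matches_oracle():
    x = np.array([1.0, 2.0] * 16)
    assert approximate_entropy(x) == pytest.approx(apen_oracle(x), abs=1e-12)
    assert approximate_entropy(x) == pytest.approx(0.0, abs=0.01)


@pytest.mark.parametrize("n", [20, 30, 45, 64])
def test_entropy_and_geometry_oracles_exact(n):
    """ApEn, SampEn, LZ76 and Katz FD match brute force on short inputs."""
    for seed in range(3):
        x = np.random.default_rng(seed + n).standard_normal(n)
        assert approximate_entropy(x) == pytest.approx(apen_oracle(x), abs=1e-12)
        s_mine, s_ref = sample_entropy(x), sampen_oracle(x)
        assert (np.isnan(s_mine) and np.isnan(s_ref)) or s_mine == pytest.approx(
            s_ref, abs=1e-12
        )
        bits = (x > np.median(x)).astype(np.uint8)
        assert _lz76_count_py(bits) == lz76_oracle(bits)
        assert katz_fd(x) == pytest.approx(katz_oracle(x), abs=1e-12)


def test_katz_straight_line_is_one():
    assert katz_fd(2.5 * np.arange(512) + 1) == pytest.approx(1.0)


def test_higuchi_white_noise_near_two():
    vals = [higuchi_fd(RNG.standard_normal(512)) for _ in range(60)]
    assert np.mean(vals) == pytest.approx(2.0, abs=0.1)


def test_zero_crossing_alternating_is_one():
    assert zero_crossing_rate(np.array([1.0, -1.0] * 256)) == 1.0


def test_permutation_entropy_extremes():
    assert permutation_entropy(np.arange(512.0)) == pytest.approx(0.0, abs=1e-12)
    vals = [permutation_entropy(RNG.standard_normal(512)) for _ in range(20)]
    assert np.mean(vals) > 0.95  # white noise ~ uniform ordinal patterns


def test_degenerate_window_complexity_policy():
    out = complexity_features(np.zeros(512))
    assert np.isnan(out["higuchi_fd"]) and np.isnan(out["katz_fd"])
    assert out["permutation_entropy"] == 0.0
    assert out["zero_crossing_rate"] == 0.0
    assert out["approximate_entropy"] == 0.0


# ---------------------------------------------------------------------------
# Frequency features
# ---------------------------------------------------------------------------


def test_pure_tone_lands_in_beta_band():
    t = np.arange(512) / 256.0
    out = frequency_features(np.sin(2 * np.pi * 20 * t))
    assert out["power_beta"] / out["power_total"] >= 0.95
    assert out["median_frequency"] == pytest.approx(20.0, abs=0.5)
    assert out["mean_frequency"] == pytest.approx(20.0, abs=1.0)


def test_white_noise_spectral_entropy_near_one():
    vals = [frequency_features(RNG.standard_normal(512))["spectral_entropy"]
            for _ in range(60)]
    assert np.mean(vals) == pytest.approx(1.0, abs=0.05)


def test_equal_power_tones_energy_ratio_unity():
    t = np.arange(512) / 256.0
    x = np.sin(2 * np.pi * 2 * t) + np.sin(2 * np.pi * 40 * t)
    assert frequency_features(x)["energy_ratio"] == pytest.approx(1.0, abs=0.05)


def test_zero_window_frequency_policy():
    out = frequency_features(np.zeros(512))
    assert out["power_total"] == 0.0
    assert np.isnan(out["median_frequency"]) and np.isnan(out["spectral_entropy"])


def test_amplitude_scaling_behaviour():
    """Variance and band powers scale by k^2; shape descriptors are invariant."""
    x = RNG.standard_normal(512)
    k = 3.0
    base_m, scaled_m = moment_features(x), moment_features(k * x)
    assert scaled_m["variance"] == pytest.approx(k**2 * base_m["variance"])
    base_f, scaled_f = frequency_features(x), frequency_features(k * x)
    assert scaled_f["power_beta"] == pytest.approx(k**2 * base_f["power_beta"])
    for name in ("mean_frequency", "median_frequency", "energy_ratio",
                 "spectral_entropy"):
        assert scaled_f[name] == pytest.approx(base_f[name], rel=1e-9)
    base_c, scaled_c = complexity_features(x), complexity_features(k * x)
    for name in ("hjorth_mobility", "approximate_entropy", "sample_entropy",
                 "higuchi_fd", "katz_fd", "zero_crossing_rate",
                 "permutation_entropy", "lempel_ziv", "autocorr_lag1"):
        assert scaled_c[name] == pytest.approx(base_c[name], rel=1e-9)


def test_powers_and_msc_nonnegative():
    x = RNG.standard_normal((4, 512))
    for ch in x:
        out = frequency_features(ch)
        assert all(out[f] >= 0 for f in out if f.startswith("power_"))
        assert out["spectral_entropy"] >= 0
    _, msc = pairwise_msc(x)
    assert np.nanmin(msc) >= 0 and np.nanmax(msc) <= 1 + 1e-9


# ---------------------------------------------------------------------------
# Network features
# ---------------------------------------------------------------------------


def test_identical_channels_fully_coherent():
    x = RNG.standard_normal(512)
    out = network_features(np.vstack([x, x]))
    for band in ("delta", "theta", "alpha", "beta", "gamma"):
        assert out[f"coherence_{band}"][0] == pytest.approx(1.0, abs=1e-9)
    assert out["correlation_strength"][0] == pytest.approx(1.0, abs=1e-12)


def test_independent_channels_low_gamma_coherence():
    vals = [network_features(RNG.standard_normal((2, 512)))["coherence_gamma"][0]
            for _ in range(60)]
    # 7-segment estimator bias ~ 1/7 under independence
    assert np.mean(vals) < 0.35


def test_duplicate_channel_outranks_independent_one():
    x = RNG.standard_normal(512)
    z = RNG.standard_normal(512)
    out = network_features(np.vstack([x, x, z]))
    assert out["correlation_strength"][2] < out["correlation_strength"][0]


def test_single_channel_network_is_missing():
    with pytest.warns(UserWarning):
        out = network_features(RNG.standard_normal((1, 512)))
    assert all(np.isnan(v).all() for v in out.values())


# ---------------------------------------------------------------------------
# Registry and tensor extraction
# ---------------------------------------------------------------------------


def test_default_registry_composition():
    reg = default_registry()
    assert len(reg) == 34
    from collections import Counter

    counts = Counter(reg.categories)
    assert counts == {"moment": 5, "complexity": 11, "frequency": 12, "network": 6}
    for required in ("mean", "median", "variance", "skewness", "kurtosis",
                     "hjorth_mobility", "approximate_entropy", "higuchi_fd",
                     "katz_fd", "energy_ratio", "power_delta", "power_theta",
                     "power_beta", "mean_frequency", "median_frequency",
                     "coherence_beta", "coherence_gamma", "correlation_strength"):
        assert required in reg.names


def make_recording(n_channels, duration_s, epoch_type="interictal", onset_s=None,
                   seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration_s * 256)
    return Recording(
        signal=rng.standard_normal((n_channels, n)),
        rate_hz=256.0,
        epoch_type=epoch_type,
        channel_names=[f"ch{i}" for i in range(n_channels)],
        patient_id="p0",
        recording_id="r0",
        onset_sample=None if onset_s is None else int(onset_s * 256),
    )


def test_extract_reduced_registry_and_determinism():
    rec = make_recording(3, 8)
    reg = default_registry().subset(["mean", "median", "variance", "skewness",
                                     "kurtosis"])
    t1 = extract_all(rec, reg)
    t2 = extract_all(rec, reg)
    assert t1.values.shape == (3, 4, 5)
    assert np.array_equal(t1.values, t2.values)


def test_interictal_tensor_resampling_and_ictal_normalisation():
    rec = make_recording(2, 60)
    reg = default_registry().subset(["mean", "variance"])
    tensor = extract_all(rec, reg)
    assert tensor.values.shape == (2, 30, 2)
    down = resample_interictal_tensor(tensor)
    assert down.values.shape == (2, 28, 2)

    ictal = make_recording(2, 58, epoch_type="ictal", onset_s=30, seed=3)
    itensor = extract_all(ictal, reg)
    assert itensor.values.shape == (2, 28, 2)
    norm = normalize_ictal_tensor(itensor)
    assert norm.values.shape == (2, 14, 2)
    # spot-check one (channel, feature) against the formula
    pre_idx = [i for i, t in enumerate(itensor.window_tags) if t == "pre"]
    post_idx = [i for i, t in enumerate(itensor.window_tags) if t == "post"]
    pre = itensor.values[0, pre_idx, 1]
    post = itensor.values[0, post_idx, 1]
    expected = (post - pre.mean()) / (post.mean() + pre.mean())
    assert np.allclose(norm.values[0, :, 1], expected)


def test_registry_rejects_duplicate_names():
    reg = default_registry()
    with pytest.raises(ValueError):
        FeatureRegistry(reg.descriptors + [reg.descriptors[0]])
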