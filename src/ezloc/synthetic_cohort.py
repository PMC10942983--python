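"""Synthetic iEEG cohorts with planted epileptogenic structure.

The generator emulates the statistical structure the localisation
analysis assumes, so every downstream stage is testable without clinical
data:

* per-patient multichannel recordings at native rates of 256/512/1024 Hz
  (varied across patients to exercise the resampling stage);
* a labelled minority of *epileptogenic* (EZ) channels — 12.87% of
  contacts by default — carrying elevated amplitude, interictal spikes,
  gamma-band bursts and, through a shared gamma source, elevated
  within-EZ coherence;
* two interictal epochs (300 s) and 1–5 ictal epochs (58 s, onset at
  +30 s) per patient; ictal epochs show post-onset low-voltage fast
  activity followed by a growing rhythmic (default 3 Hz) spike-wave
  component on EZ channels.

Background activity is Gaussian 1/f^alpha noise produced by spectral
shaping — the simplest model with realistic spectra for band-power
features; spikes are biphasic 70-ms templates at Poisson times.  No
biophysical neural-mass modelling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import ICTAL, INTERICTAL, Recording, write_recording

NATIVE_RATES_HZ = (256, 512, 1024)


class ConfigurationError(ValueError):
    """A cohort or effect specification field is out of range."""


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass
class EffectSpec:
    """Planted differences between EZ and non-EZ channels.

    Amplitude gains are expressed relative to the unit-SD background;
    ``variance_gain`` multiplies EZ channel amplitude (a gain of 4 raises
    variance ~16x).  ``shared_gamma_mix`` is the fraction of each EZ
    channel's gamma component drawn from a single common source; it is
    what drives within-EZ coherence.
    """

    variance_gain: float = 2.0
    spike_rate_hz: float = 0.5
    spike_amp: float = 6.0
    gamma_burst_power: float = 0.5
    shared_gamma_mix: float = 0.5
    ictal_lvfa_gain: float = 1.5
    ictal_rhythmic_freq_hz: float = 3.0
    ictal_rhythmic_amp: float = 3.0
    noise_exponent: float = 1.0
    common_noise_mix: float = 0.05

    def validate(self) -> None:
        for name in (
            "variance_gain",
            "spike_rate_hz",
            "spike_amp",
            "gamma_burst_power",
            "ictal_lvfa_gain",
            "ictal_rhythmic_freq_hz",
            "ictal_rhythmic_amp",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"EffectSpec.{name} must be >= 0")
        if self.variance_gain < 1:
            raise ConfigurationError("EffectSpec.variance_gain must be >= 1")
        if not 0 <= self.shared_gamma_mix <= 1:
            raise ConfigurationError("EffectSpec.shared_gamma_mix must be in [0, 1]")
        if not 0 <= self.common_noise_mix <= 1:
            raise ConfigurationError("EffectSpec.common_noise_mix must be in [0, 1]")


@dataclass
class CohortSpec:
    """Size, composition and effect sizes of a synthetic cohort.

    Defaults mirror the clinical cohort the analysis is designed for:
    ~106 contacts per patient (sd 38), 12.87% epileptogenic, 2 interictal
    recordings of 300 s and 1–5 ictal recordings of 58 s per patient,
    native rates spanning 256–1024 Hz.  ``seed`` fully determines every
    signal and label.
    """

    n_patients: int = 6
    n_channels_mean: float = 106.0
    n_channels_sd: float = 38.0
    ez_fraction: float = 0.1287
    native_rate_hz: int | None = None  # None: cycle through 256/512/1024
    n_interictal_per_patient: int = 2
    n_ictal_min: int = 1
    n_ictal_max: int = 5
    interictal_duration_s: float = 300.0
    ictal_duration_s: float = 58.0
    ictal_onset_s: float = 30.0
    effects: EffectSpec = field(default_factory=EffectSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("CohortSpec.n_patients must be >= 1")
        if not 0 < self.ez_fraction < 1:
            raise ConfigurationError("CohortSpec.ez_fraction must be in (0, 1)")
        if self.n_channels_mean < 2:
            raise ConfigurationError("CohortSpec.n_channels_mean must be >= 2")
        if self.n_channels_sd < 0:
            raise ConfigurationError("CohortSpec.n_channels_sd must be >= 0")
        if self.native_rate_hz is not None and self.native_rate_hz not in NATIVE_RATES_HZ:
            raise ConfigurationError(
                f"CohortSpec.native_rate_hz must be one of {NATIVE_RATES_HZ}"
            )
        if self.n_interictal_per_patient < 1:
            raise ConfigurationError("CohortSpec.n_interictal_per_patient must be >= 1")
        if not 1 <= self.n_ictal_min <= self.n_ictal_max:
            raise ConfigurationError("CohortSpec requires 1 <= n_ictal_min <= n_ictal_max")
        if self.interictal_duration_s <= 0 or self.ictal_duration_s <= 0:
            raise ConfigurationError("CohortSpec durations must be positive")
        if not 0 < self.ictal_onset_s < self.ictal_duration_s:
            raise ConfigurationError("CohortSpec.ictal_onset_s must lie inside the epoch")
        self.effects.validate()


@dataclass
class GroundTruth:
    """Channel labels for one synthetic patient.

    ``epileptogenic`` and ``bad`` align one-to-one with the patient's
    signal rows.  ``outcome`` is an Engel-style surgical-outcome label;
    it is cosmetic metadata only and enters no computation here.
    """

    patient_id: str
    channel_names: list[str]
    epileptogenic: np.ndarray
    bad: np.ndarray
    outcome: str = "Engel I"

    def __post_init__(self) -> None:
        self.epileptogenic = np.asarray(self.epileptogenic, dtype=bool)
        self.bad = np.asarray(self.bad, dtype=bool)
        n = len(self.channel_names)
        if self.epileptogenic.shape != (n,) or self.bad.shape != (n,):
            raise ConfigurationError(
                f"{self.patient_id}: label arrays must align with channel names"
            )


@dataclass
class PatientData:
    patient_id: str
    recordings: list[Recording]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------


def one_over_f_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    rate_hz: float,
    exponent: float = 1.0,
) -> np.ndarray:
    """Unit-SD Gaussian noise with a 1/f^alpha amplitude spectrum (per channel)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC drift
    spectrum = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * shape
    sig = np.fft.irfft(spectrum, n=n_samples, axis=1)
    sd = sig.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return sig / sd


def band_limited_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    rate_hz: float,
    band: tuple[float, float],
) -> np.ndarray:
    """Unit-SD Gaussian noise confined to ``band`` Hz (spectral masking)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    mask = (freqs >= band[0]) & (freqs < band[1])
    spectrum = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * mask
    sig = np.fft.irfft(spectrum, n=n_samples, axis=1)
    sd = sig.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return sig / sd


def spike_template(rate_hz: float, duration_s: float = 0.070) -> np.ndarray:
    """Biphasic interictal-spike template: sharp positive lobe, slower negative."""
    n = max(int(round(duration_s * rate_hz)), 3)
    t = np.linspace(0, 1, n)
    sharp = np.exp(-(((t - 0.25) / 0.10) ** 2))
    slow = -0.6 * np.exp(-(((t - 0.60) / 0.22) ** 2))
    w = sharp + slow
    return w / np.abs(w).max()


def _add_spikes(
    rng: np.random.Generator,
    sig: np.ndarray,
    channel_idx: np.ndarray,
    rate_hz: float,
    spike_rate_hz: float,
    spike_amp: float,
    sample_range: tuple[int, int] | None = None,
) -> None:
    """Superimpose Poisson-timed spike templates on selected channels, in place."""
    if spike_rate_hz <= 0 or spike_amp <= 0 or channel_idx.size == 0:
        return
    lo, hi = sample_range if sample_range is not None else (0, sig.shape[1])
    template = spike_template(rate_hz) * spike_amp
    span = hi - lo
    for ch in channel_idx:
        n_spikes = rng.poisson(spike_rate_hz * span / rate_hz)
        starts = rng.integers(lo, max(hi - template.size, lo + 1), size=n_spikes)
        jitter = rng.uniform(0.7, 1.3, size=n_spikes)
        for s, j in zip(starts, jitter):
            seg = sig[ch, s : s + template.size]
            seg += j * template[: seg.size]


def _gamma_component(
    rng: np.random.Generator,
    n_ez: int,
    n_samples: int,
    rate_hz: float,
    effects: EffectSpec,
) -> np.ndarray:
    """Burst-modulated 30-90 Hz activity for EZ channels.

    Each EZ channel mixes a private and a single shared gamma source
    (weight ``shared_gamma_mix``); the shared source is what makes EZ
    channel pairs coherent in the gamma band.  A slow non-negative
    envelope makes the activity arrive in bursts.
    """
    if n_ez == 0 or effects.gamma_burst_power <= 0:
        return np.zeros((0, n_samples))
    private = band_limited_noise(rng, n_ez, n_samples, rate_hz, (30.0, 90.0))
    shared = band_limited_noise(rng, 1, n_samples, rate_hz, (30.0, 90.0))
    mix = effects.shared_gamma_mix
    combined = np.sqrt(1.0 - mix) * private + np.sqrt(mix) * shared
    envelope = band_limited_noise(rng, n_ez, n_samples, rate_hz, (0.0, 0.5))
    envelope = 1.0 + 0.5 * np.tanh(envelope)  # smooth, positive, burst-like
    sig = combined * envelope
    sig /= sig.std(axis=1, keepdims=True)
    return np.sqrt(effects.gamma_burst_power) * sig


# ---------------------------------------------------------------------------
# Recording generators
# ---------------------------------------------------------------------------


def _background(
    rng: np.random.Generator,
    n_channels: int,
    ez_mask: np.ndarray,
    n_samples: int,
    rate_hz: float,
    effects: EffectSpec,
) -> np.ndarray:
    """Common background for both epoch types: 1/f noise + EZ effects."""
    sig = one_over_f_noise(rng, n_channels, n_samples, rate_hz, effects.noise_exponent)
    if effects.common_noise_mix > 0:
        common = one_over_f_noise(rng, 1, n_samples, rate_hz, effects.noise_exponent)
        sig = (
            np.sqrt(1 - effects.common_noise_mix) * sig
            + np.sqrt(effects.common_noise_mix) * common
        )
    ez_idx = np.flatnonzero(ez_mask)
    sig[ez_idx] *= effects.variance_gain
    gamma = _gamma_component(rng, ez_idx.size, n_samples, rate_hz, effects)
    if gamma.size:
        sig[ez_idx] += effects.variance_gain * gamma
    _add_spikes(
        rng,
        sig,
        ez_idx,
        rate_hz,
        effects.spike_rate_hz,
        effects.spike_amp * effects.variance_gain,
    )
    return sig


def generate_interictal_recording(
    rng: np.random.Generator,
    patient_id: str,
    recording_id: str,
    channel_names: list[str],
    ez_mask: np.ndarray,
    rate_hz: float,
    duration_s: float,
    effects: EffectSpec,
) -> Recording:
    n_samples = int(round(duration_s * rate_hz))
    sig = _background(rng, len(channel_names), ez_mask, n_samples, rate_hz, effects)
    return Recording(
        signal=sig,
        rate_hz=rate_hz,
        epoch_type=INTERICTAL,
        channel_names=list(channel_names),
        patient_id=patient_id,
        recording_id=recording_id,
    )


def generate_ictal_recording(
    rng: np.random.Generator,
    patient_id: str,
    recording_id: str,
    channel_names: list[str],
    ez_mask: np.ndarray,
    rate_hz: float,
    duration_s: float,
    onset_s: float,
    effects: EffectSpec,
) -> Recording:
    """One seizure epoch: interictal-like before onset, EZ dynamics after.

    Post-onset EZ channels first show low-voltage fast activity (amplitude
    suppression plus 60–120 Hz noise, ~first 8 s) and then a linearly
    growing rhythmic spike-wave component at ``ictal_rhythmic_freq_hz``.
    With both ictal gains at zero the post-onset segment is statistically
    identical to the pre-onset background.
    """
    n_samples = int(round(duration_s * rate_hz))
    onset = int(round(onset_s * rate_hz))
    sig = _background(rng, len(channel_names), ez_mask, n_samples, rate_hz, effects)
    ez_idx = np.flatnonzero(ez_mask)
    post = n_samples - onset
    t_post = np.arange(post) / rate_hz

    if ez_idx.size and effects.ictal_lvfa_gain > 0:
        lvfa_span = min(int(round(8.0 * rate_hz)), post)
        suppress = 1.0 / (1.0 + effects.ictal_lvfa_gain)
        sig[ez_idx, onset : onset + lvfa_span] *= suppress
        fast = band_limited_noise(rng, ez_idx.size, lvfa_span, rate_hz, (60.0, 120.0))
        sig[ez_idx, onset : onset + lvfa_span] += (
            effects.ictal_lvfa_gain * effects.variance_gain * fast
        )

    if ez_idx.size and effects.ictal_rhythmic_amp > 0:
        ramp_start = 8.0 if effects.ictal_lvfa_gain > 0 else 0.0
        ramp = np.clip((t_post - ramp_start) / max(t_post[-1] - ramp_start, 1e-9), 0, 1)
        f = effects.ictal_rhythmic_freq_hz
        phases = rng.uniform(0, 2 * np.pi, size=ez_idx.size)
        for k, ch in enumerate(ez_idx):
            wave = np.sin(2 * np.pi * f * t_post + phases[k]) + 0.4 * np.sin(
                4 * np.pi * f * t_post + 2 * phases[k]
            )
            sig[ch, onset:] += (
                effects.ictal_rhythmic_amp * effects.variance_gain * ramp * wave
            )

    return Recording(
        signal=sig,
        rate_hz=rate_hz,
        epoch_type=ICTAL,
        channel_names=list(channel_names),
        patient_id=patient_id,
        recording_id=recording_id,
        onset_sample=onset,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_OUTCOMES = ("Engel I", "Engel II", "Engel III", "Engel IV")


def generate_patient(spec: CohortSpec, patient_index: int) -> PatientData:
    """Generate one patient deterministically from the cohort seed."""
    spec.validate()
    seed_seq = np.random.SeedSequence(entropy=spec.seed, spawn_key=(patient_index,))
    rng = np.random.default_rng(seed_seq)
    pid = f"sub-{patient_index + 1:02d}"

    n_ch = int(round(rng.normal(spec.n_channels_mean, spec.n_channels_sd)))
    n_ch = max(n_ch, 16)
    n_ez = int(round(spec.ez_fraction * n_ch))
    n_ez = min(max(n_ez, 1), n_ch - 1)
    ez_mask = np.zeros(n_ch, dtype=bool)
    ez_mask[rng.choice(n_ch, size=n_ez, replace=False)] = True
    names = [f"{pid}-ch{i + 1:03d}" for i in range(n_ch)]

    rate = spec.native_rate_hz or NATIVE_RATES_HZ[patient_index % len(NATIVE_RATES_HZ)]

    recordings: list[Recording] = []
    for i in range(spec.n_interictal_per_patient):
        recordings.append(
            generate_interictal_recording(
                rng,
                pid,
                f"interictal-{i + 1:02d}",
                names,
                ez_mask,
                float(rate),
                spec.interictal_duration_s,
                spec.effects,
            )
        )
    n_ictal = int(rng.integers(spec.n_ictal_min, spec.n_ictal_max + 1))
    for i in range(n_ictal):
        recordings.append(
            generate_ictal_recording(
                rng,
                pid,
                f"ictal-{i + 1:02d}",
                names,
                ez_mask,
                float(rate),
                spec.ictal_duration_s,
                spec.ictal_onset_s,
                spec.effects,
            )
        )

    truth = GroundTruth(
        patient_id=pid,
        channel_names=names,
        epileptogenic=ez_mask,
        bad=np.zeros(n_ch, dtype=bool),
        outcome=_OUTCOMES[int(rng.integers(len(_OUTCOMES)))],
    )
    return PatientData(pid, recordings, truth)


def generate_cohort(spec: CohortSpec) -> list[PatientData]:
    """Generate the full cohort; identical spec + seed → identical output."""
    spec.validate()
    return [generate_patient(spec, i) for i in range(spec.n_patients)]


# ---------------------------------------------------------------------------
# On-disk cohort layout
# ---------------------------------------------------------------------------


def write_cohort(
    cohort: list[PatientData], out_dir, container: str = "bin"
) -> None:
    """Write the cohort directory read by io_preprocess.load_recording."""
    from pathlib import Path

    out_dir = Path(out_dir)
    for patient in cohort:
        pdir = out_dir / patient.patient_id
        pdir.mkdir(parents=True, exist_ok=True)
        truth = patient.ground_truth
        with open(pdir / "channels.tsv", "w") as fh:
            fh.write("name\tstatus\tepileptogenic\n")
            for name, ez, bad in zip(
                truth.channel_names, truth.epileptogenic, truth.bad
            ):
                status = "bad" if bad else "good"
                fh.write(f"{name}\t{status}\t{'true' if ez else 'false'}\n")
        for rec in patient.recordings:
            stem = pdir / f"{patient.patient_id}_{rec.recording_id}_ieeg"
            write_recording(rec, stem, container=container)
            if rec.epoch_type == ICTAL:
                events = pdir / f"{patient.patient_id}_{rec.recording_id}_events.tsv"
                with open(events, "w") as fh:
                    fh.write("onset_sample\n")
                    fh.write(f"{rec.onset_sample}\n")


__all__ = [
    "NATIVE_RATES_HZ",
    "ConfigurationError",
    "EffectSpec",
    "CohortSpec",
    "GroundTruth",
    "PatientData",
    "generate_patient",
    "generate_cohort",
    "generate_interictal_recording",
    "generate_ictal_recording",
    "write_cohort",
    "one_over_f_noise",
    "band_limited_noise",
    "spike_template",
]
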