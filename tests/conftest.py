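"""Shared fixtures: small synthetic patients/cohorts and toy observation tables.

Signal-level fixtures are session-scoped because the feature battery is
the expensive stage; classifier-level property tests use directly
constructed observation tables instead of signals wherever the property
under test does not involve signal processing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ezloc.cli import extract_patient_observations
from ezloc.localization import META_COLS
from ezloc.synthetic_cohort import (
    CohortSpec,
    EffectSpec,
    PatientData,
    generate_patient,
)

STRONG_EFFECTS = EffectSpec(
    variance_gain=4.0,
    spike_rate_hz=1.0,
    spike_amp=6.0,
    gamma_burst_power=0.8,
    shared_gamma_mix=0.5,
)

NULL_EFFECTS = EffectSpec(
    variance_gain=1.0,
    spike_rate_hz=0.0,
    spike_amp=0.0,
    gamma_burst_power=0.0,
    shared_gamma_mix=0.0,
    ictal_lvfa_gain=0.0,
    ictal_rhythmic_amp=0.0,
)


def small_spec(n_patients=1, effects=STRONG_EFFECTS, seed=11, n_channels=24,
               interictal_s=60.0, n_ictal=(1, 2)):
    return CohortSpec(
        n_patients=n_patients,
        n_channels_mean=n_channels,
        n_channels_sd=0,
        interictal_duration_s=interictal_s,
        n_ictal_min=n_ictal[0],
        n_ictal_max=n_ictal[1],
        effects=effects,
        seed=seed,
    )


@pytest.fixture(scope="session")
def strong_patient():
    return generate_patient(small_spec(), 0)


@pytest.fixture(scope="session")
def strong_patient_table(strong_patient):
    return extract_patient_observations(strong_patient)


@pytest.fixture(scope="session")
def calibration_table():
    """Study-scale patient (106 contacts) for chance calibration.

    The permutation null only centres within +/-0.02 of 0.5 at realistic
    contact counts: with few contacts, sampling shuffled labels without
    replacement anti-correlates a held-out contact's label with its
    neighbours' training labels.
    """
    spec = small_spec(effects=EffectSpec(), seed=71, n_channels=106,
                      n_ictal=(1, 1))
    patient = generate_patient(spec, 0)
    interictal_only = PatientData(
        patient.patient_id,
        [r for r in patient.recordings if r.epoch_type == "interictal"],
        patient.ground_truth,
    )
    return extract_patient_observations(interictal_only)


@pytest.fixture(scope="session")
def null_patient_table():
    patient = generate_patient(
        small_spec(effects=NULL_EFFECTS, seed=21, n_channels=16), 0
    )
    return extract_patient_observations(patient)


@pytest.fixture(scope="session")
def shared_cohort_tables():
    """Four patients with identical planted-effect structure (for LOPO)."""
    spec = small_spec(n_patients=4, seed=31, n_channels=16, n_ictal=(1, 1))
    tables = [
        extract_patient_observations(generate_patient(spec, i)) for i in range(4)
    ]
    return pd.concat(tables, ignore_index=True)


def make_toy_table(
    n_patients: int = 1,
    n_contacts: int = 16,
    n_ez: int = 4,
    rows_per_contact: int = 20,
    informative: dict[str, float] | None = None,
    n_features: int = 10,
    noise_sd: float = 1.0,
    seed: int = 0,
    epoch_types: tuple[str, ...] = ("interictal",),
    flip_effect_per_patient: bool = False,
) -> pd.DataFrame:
    """Gaussian observation table with chosen informative feature shifts.

    ``informative`` maps feature name (f0..fN) to the mean shift added to
    epileptogenic-contact rows.  With ``flip_effect_per_patient`` each
    patient's effect is relocated to a different feature column and its
    sign alternated, so no epileptogenic signature is shared across
    patients (a cross-patient null that bagged trees cannot exploit
    through symmetric splits).
    """
    rng = np.random.default_rng(seed)
    informative = informative or {}
    rows = []
    for p in range(n_patients):
        sign = (-1) ** p if flip_effect_per_patient else 1
        for c in range(n_contacts):
            label = int(c < n_ez)
            for epoch in epoch_types:
                for w in range(rows_per_contact):
                    feats = rng.normal(0, noise_sd, n_features)
                    if label:
                        for fname, shift in informative.items():
                            j = int(fname[1:])
                            if flip_effect_per_patient:
                                j = (j + p) % n_features
                            feats[j] += sign * shift
                    rows.append(
                        {
                            "patient": f"p{p}",
                            "contact": f"p{p}-c{c}",
                            "epoch_type": epoch,
                            "recording": "r0",
                            "window_index": w,
                            "label": label,
                            **{f"f{j}": feats[j] for j in range(n_features)},
                        }
                    )
    table = pd.DataFrame(rows)
    return table[META_COLS + [f"f{j}" for j in range(n_features)]]
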