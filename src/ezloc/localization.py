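"""Contact classification: within-patient, cross-time and cross-patient.

The unit of classification is the *contact* (electrode channel), each
contributing multiple observation rows (one per retained 2-s window:
28 x n_interictal_recordings interictal rows and 14 x n_ictal_recordings
normalised ictal rows).  Contacts are labelled epileptogenic or
non-epileptogenic from ground truth.

Three schemes quantify how separable the two classes are:

* **within-patient** — grouped, stratified 10-fold cross-validation
  inside one patient and epoch type; folds never split a contact's rows;
* **cross-time** — train on a patient's interictal rows, test on its
  ictal rows (or the reverse), probing whether epileptiform patterns
  generalise across time windows;
* **cross-patient** — leave-one-patient-out within an epoch type,
  probing generalisation across patients.

Because epileptogenic contacts are a small minority (~13%), every
classification run down-samples non-epileptogenic contacts to the
epileptogenic count and is repeated many times (default 1000) before
averaging.  Empirical chance levels come from contact-level label
shuffles with the full scheme re-run per shuffle.  The classifier is a
bagged decision-tree ensemble (50 trees, sqrt-feature subsampling per
split) scored by threshold-free AUC on ensemble vote fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold

from .features import FeatureTensor
from .io_preprocess import ICTAL, INTERICTAL
from .synthetic_cohort import GroundTruth

logger = logging.getLogger(__name__)

META_COLS = ["patient", "contact", "epoch_type", "recording", "window_index", "label"]

SCHEMES = (
    "within-interictal",
    "within-ictal",
    "interictal->ictal",
    "ictal->interictal",
    "cross-patient-interictal",
    "cross-patient-ictal",
)


@dataclass
class ClassifierConfig:
    """Ensemble and resampling settings.

    Defaults are the full-scale analysis settings (1000 balance repeats,
    1000 label shuffles); :meth:`desk` returns a reduced configuration
    for interactive runs and testing.
    """

    n_trees: int = 50
    balance_repeats: int = 1000
    chance_shuffles: int = 1000
    chance_balance_repeats: int = 3
    cv_folds: int = 10
    contribution_draws: int = 20
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0) -> "ClassifierConfig":
        return cls(balance_repeats=50, chance_shuffles=200, seed=seed)

    def validate(self) -> None:
        for name in (
            "n_trees",
            "balance_repeats",
            "chance_shuffles",
            "chance_balance_repeats",
            "cv_folds",
            "contribution_draws",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"ClassifierConfig.{name} must be >= 1")


@dataclass
class SchemeResult:
    """Outcome of one scheme evaluation.

    ``aucs`` holds the row-level AUC per balance repeat (or per test
    patient for cross-patient); ``contact_aucs`` the contact-level
    aggregation (mean ensemble vote per contact).  ``chance_aucs`` and
    ``contributions`` are filled by :func:`chance_distribution` and
    :func:`permutation_contribution`.
    """

    scheme: str
    aucs: np.ndarray
    contact_aucs: np.ndarray
    chance_aucs: np.ndarray | None = None
    contributions: pd.DataFrame | None = None
    per_patient: pd.DataFrame | None = None
    artifacts: list | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean(self.aucs))

    @property
    def chance_mean(self) -> float | None:
        return None if self.chance_aucs is None else float(np.nanmean(self.chance_aucs))

    def chance_percentile(self, q: float = 95.0) -> float | None:
        if self.chance_aucs is None:
            return None
        return float(np.nanpercentile(self.chance_aucs, q))


# ---------------------------------------------------------------------------
# Observation building
# ---------------------------------------------------------------------------


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


def build_observations(
    tensors: list[FeatureTensor],
    truth: GroundTruth,
    max_missing_fraction: float = 0.5,
) -> pd.DataFrame:
    """Flatten feature tensors into one row per (contact, retained window).

    Labels come from the ground-truth epileptogenic flags; a channel
    present in a tensor but absent from ground truth is an error.  Rows
    missing more than ``max_missing_fraction`` of their features are
    dropped (remaining NaNs are handled per model fit).
    """
    if not tensors:
        raise ValueError("no feature tensors supplied")
    flag = dict(zip(truth.channel_names, truth.epileptogenic))
    frames = []
    names = tensors[0].registry.names
    for tensor in tensors:
        if tensor.registry.names != names:
            raise ValueError("all tensors must share one feature registry")
        unknown = [ch for ch in tensor.channel_names if ch not in flag]
        if unknown:
            raise ValueError(
                f"channels missing from ground truth for {tensor.patient_id}: "
                f"{unknown[:5]}"
            )
        c, w, f = tensor.values.shape
        frame = pd.DataFrame(
            tensor.values.reshape(c * w, f), columns=names
        )
        frame.insert(0, "patient", tensor.patient_id)
        frame.insert(1, "contact", np.repeat(tensor.channel_names, w))
        frame.insert(2, "epoch_type", tensor.epoch_type)
        frame.insert(3, "recording", tensor.recording_id)
        frame.insert(4, "window_index", np.tile(np.arange(w), c))
        frame.insert(5, "label", np.repeat(
            [int(flag[ch]) for ch in tensor.channel_names], w
        ))
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    missing_frac = table[names].isna().mean(axis=1)
    n_dropped = int((missing_frac > max_missing_fraction).sum())
    if n_dropped:
        logger.warning("dropping %d rows missing >%.0f%% of features",
                       n_dropped, 100 * max_missing_fraction)
        table = table[missing_frac <= max_missing_fraction].reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# Fitting and scoring primitives
# ---------------------------------------------------------------------------


def _contact_labels(table: pd.DataFrame) -> pd.Series:
    """label per contact; raises if a contact carries mixed labels."""
    per = table.groupby("contact", sort=True)["label"].agg(["min", "max"])
    if (per["min"] != per["max"]).any():
        raise ValueError("labels must be constant within contact")
    return per["min"]


def _balanced_contact_sample(
    labels: pd.Series, rng: np.random.Generator, min_per_class: int = 2
) -> np.ndarray:
    """Down-sample the majority class to the minority class contact count."""
    pos = labels.index[labels == 1].to_numpy()
    neg = labels.index[labels == 0].to_numpy()
    if len(pos) < min_per_class or len(neg) < min_per_class:
        raise ValueError("need >=2 contacts per class for balanced classification")
    k = min(len(pos), len(neg))
    pos_sel = pos if len(pos) == k else rng.choice(pos, size=k, replace=False)
    neg_sel = neg if len(neg) == k else rng.choice(neg, size=k, replace=False)
    return np.concatenate([pos_sel, neg_sel])


def _complete_rows(frame: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    complete = frame.dropna(subset=cols)
    dropped = len(frame) - len(complete)
    if dropped:
        logger.debug("dropped %d incomplete rows before fit/score", dropped)
    return complete


def _fit(train: pd.DataFrame, cols: list[str], config: ClassifierConfig,
         seed: int) -> RandomForestClassifier:
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features="sqrt",
        random_state=int(seed % (2**32)),
        n_jobs=1,
    )
    model.fit(train[cols].to_numpy(), train["label"].to_numpy())
    return model


def _votes(model: RandomForestClassifier, test: pd.DataFrame,
           cols: list[str]) -> np.ndarray:
    proba = model.predict_proba(test[cols].to_numpy())
    if proba.shape[1] == 1:  # degenerate single-class training set
        return np.full(len(test), float(model.classes_[0]))
    return proba[:, list(model.classes_).index(1)]


def row_and_contact_auc(
    y: np.ndarray, votes: np.ndarray, contacts: np.ndarray
) -> tuple[float, float]:
    """Row-level AUC plus the contact-level AUC on per-contact mean votes."""
    if len(np.unique(y)) < 2:
        return np.nan, np.nan
    row_auc = float(roc_auc_score(y, votes))
    frame = pd.DataFrame({"y": y, "v": votes, "c": contacts})
    per = frame.groupby("c").agg(y=("y", "first"), v=("v", "mean"))
    contact_auc = (
        float(roc_auc_score(per["y"], per["v"]))
        if per["y"].nunique() == 2
        else np.nan
    )
    return row_auc, contact_auc


# ---------------------------------------------------------------------------
# Scheme: within-patient grouped cross-validation
# ---------------------------------------------------------------------------


def _within_single_repeat(
    table: pd.DataFrame,
    cols: list[str],
    config: ClassifierConfig,
    rng: np.random.Generator,
    keep_models: bool,
):
    labels = _contact_labels(table)
    selected = _balanced_contact_sample(labels, rng)
    sub = table[table["contact"].isin(selected)]
    sub = _complete_rows(sub, cols)
    contacts = sub["contact"].to_numpy()
    groups = pd.factorize(contacts)[0]
    n_contacts = len(np.unique(groups))
    n_folds = min(config.cv_folds, n_contacts)
    if n_folds < config.cv_folds:
        logger.debug("reducing CV folds to contact count (%d)", n_folds)
    splitter = StratifiedGroupKFold(
        n_splits=n_folds, shuffle=True,
        random_state=int(rng.integers(2**32)),
    )
    y_all = sub["label"].to_numpy()
    votes = np.full(len(sub), np.nan)
    fold_artifacts = []
    for train_idx, test_idx in splitter.split(sub[cols], y_all, groups):
        train = sub.iloc[train_idx]
        test = sub.iloc[test_idx]
        if train["label"].nunique() < 2 or len(test) == 0:
            continue
        # Re-balance the training contacts inside the fold: holding out a
        # contact leaves the remaining classes unequal, which would bias
        # the ensemble against the held-out class (and centre the chance
        # null below 0.5).
        fold_labels = _contact_labels(train)
        if (fold_labels == 1).sum() != (fold_labels == 0).sum():
            keep = _balanced_contact_sample(fold_labels, rng, min_per_class=1)
            train = train[train["contact"].isin(keep)]
        model = _fit(train, cols, config, rng.integers(2**31))
        votes[test_idx] = _votes(model, test, cols)
        if keep_models:
            fold_artifacts.append((model, test_idx))
    ok = ~np.isnan(votes)
    row_auc, contact_auc = row_and_contact_auc(y_all[ok], votes[ok], contacts[ok])
    artifact = None
    if keep_models:
        artifact = {"frame": sub, "models": fold_artifacts, "base_auc": row_auc}
    return row_auc, contact_auc, artifact


def within_patient(
    table: pd.DataFrame,
    config: ClassifierConfig,
    epoch_type: str,
    keep_models: bool = False,
) -> SchemeResult:
    """Grouped, stratified k-fold classification inside one patient.

    All rows of a contact stay in one fold; AUC is computed on the
    pooled out-of-fold votes (always well defined, unlike per-fold AUC
    with few contacts) and averaged over balance repeats.
    """
    config.validate()
    sub = table[table["epoch_type"] == epoch_type]
    if sub.empty:
        raise ValueError(f"no rows with epoch_type={epoch_type!r}")
    cols = feature_columns(table)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    aucs, contact_aucs, artifacts = [], [], []
    for _ in range(config.balance_repeats):
        row_auc, contact_auc, art = _within_single_repeat(
            sub, cols, config, rng, keep_models
        )
        aucs.append(row_auc)
        contact_aucs.append(contact_auc)
        if art is not None:
            artifacts.append(art)
    return SchemeResult(
        scheme=f"within-{epoch_type}",
        aucs=np.asarray(aucs),
        contact_aucs=np.asarray(contact_aucs),
        artifacts=artifacts or None,
    )


# ---------------------------------------------------------------------------
# Scheme: cross-time generalisation
# ---------------------------------------------------------------------------


def equalize_epoch_observations(
    table: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Equalise per-contact row counts between epoch types by subsampling.

    Used when the two generalisation directions are compared, so neither
    direction trains or tests on systematically more observations.
    """
    counts = table.groupby(["contact", "epoch_type"]).size().unstack(fill_value=0)
    keep_idx = []
    for contact, row in counts.iterrows():
        target = int(row[row > 0].min())
        for epoch in row.index:
            idx = table.index[
                (table["contact"] == contact) & (table["epoch_type"] == epoch)
            ].to_numpy()
            if len(idx) > target:
                idx = rng.choice(idx, size=target, replace=False)
            keep_idx.append(idx)
    return table.loc[np.sort(np.concatenate(keep_idx))]


def cross_time(
    table: pd.DataFrame,
    config: ClassifierConfig,
    direction: str = "interictal->ictal",
    equalize: bool = False,
    keep_models: bool = False,
) -> SchemeResult:
    """Train on one epoch type of a patient, test on the other.

    Balancing is applied to the training contacts; the test set keeps
    every contact of the test epoch.
    """
    config.validate()
    try:
        train_epoch, test_epoch = direction.split("->")
    except ValueError:
        raise ValueError(f"direction must look like 'interictal->ictal', got {direction!r}")
    for epoch in (train_epoch, test_epoch):
        if epoch not in (INTERICTAL, ICTAL):
            raise ValueError(f"unknown epoch type {epoch!r}")
        if not (table["epoch_type"] == epoch).any():
            raise ValueError(f"table has no {epoch} rows")
    cols = feature_columns(table)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if equalize:
        table = equalize_epoch_observations(table, rng)
    train_all = table[table["epoch_type"] == train_epoch]
    test_all = _complete_rows(table[table["epoch_type"] == test_epoch], cols)
    labels = _contact_labels(train_all)
    aucs, contact_aucs, artifacts = [], [], []
    for _ in range(config.balance_repeats):
        selected = _balanced_contact_sample(labels, rng)
        train = _complete_rows(train_all[train_all["contact"].isin(selected)], cols)
        model = _fit(train, cols, config, rng.integers(2**31))
        votes = _votes(model, test_all, cols)
        row_auc, contact_auc = row_and_contact_auc(
            test_all["label"].to_numpy(), votes, test_all["contact"].to_numpy()
        )
        aucs.append(row_auc)
        contact_aucs.append(contact_auc)
        if keep_models:
            artifacts.append(
                {"frame": test_all, "models": [(model, np.arange(len(test_all)))],
                 "base_auc": row_auc}
            )
    return SchemeResult(
        scheme=direction,
        aucs=np.asarray(aucs),
        contact_aucs=np.asarray(contact_aucs),
        artifacts=artifacts or None,
    )


# ---------------------------------------------------------------------------
# Scheme: cross-patient leave-one-out
# ---------------------------------------------------------------------------


def cross_patient(
    table: pd.DataFrame,
    config: ClassifierConfig,
    epoch_type: str,
    zscore_per_patient: bool = False,
    keep_models: bool = False,
) -> SchemeResult:
    """Leave-one-patient-out classification within one epoch type.

    Balancing is applied at contact level within the pooled training
    patients.  ``aucs`` holds one mean AUC per test patient; a test
    patient with a single class yields NaN (logged).
    """
    config.validate()
    sub = table[table["epoch_type"] == epoch_type].copy()
    patients = sub["patient"].unique()
    if len(patients) < 3:
        raise ValueError("cross-patient classification needs >=3 patients")
    cols = feature_columns(table)
    if zscore_per_patient:
        sub[cols] = sub.groupby("patient")[cols].transform(
            lambda g: (g - g.mean()) / g.std(ddof=0).replace(0, np.nan)
        )
    seed_seq = np.random.SeedSequence(config.seed)
    streams = seed_seq.spawn(len(patients))
    per_patient_auc, per_patient_contact, artifacts = [], [], []
    for patient, stream in zip(patients, streams):
        rng = np.random.default_rng(stream)
        train_all = sub[sub["patient"] != patient]
        test = _complete_rows(sub[sub["patient"] == patient], cols)
        if test["label"].nunique() < 2:
            logger.warning("patient %s has one class only; AUC undefined", patient)
            per_patient_auc.append(np.nan)
            per_patient_contact.append(np.nan)
            continue
        labels = _contact_labels(train_all)
        rep_aucs, rep_contact = [], []
        for _ in range(config.balance_repeats):
            selected = _balanced_contact_sample(labels, rng)
            train = _complete_rows(
                train_all[train_all["contact"].isin(selected)], cols
            )
            model = _fit(train, cols, config, rng.integers(2**31))
            votes = _votes(model, test, cols)
            row_auc, contact_auc = row_and_contact_auc(
                test["label"].to_numpy(), votes, test["contact"].to_numpy()
            )
            rep_aucs.append(row_auc)
            rep_contact.append(contact_auc)
            if keep_models:
                artifacts.append(
                    {"frame": test, "models": [(model, np.arange(len(test)))],
                     "base_auc": row_auc}
                )
        per_patient_auc.append(float(np.nanmean(rep_aucs)))
        per_patient_contact.append(float(np.nanmean(rep_contact)))
    return SchemeResult(
        scheme=f"cross-patient-{epoch_type}",
        aucs=np.asarray(per_patient_auc),
        contact_aucs=np.asarray(per_patient_contact),
        per_patient=pd.DataFrame(
            {"patient": patients, "mean_auc": per_patient_auc,
             "contact_auc": per_patient_contact}
        ),
        artifacts=artifacts or None,
    )


# ---------------------------------------------------------------------------
# Chance distributions
# ---------------------------------------------------------------------------


def shuffle_contact_labels(
    table: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Permute epileptogenic labels across contacts, within each patient.

    All rows of a contact receive the contact's shuffled label, so the
    per-patient class balance is preserved exactly.
    """
    shuffled = table.copy()
    for _, idx in table.groupby("patient").groups.items():
        block = table.loc[idx]
        labels = _contact_labels(block)
        permuted = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index
        )
        shuffled.loc[idx, "label"] = block["contact"].map(permuted).to_numpy()
    return shuffled


def chance_distribution(
    table: pd.DataFrame,
    config: ClassifierConfig,
    scheme: str,
    **scheme_kwargs,
) -> np.ndarray:
    """Empirical null AUC distribution for any scheme.

    Contact labels are shuffled (within patient) ``chance_shuffles``
    times and the full scheme re-run per shuffle with
    ``chance_balance_repeats`` balance repeats; each shuffle contributes
    its mean AUC.
    """
    config.validate()
    runners = {
        "within": within_patient,
        "cross-time": cross_time,
        "cross-patient": cross_patient,
    }
    if scheme not in runners:
        raise ValueError(f"unknown scheme {scheme!r}; one of {sorted(runners)}")
    master = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    nulls = np.empty(config.chance_shuffles)
    for i in range(config.chance_shuffles):
        shuffled = shuffle_contact_labels(table, master)
        sub_config = replace(
            config,
            balance_repeats=config.chance_balance_repeats,
            seed=int(master.integers(2**31)),
        )
        result = runners[scheme](shuffled, sub_config, **scheme_kwargs)
        nulls[i] = result.mean_auc
    return nulls


# ---------------------------------------------------------------------------
# Permutation feature contributions
# ---------------------------------------------------------------------------


def permutation_contribution(
    result: SchemeResult,
    config: ClassifierConfig,
    n_draws: int | None = None,
) -> pd.DataFrame:
    """Per-feature contribution to a completed scheme evaluation.

    For each feature, its column is permuted across the stored test rows
    and the held-out votes re-scored; the contribution is
    ``max(0, AUC - AUC_permuted)`` averaged over balance repeats and
    permutation draws, reported raw and normalised to sum 1.
    """
    if not result.artifacts:
        raise ValueError("scheme result was produced without keep_models=True")
    n_draws = n_draws or config.contribution_draws
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    sample = result.artifacts[0]["frame"]
    cols = feature_columns(sample)
    drops = np.zeros(len(cols))
    for artifact in result.artifacts:
        frame, base_auc = artifact["frame"], artifact["base_auc"]
        if not np.isfinite(base_auc):
            continue
        y = frame["label"].to_numpy()
        x = frame[cols].to_numpy()
        feature_drop = np.zeros(len(cols))
        for j, _ in enumerate(cols):
            for _ in range(n_draws):
                x_perm = x.copy()
                x_perm[:, j] = rng.permutation(x_perm[:, j])
                votes = np.full(len(frame), np.nan)
                for model, test_idx in artifact["models"]:
                    proba = model.predict_proba(x_perm[test_idx])
                    if proba.shape[1] == 1:
                        votes[test_idx] = float(model.classes_[0])
                    else:
                        votes[test_idx] = proba[:, list(model.classes_).index(1)]
                ok = ~np.isnan(votes)
                if len(np.unique(y[ok])) < 2:
                    continue
                feature_drop[j] += base_auc - roc_auc_score(y[ok], votes[ok])
        drops += feature_drop / n_draws
    drops /= max(len(result.artifacts), 1)
    raw = np.maximum(drops, 0.0)
    total = raw.sum()
    if total <= 0:
        logger.warning("degenerate permutation contributions (baseline at chance)")
    normalised = raw / total if total > 0 else np.zeros_like(raw)
    return pd.DataFrame(
        {"feature": cols, "raw": raw, "normalised": normalised}
    )


__all__ = [
    "META_COLS",
    "SCHEMES",
    "ClassifierConfig",
    "SchemeResult",
    "feature_columns",
    "build_observations",
    "within_patient",
    "cross_time",
    "cross_patient",
    "chance_distribution",
    "shuffle_contact_labels",
    "equalize_epoch_observations",
    "permutation_contribution",
    "row_and_contact_auc",
]
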