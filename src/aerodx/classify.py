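"""Random-forest classification of body site and aspiration status.

Site classifiers use 5-fold cross-validation with folds that partition
patients (both of a patient's samples always share a split); aspiration
classifiers use leave-one-out evaluation. AUC is computed from the pooled
out-of-fold probabilities and a Fisher exact p-value from the 2x2
confusion matrix of hard predictions at probability 0.5. Feature
encodings follow the study design: site-tagged community abundances,
per-site presence of exchanged OTUs, or cross-site concordance codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from aerodx.core_io import AbundanceTable, SampleMetadata

FEATURE_MODES = ("community", "exchanged_presence", "exchanged_concordance")


@dataclass
class FeatureMatrix:
    """Unit-by-feature matrix with binary labels (1 = aspirator)."""

    data: pd.DataFrame  # index: unit IDs (patients), columns: feature names
    labels: pd.Series  # aligned with data.index; values in {0, 1}

    def __post_init__(self) -> None:
        if list(self.data.index) != list(self.labels.index):
            raise ValueError("feature matrix and labels are misaligned")
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing values")


@dataclass
class ClassifierReport:
    """Out-of-fold evaluation of one classifier."""

    auc: float
    fisher_p: float
    predictions: pd.DataFrame  # unit, truth, probability, hard_label, fold
    n_per_class: dict
    confusion: np.ndarray  # 2x2 at probability threshold 0.5


def concordance_encoding(presence_a, presence_b) -> np.ndarray:
    """1 where an OTU is present in both sites or absent in both; else 0."""
    a = np.asarray(presence_a).astype(int)
    b = np.asarray(presence_b).astype(int)
    if a.shape != b.shape:
        raise ValueError("presence vectors have different lengths")
    return (a == b).astype(int)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]]."""
    cells = (a, b, c, d)
    for v in cells:
        if v < 0 or int(v) != v:
            raise ValueError(f"cells must be non-negative integers, got {cells}")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _confusion_and_fisher(truth: np.ndarray, hard: np.ndarray):
    tp = int(np.sum((truth == 1) & (hard == 1)))
    fn = int(np.sum((truth == 1) & (hard == 0)))
    fp = int(np.sum((truth == 0) & (hard == 1)))
    tn = int(np.sum((truth == 0) & (hard == 0)))
    confusion = np.array([[tn, fp], [fn, tp]])
    return confusion, fisher_exact_2x2(tn, fp, fn, tp)


def build_features(
    table: AbundanceTable,
    metadata: SampleMetadata,
    mode: str,
    sites,
    exchanged_otus=None,
) -> FeatureMatrix:
    """Build an aspiration-prediction feature matrix over patients.

    Units are patients having every requested site sampled and a
    non-untested aspiration label. Modes:

    - ``community``: site-tagged relative abundances of every OTU;
    - ``exchanged_presence``: 0/1 presence of each exchanged OTU in a
      single named site (``sites`` must have length 1);
    - ``exchanged_concordance``: concordance code of each exchanged OTU
      across the two sites of the pair.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown feature mode {mode!r}")
    if table.mode != "relative":
        raise ValueError("build_features requires a relative-mode table")
    sites = list(sites)
    if mode == "exchanged_presence" and len(sites) != 1:
        raise ValueError("exchanged_presence uses exactly one site")
    if mode == "exchanged_concordance" and len(sites) != 2:
        raise ValueError("exchanged_concordance uses exactly two sites")
    if mode in ("exchanged_presence", "exchanged_concordance"):
        if exchanged_otus is None:
            raise ValueError(f"mode {mode!r} requires an exchanged-OTU list")
        otus = list(exchanged_otus)
    else:
        otus = table.otu_ids
    sample_set = set(table.sample_ids)
    units = []
    for p in metadata.patients_with_sites(sites):
        if metadata.patient_status(p) == "untested":
            continue
        if all(metadata.sample_for(p, s) in sample_set for s in sites):
            units.append(p)
    if not units:
        raise ValueError("no eligible patients for the requested sites")
    per_site = {}
    for s in sites:
        samples = [metadata.sample_for(p, s) for p in units]
        sub = table.data.loc[otus, samples] if otus != table.otu_ids else table.data[samples]
        per_site[s] = pd.DataFrame(
            sub.to_numpy(dtype=float).T, index=units, columns=otus
        )
    if mode == "community":
        blocks = [
            per_site[s].rename(columns=lambda o, s=s: f"{s}:{o}") for s in sites
        ]
        data = pd.concat(blocks, axis=1)
    elif mode == "exchanged_presence":
        data = (per_site[sites[0]] > 0).astype(int)
        data.columns = [f"{sites[0]}:{o}:present" for o in otus]
    else:
        pa = (per_site[sites[0]] > 0).to_numpy().astype(int)
        pb = (per_site[sites[1]] > 0).to_numpy().astype(int)
        data = pd.DataFrame(
            (pa == pb).astype(int),
            index=units,
            columns=[f"{o}:concordant" for o in otus],
        )
    labels = pd.Series(
        [1 if metadata.patient_status(p) == "aspirator" else 0 for p in units],
        index=units,
    )
    return FeatureMatrix(data, labels)


def _patient_folds(patients, n_folds: int, rng: np.random.Generator) -> dict[str, int]:
    order = list(patients)
    rng.shuffle(order)
    return {p: i % n_folds for i, p in enumerate(order)}


def site_classifier_cv(
    table: AbundanceTable,
    metadata: SampleMetadata,
    sites,
    n_folds: int = 5,
    n_trees: int = 1000,
    seed=None,
) -> ClassifierReport:
    """Random-forest discrimination of two body sites, patient-grouped CV.

    Folds partition patients, never samples, so a patient's samples are
    always in the same train/test split; out-of-fold probabilities are
    pooled into a single ROC/AUC. The positive class is ``sites[1]``.
    """
    sites = list(sites)
    if len(sites) != 2:
        raise ValueError("site_classifier_cv compares exactly two sites")
    if table.mode != "relative":
        raise ValueError("site_classifier_cv requires a relative-mode table")
    rows = metadata.data[metadata.data["site"].isin(sites)]
    rows = rows[rows.index.isin(set(table.sample_ids))]
    patients = sorted(rows["patient_id"].unique())
    if len(patients) < n_folds:
        raise ValueError(f"need at least {n_folds} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    fold_of = _patient_folds(patients, n_folds, rng)
    X = table.data[rows.index].to_numpy(dtype=float).T
    y = (rows["site"] == sites[1]).to_numpy().astype(int)
    folds = np.array([fold_of[p] for p in rows["patient_id"]])
    prob = np.full(len(y), np.nan)
    forest_seeds = np.random.SeedSequence(
        rng.integers(0, 2**31)
    ).spawn(n_folds)
    for f in range(n_folds):
        test = folds == f
        if not test.any() or len(np.unique(y[~test])) < 2:
            raise ValueError(f"fold {f} leaves a single-class training set")
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=np.random.default_rng(forest_seeds[f]).integers(0, 2**31),
        )
        clf.fit(X[~test], y[~test])
        pos = list(clf.classes_).index(1)
        prob[test] = clf.predict_proba(X[test])[:, pos]
    hard = (prob >= 0.5).astype(int)
    confusion, fisher_p = _confusion_and_fisher(y, hard)
    predictions = pd.DataFrame(
        {
            "unit": rows.index,
            "truth": y,
            "probability": prob,
            "hard_label": hard,
            "fold": folds,
        }
    ).set_index("unit")
    return ClassifierReport(
        auc=float(roc_auc_score(y, prob)),
        fisher_p=fisher_p,
        predictions=predictions,
        n_per_class={sites[0]: int((y == 0).sum()), sites[1]: int((y == 1).sum())},
        confusion=confusion,
    )


def aspiration_classifier_loo(
    features: FeatureMatrix, n_trees: int = 1000, seed=None
) -> ClassifierReport:
    """Leave-one-out random-forest prediction of aspiration status.

    Each unit is predicted by a forest trained on all other units; AUC is
    computed from the pooled held-out probabilities and the Fisher exact
    p-value from the confusion matrix of hard labels at 0.5.
    """
    X = features.data.to_numpy(dtype=float)
    y = features.labels.to_numpy().astype(int)
    n = len(y)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 units per class")
    seeds = np.random.SeedSequence(seed).spawn(n)
    prob = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=np.random.default_rng(seeds[i]).integers(0, 2**31),
        )
        clf.fit(X[mask], y[mask])
        pos = list(clf.classes_).index(1)
        prob[i] = clf.predict_proba(X[i : i + 1])[0, pos]
    hard = (prob >= 0.5).astype(int)
    confusion, fisher_p = _confusion_and_fisher(y, hard)
    predictions = pd.DataFrame(
        {
            "unit": features.data.index,
            "truth": y,
            "probability": prob,
            "hard_label": hard,
            "fold": np.arange(n),
        }
    ).set_index("unit")
    return ClassifierReport(
        auc=float(roc_auc_score(y, prob)),
        fisher_p=fisher_p,
        predictions=predictions,
        n_per_class={"non_aspirator": int((y == 0).sum()), "aspirator": int((y == 1).sum())},
        confusion=confusion,
    )
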