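"""Training protocol for the three-class intoxication classifier.

Stages, in order: stratified 80/20 split; training-median imputation;
greedy removal of one feature from every pair with |Pearson r| > 0.9
(the first-listed feature of a pair is kept, so the result is a
deterministic function of the documented feature order); impurity
("Gini") importance selection keeping features scoring > 0.005 on an
auxiliary random forest; minority oversampling to equal class counts by
convex combination of same-class nearest neighbors (applied inside
training folds only, never to validation or test rows); Bayesian
hyperparameter search — a Gaussian-process surrogate with expected-
improvement acquisition — maximizing mean 10-fold cross-validated
macro-F1 of a gradient-boosted tree ensemble; final refit on the full
training set with the chosen hyperparameters.

Three sensor variants share identical labels and windows and differ only
in feature columns: ``mobile`` (smartphone), ``fitbit`` (wearable) and
``mobifit`` (both).  Sensitivity configurations drop GPS-derived travel
features, prior-night sleep features, or both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from xgboost import XGBClassifier

from .datamodel import RawCohort, log
from .fitbit import FITBIT_FEATURES, SLEEP_FEATURES, extract_fitbit_features
from .labeling import CLASS_ORDER, down_sample_to_overlap, label_cohort
from .mobile import GPS_FEATURES, MOBILE_FEATURES, extract_mobile_features

VARIANTS = ("mobile", "fitbit", "mobifit")
SENSITIVITIES = ("none", "gps_excluded", "sleep_excluded", "gps_sleep_excluded")


@dataclass
class PipelineConfig:
    variant: str = "mobifit"
    sensitivity: str = "none"
    test_fraction: float = 0.20
    corr_threshold: float = 0.9
    gini_threshold: float = 0.005
    cv_folds: int = 10
    n_trials: int = 20          # Bayesian search budget
    seed: int = 0
    n_per_day: int = 24         # not-intoxicated windows per anchor day

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.sensitivity not in SENSITIVITIES:
            raise ValueError(f"sensitivity must be one of {SENSITIVITIES}")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def variant_features(variant: str, sensitivity: str = "none") -> list[str]:
    """Feature columns for a sensor variant / sensitivity configuration."""
    if variant == "mobile":
        cols = list(MOBILE_FEATURES)
    elif variant == "fitbit":
        cols = list(FITBIT_FEATURES)
    else:
        cols = list(MOBILE_FEATURES) + list(FITBIT_FEATURES)
    drop: set[str] = set()
    if sensitivity in ("gps_excluded", "gps_sleep_excluded"):
        drop |= set(GPS_FEATURES)
    if sensitivity in ("sleep_excluded", "gps_sleep_excluded"):
        drop |= set(SLEEP_FEATURES)
    return [c for c in cols if c not in drop]


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def build_dataset(cohort: RawCohort, config: PipelineConfig
                  ) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Labeled feature matrix for a cohort under one pipeline config.

    All variants are evaluated on the common window set — windows holding
    both smartphone and wearable coverage — so they differ only in feature
    columns.  Returns (X indexed by (participant, window_start), y, audit).
    """
    config.validate()
    labels, audit = label_cohort(cohort, seed=config.seed,
                                 n_per_day=config.n_per_day)
    labeled = labels[labels["label"].isin(CLASS_ORDER)]
    frames = []
    for pid in sorted(cohort.participants):
        p = cohort.participants[pid]
        starts = labeled.loc[labeled["participant"] == pid, "window_start"]
        if starts.empty:
            continue
        mob = extract_mobile_features(p, starts)
        fit = extract_fitbit_features(p, starts)
        feat = mob.join(fit)
        feat.insert(0, "participant", pid)
        frames.append(feat.reset_index())
    if not frames:
        raise ValueError("no labeled windows with sensor data")
    feats = pd.concat(frames, ignore_index=True)
    feats = feats.merge(labeled[["participant", "window_start", "label"]],
                        on=["participant", "window_start"], how="inner")

    # coverage: a window needs >= 1 smartphone sample and >= 1 valid HR sample
    mobile_cov = feats[~feats[list(MOBILE_FEATURES)].isna().all(axis=1)]
    fitbit_cov = feats[feats["hr_avg"].notna()]
    common = down_sample_to_overlap(mobile_cov, fitbit_cov)
    audit["coverage"] = {"mobile": int(len(mobile_cov)),
                         "fitbit": int(len(fitbit_cov)),
                         "common": int(len(common))}
    common = common.set_index(["participant", "window_start"]).sort_index()
    y = common["label"]
    X = common[variant_features(config.variant, config.sensitivity)]
    log.info("build_dataset: %d windows, %d features (%s/%s)",
             len(X), X.shape[1], config.variant, config.sensitivity)
    return X, y, audit


def split(X: pd.DataFrame, y: pd.Series, test_fraction: float = 0.20,
          seed: int = 0):
    """Deterministic class-stratified train/test split."""
    return train_test_split(X, y, test_size=test_fraction, stratify=y,
                            random_state=seed)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def prune_correlated(X: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Greedy pass in column order keeping the first feature of every
    offending pair; |r| must exceed the threshold strictly (r = 0.9 stays).
    Constant features have undefined r, treated as 0 and retained.
    """
    arr = X.to_numpy(dtype=float)
    cols = list(X.columns)
    sd = arr.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    kept: list[int] = []
    for j in range(len(cols)):
        if sd[j] == 0:
            kept.append(j)  # undefined correlation: retain
            continue
        if any(abs(corr[j, k]) > threshold for k in kept if sd[k] > 0):
            continue
        kept.append(j)
    return [cols[j] for j in kept]


def select_by_gini(X: pd.DataFrame, y: pd.Series,
                   threshold: float = 0.005, seed: int = 0,
                   n_estimators: int = 300) -> list[str]:
    """Keep features whose normalized impurity importance on an auxiliary
    random forest exceeds the threshold; falls back to the single most
    important feature if none clears it."""
    forest = RandomForestClassifier(n_estimators=n_estimators,
                                    random_state=seed, n_jobs=1)
    forest.fit(X.to_numpy(dtype=float), y.to_numpy())
    imp = forest.feature_importances_
    kept = [c for c, v in zip(X.columns, imp) if v > threshold]
    if not kept:
        kept = [X.columns[int(np.argmax(imp))]]
    return kept


# ---------------------------------------------------------------------------
# minority oversampling (SMOTE)
# ---------------------------------------------------------------------------

def oversample_minority(X: np.ndarray, y: np.ndarray, seed: int = 0,
                        k_neighbors: int = 5):
    """Equalize class counts by interpolating minority nearest neighbors.

    Each synthetic row is x_i + u * (x_nn - x_i) for a random same-class
    neighbor and u ~ U(0, 1).  Classes with a single member are duplicated.
    Never applied outside training folds.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    out_X, out_y = [X], [y]
    for cls, count in zip(classes, counts):
        need = int(target - count)
        if need == 0:
            continue
        Xc = X[y == cls]
        if len(Xc) == 1:
            synth = np.repeat(Xc, need, axis=0)
        else:
            k = min(k_neighbors, len(Xc) - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            _, idx = nn.kneighbors(Xc)
            base = rng.integers(0, len(Xc), size=need)
            pick = idx[base, rng.integers(1, k + 1, size=need)]
            gap = rng.uniform(0, 1, size=(need, 1))
            synth = Xc[base] + gap * (Xc[pick] - Xc[base])
        out_X.append(synth)
        out_y.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(out_X), np.concatenate(out_y)


# ---------------------------------------------------------------------------
# Bayesian hyperparameter search
# ---------------------------------------------------------------------------

#: (name, low, high, log-scale, integer)
SEARCH_SPACE = [
    ("n_estimators", 50, 300, True, True),
    ("max_depth", 2, 8, False, True),
    ("learning_rate", 0.02, 0.3, True, False),
    ("subsample", 0.6, 1.0, False, False),
    ("colsample_bytree", 0.5, 1.0, False, False),
    ("min_child_weight", 1.0, 16.0, True, False),
]


def _decode(unit: np.ndarray) -> dict:
    params = {}
    for u, (name, lo, hi, logscale, is_int) in zip(unit, SEARCH_SPACE):
        if logscale:
            v = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
        else:
            v = lo + u * (hi - lo)
        params[name] = int(round(v)) if is_int else float(v)
    return params


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return sigma * (z * stats.norm.cdf(z) + stats.norm.pdf(z))


def bayesian_maximize(objective, n_trials: int, seed: int = 0
                      ) -> tuple[dict, float, list]:
    """GP expected-improvement maximization over the documented space.

    The first third of the budget (at least 4 points when available) is
    random exploration; remaining trials fit a Matern-5/2 GP on observed
    scores and evaluate the EI-maximizing candidate from a random pool.
    """
    rng = np.random.default_rng(seed)
    dim = len(SEARCH_SPACE)
    n_init = min(n_trials, max(4, n_trials // 3))
    U, scores, history = [], [], []
    for t in range(n_trials):
        if t < n_init:
            u = rng.uniform(0, 1, dim)
        else:
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5, length_scale=np.full(dim, 0.3)),
                alpha=1e-4, normalize_y=True, random_state=seed)
            gp.fit(np.array(U), np.array(scores))
            cand = rng.uniform(0, 1, (256, dim))
            mu, sd = gp.predict(cand, return_std=True)
            u = cand[int(np.argmax(_expected_improvement(mu, sd, max(scores))))]
        params = _decode(u)
        score = objective(params)
        U.append(u)
        scores.append(score)
        history.append((params, score))
    best_idx = int(np.argmax(scores))
    return history[best_idx][0], float(scores[best_idx]), history


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    model: XGBClassifier
    features: list[str]            # frozen post-selection feature list
    medians: pd.Series             # training-set imputation values
    best_params: dict
    cv_macro_f1: float
    class_order: tuple = CLASS_ORDER
    present_codes: tuple = (0, 1, 2)  # class codes seen in training
    config: PipelineConfig | None = None
    search_history: list = field(default_factory=list, repr=False)

    @property
    def present_classes(self) -> tuple:
        """Class names the booster was actually fit on, in report order."""
        return tuple(self.class_order[c] for c in self.present_codes)

    def prepare(self, X: pd.DataFrame) -> np.ndarray:
        return (X[self.features].fillna(self.medians[self.features])
                .to_numpy(dtype=float))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        proba = self.model.predict_proba(self.prepare(X))
        codes = np.asarray(self.present_codes)[np.argmax(proba, axis=1)]
        return np.asarray(self.class_order)[codes]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """(n, 3) probabilities in report class order; a class absent from
        training scores 0 everywhere."""
        compact = self.model.predict_proba(self.prepare(X))
        out = np.zeros((len(compact), len(self.class_order)))
        out[:, list(self.present_codes)] = compact
        return out


def _make_xgb(params: dict, seed: int, num_class: int = 3) -> XGBClassifier:
    # softprob even for two present classes, so margins/attributions keep
    # one column per class
    return XGBClassifier(
        objective="multi:softprob", num_class=num_class, tree_method="hist",
        n_jobs=1, random_state=seed, eval_metric="mlogloss", **params)


def encode_labels(y) -> np.ndarray:
    lut = {c: i for i, c in enumerate(CLASS_ORDER)}
    return np.array([lut[v] for v in y], dtype=np.int64)


def tune_and_train(X_train: pd.DataFrame, y_train: pd.Series,
                   config: PipelineConfig) -> TrainedModel:
    """Impute, prune, select, tune with oversampled 10-fold CV, refit."""
    config.validate()
    y_codes = encode_labels(y_train)
    present = np.unique(y_codes)
    if present.size < 2:
        raise ValueError("training data contains a single class")
    # fit on a compact 0..k-1 label space; predictions map back to N/L/MI
    y_codes = np.searchsorted(present, y_codes)

    medians = X_train.median(numeric_only=True)
    medians = medians.fillna(0.0)  # all-missing columns impute to 0
    X_imp = X_train.fillna(medians)

    pruned = prune_correlated(X_imp, config.corr_threshold)
    selected = select_by_gini(X_imp[pruned], y_train,
                              threshold=config.gini_threshold,
                              seed=config.seed)
    Xs = X_imp[selected].to_numpy(dtype=float)

    max_folds = int(np.bincount(y_codes).min())
    folds = max(2, min(config.cv_folds, max_folds))
    cv = StratifiedKFold(n_splits=folds, shuffle=True,
                         random_state=config.seed)
    fold_idx = list(cv.split(Xs, y_codes))

    def objective(params: dict) -> float:
        scores = []
        for tr, va in fold_idx:
            Xb, yb = oversample_minority(Xs[tr], y_codes[tr],
                                         seed=config.seed)
            clf = _make_xgb(params, config.seed, present.size)
            clf.fit(Xb, yb)
            pred = np.argmax(clf.predict_proba(Xs[va]), axis=1)
            scores.append(f1_score(y_codes[va], pred, average="macro",
                                   zero_division=0))
        return float(np.mean(scores))

    best_params, best_score, history = bayesian_maximize(
        objective, config.n_trials, seed=config.seed)

    Xb, yb = oversample_minority(Xs, y_codes, seed=config.seed)
    final = _make_xgb(best_params, config.seed, present.size)
    final.fit(Xb, yb)
    log.info("tune_and_train: %s cv macro-F1=%.3f params=%s",
             config.variant, best_score, best_params)
    return TrainedModel(model=final, features=selected, medians=medians,
                        best_params=best_params, cv_macro_f1=best_score,
                        present_codes=tuple(int(c) for c in present),
                        config=config, search_history=history)


def run_pipeline(cohort: RawCohort, config: PipelineConfig):
    """Dataset -> split -> tune/train; returns (model, splits, audit)."""
    X, y, audit = build_dataset(cohort, config)
    X_tr, X_te, y_tr, y_te = split(X, y, config.test_fraction, config.seed)
    model = tune_and_train(X_tr, y_tr, config)
    return model, (X_tr, X_te, y_tr, y_te), audit
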