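"""Sleep-staging evaluation harness.

Assembles the 23-feature epoch table (6 entropy + 17 linear features),
runs the three classification tasks (5-, 4-, and 3-class) under
subject-wise 8-fold cross-validation with a gradient-boosted decision-tree
ensemble (XGBoost), and reports accuracy, Cohen's kappa, and per-class
Shapley-value feature importances.

Protocol per fold: two subjects are held out for testing, two more are set
aside from the remaining pool for validation; the rest train the model.
Hyperparameters are tuned by Bayesian optimization (Gaussian-process
surrogate, expected-improvement acquisition) against validation-set kappa;
boosting stops early once validation kappa has not improved for 20
consecutive rounds.  Class imbalance is handled with inverse-frequency
sample weights computed on the training fold.  Missing feature values are
imputed with the training-fold median at fit time.

Cohen's kappa is the chance-corrected agreement
``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_o`` the overall accuracy and
``p_e = sum_k p_{k+} p_{+k}`` the chance agreement from the confusion
matrix's marginals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xgboost as xgb

from .entropy import ENTROPY_FEATURES, EntropyParams, entropy_features
from .epochs import Epoch, EpochScheme, build_epochs
from .hrv_linear import LINEAR_FEATURES, linear_features
from .io import SCORABLE_STAGES, BeatSeries, Hypnogram, SleepStage
from .preprocess import PreprocessConfig

__all__ = [
    "FEATURE_COLUMNS",
    "TaskSpec",
    "make_task",
    "assemble_feature_table",
    "compute_feature_table",
    "make_subject_folds",
    "TrainConfig",
    "train_and_predict",
    "evaluate",
    "confusion_matrix",
    "cohen_kappa",
    "feature_importance",
    "FoldResult",
    "CVResults",
    "run_experiment",
]

FEATURE_COLUMNS: Tuple[str, ...] = tuple(ENTROPY_FEATURES) + tuple(LINEAR_FEATURES)


# ---------------------------------------------------------------------------
# classification tasks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskSpec:
    """A staging task: number of classes and the stage -> class map."""

    n_classes: int
    label_map: Tuple[Tuple[str, str], ...]

    def map_labels(self, stages: Iterable[str]) -> np.ndarray:
        m = dict(self.label_map)
        return np.array([m[str(s)] for s in stages])

    @property
    def classes(self) -> List[str]:
        seen: List[str] = []
        for _, v in self.label_map:
            if v not in seen:
                seen.append(v)
        return seen


_TASK_MAPS = {
    5: {"W": "W", "N1": "N1", "N2": "N2", "N3": "N3", "REM": "REM"},
    4: {"W": "W", "N1": "LS", "N2": "LS", "N3": "DS", "REM": "REM"},
    3: {"W": "W", "N1": "NREM", "N2": "NREM", "N3": "NREM", "REM": "REM"},
}


def make_task(n_classes: int) -> TaskSpec:
    """The 5-class (full stages), 4-class (light/deep sleep), or 3-class
    (W/NREM/REM) task."""
    if n_classes not in _TASK_MAPS:
        raise ValueError("n_classes must be 3, 4, or 5")
    return TaskSpec(n_classes, tuple(_TASK_MAPS[n_classes].items()))


# ---------------------------------------------------------------------------
# feature-table assembly
# ---------------------------------------------------------------------------

def assemble_feature_table(
    epochs: Sequence[Epoch],
    entropy_params: EntropyParams | None = None,
    spectral_method: str = "lomb",
    linear_only: bool = False,
    scheme_tag: Optional[str] = None,
) -> pd.DataFrame:
    """One row per *retained* epoch: 23 features + subject, stage, start.

    With ``linear_only=True`` the six entropy columns are dropped (the
    ablation arm).  NaN features are kept and flagged via ``has_nan``;
    imputation happens per training fold at fit time, never here.
    """
    entropy_params = entropy_params or EntropyParams()
    rows = []
    for ep in epochs:
        if not ep.retained:
            continue
        row: Dict = {
            "subject_id": ep.subject_id,
            "stage": ep.stage.value,
            "epoch_start_s": ep.start_time,
            "scheme": scheme_tag or str(ep.window_len),
        }
        if not linear_only:
            row.update(entropy_features(ep.rr, entropy_params).as_dict())
        row.update(linear_features(ep.rr, method=spectral_method))
        rows.append(row)
    if not rows:
        raise ValueError("no retained epochs; cannot assemble a feature table")
    df = pd.DataFrame(rows)
    feats = [c for c in FEATURE_COLUMNS if c in df.columns]
    df["has_nan"] = df[feats].isna().any(axis=1)
    return df


def compute_feature_table(
    cohort: Sequence[Tuple[BeatSeries, Hypnogram]],
    scheme: EpochScheme | None = None,
    entropy_params: EntropyParams | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
    spectral_method: str = "lomb",
    linear_only: bool = False,
) -> pd.DataFrame:
    """Full front half of the pipeline: epochs -> features for a cohort."""
    scheme = scheme or EpochScheme()
    all_epochs: List[Epoch] = []
    for beats, hyp in cohort:
        all_epochs.extend(build_epochs(hyp, beats, scheme, preprocess_cfg))
    return assemble_feature_table(
        all_epochs,
        entropy_params=entropy_params,
        spectral_method=spectral_method,
        linear_only=linear_only,
        scheme_tag=str(scheme.window_len),
    )


# ---------------------------------------------------------------------------
# folds and metrics
# ---------------------------------------------------------------------------

def make_subject_folds(
    subject_ids: Sequence[str],
    k: int = 8,
    n_val_subjects: int = 2,
    seed: int = 0,
) -> List[Dict[str, List[str]]]:
    """Subject-wise folds: per fold, 2 test subjects, 2 validation subjects
    from the remainder, and the rest for training.

    Test sets are disjoint and jointly cover every subject.  Validation
    subjects rotate deterministically (each fold validates on the next
    fold's test subjects).  With fewer than ``2 * k`` subjects the fold
    count shrinks proportionally, with a warning.
    """
    subjects = sorted(set(map(str, subject_ids)))
    n = len(subjects)
    per_fold = 2
    if n < per_fold * k:
        k_new = max(2, n // per_fold)
        warnings.warn(f"only {n} subjects; shrinking fold count {k} -> {k_new}")
        k = k_new
    if n < 2 * per_fold:
        raise ValueError("need at least 4 subjects for held-out validation")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(subjects))
    groups = [order[i::k] for i in range(k)]
    folds = []
    for i in range(k):
        test = groups[i]
        remaining = [s for s in order if s not in test]
        n_val = min(n_val_subjects, max(1, len(remaining) - 1))
        val = [s for s in groups[(i + 1) % k] if s in remaining][:n_val]
        if len(val) < n_val:
            val += [s for s in remaining if s not in val][: n_val - len(val)]
        train = [s for s in remaining if s not in val]
        folds.append({"train": train, "val": val, "test": test})
    return folds


def confusion_matrix(truth, pred, classes: Sequence[str]) -> np.ndarray:
    """q x q count matrix, rows = truth, columns = prediction."""
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, pred):
        cm[idx[str(t)], idx[str(p)]] += 1
    return cm


def cohen_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement from a confusion matrix."""
    n = cm.sum()
    po = np.trace(cm) / n
    pe = float((cm.sum(axis=0) / n) @ (cm.sum(axis=1) / n))
    if pe == 1.0:
        return float("nan")
    return float((po - pe) / (1.0 - pe))


def evaluate(pred, truth, task: TaskSpec) -> Tuple[float, float, np.ndarray]:
    """(accuracy, kappa, confusion matrix) for one prediction set."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have equal length")
    cm = confusion_matrix(truth, pred, task.classes)
    acc = float(np.trace(cm) / cm.sum())
    return acc, cohen_kappa(cm), cm


# ---------------------------------------------------------------------------
# model training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Classifier and tuning configuration.

    The Bayesian search space covers max depth 2-10, learning rate
    0.01-0.3 (log scale), subsample and column subsample 0.5-1.0, and L1/L2
    regularization 0-5.  ``n_bo_iter = 0`` (with ``n_bo_init = 0``) skips
    tuning and uses ``base_params``.
    """

    max_rounds: int = 300
    early_stopping_rounds: int = 20
    n_bo_init: int = 8
    n_bo_iter: int = 22
    base_params: Dict = field(
        default_factory=lambda: {
            "max_depth": 4,
            "eta": 0.1,
            "subsample": 0.9,
            "colsample_bytree": 0.9,
            "alpha": 0.0,
            "lambda": 1.0,
        }
    )
    nthread: int = 1


_BO_SPACE = (
    ("max_depth", 2, 10, "int"),
    ("eta", math.log(0.01), math.log(0.3), "log"),
    ("subsample", 0.5, 1.0, "lin"),
    ("colsample_bytree", 0.5, 1.0, "lin"),
    ("alpha", 0.0, 5.0, "lin"),
    ("lambda", 0.0, 5.0, "lin"),
)


def _decode_point(u: np.ndarray) -> Dict:
    out = {}
    for ui, (name, lo, hi, kind) in zip(u, _BO_SPACE):
        v = lo + ui * (hi - lo)
        if kind == "log":
            v = math.exp(v)
        elif kind == "int":
            v = int(round(v))
        out[name] = v
    return out


def _bayes_opt(objective, n_init: int, n_iter: int, rng: np.random.Generator) -> Dict:
    """Maximize ``objective(params) -> float`` over the hyperparameter box.

    Gaussian-process surrogate (Matern 5/2) with expected-improvement
    acquisition evaluated on random candidate draws.  Deterministic under
    the supplied generator.
    """
    from scipy.stats import norm
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern, WhiteKernel

    d = len(_BO_SPACE)
    X = rng.random((max(n_init, 2), d))
    y = np.array([objective(_decode_point(u)) for u in X])
    for _ in range(n_iter):
        kernel = Matern(nu=2.5, length_scale=np.full(d, 0.3)) + WhiteKernel(1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, random_state=0
            ).fit(X, y)
        cand = rng.random((256, d))
        mu, sd = gp.predict(cand, return_std=True)
        best = y.max()
        sd = np.maximum(sd, 1e-9)
        z = (mu - best) / sd
        ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
        u = cand[int(np.argmax(ei))]
        X = np.vstack([X, u])
        y = np.append(y, objective(_decode_point(u)))
    return _decode_point(X[int(np.argmax(y))])


def _kappa_eval(classes: Sequence[int]):
    q = len(classes)

    def feval(predt: np.ndarray, dmat: xgb.DMatrix):
        labels = dmat.get_label().astype(int)
        pred = predt.reshape(len(labels), -1).argmax(axis=1)
        cm = np.zeros((q, q))
        for t, p in zip(labels, pred):
            cm[t, p] += 1
        return "kappa", cohen_kappa(cm)

    return feval


def _fit_booster(params, dtrain, dval, cfg: TrainConfig, n_classes: int, seed: int):
    full = {
        "objective": "multi:softprob",
        "num_class": n_classes,
        "tree_method": "hist",
        "nthread": cfg.nthread,
        "seed": seed,
        "verbosity": 0,
        **params,
    }
    return xgb.train(
        full,
        dtrain,
        num_boost_round=cfg.max_rounds,
        evals=[(dval, "val")],
        custom_metric=_kappa_eval(range(n_classes)),
        maximize=True,
        early_stopping_rounds=cfg.early_stopping_rounds,
        verbose_eval=False,
    )


def _prepare_fold(table: pd.DataFrame, task: TaskSpec, fold, feats):
    """Split, impute (train-fold medians), weight, and encode one fold."""
    y_all = task.map_labels(table["stage"])
    sid = table["subject_id"].astype(str).to_numpy()
    masks = {part: np.isin(sid, fold[part]) for part in ("train", "val", "test")}
    X = table[feats].to_numpy(dtype=float)
    med = np.nanmedian(X[masks["train"]], axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    X = np.where(np.isfinite(X), X, med)

    classes = sorted(set(y_all[masks["train"]]))
    enc = {c: i for i, c in enumerate(classes)}
    out = {}
    for part in ("train", "val", "test"):
        m = masks[part] & np.isin(y_all, classes)
        out[part] = (X[m], np.array([enc[c] for c in y_all[m]], dtype=int), m)
    y_tr = out["train"][1]
    freq = np.bincount(y_tr, minlength=len(classes)).astype(float)
    w = len(y_tr) / (len(classes) * np.maximum(freq, 1.0))
    out["weights"] = w[y_tr]
    out["classes"] = classes
    return out


@dataclass
class FoldResult:
    acc: float
    kappa: float
    cm: np.ndarray
    pred: np.ndarray
    truth: np.ndarray
    test_subjects: List[str]
    best_params: Dict
    importance: Optional[pd.DataFrame] = None


def train_and_predict(
    table: pd.DataFrame,
    task: TaskSpec,
    folds: List[Dict[str, List[str]]],
    cfg: TrainConfig | None = None,
    seed: int = 0,
    compute_importance: bool = False,
) -> List[FoldResult]:
    """Train the boosted ensemble per fold and predict its test epochs.

    A class absent from a training fold is logged and excluded from that
    fold's model (its epochs cannot be predicted as that class).
    """
    cfg = cfg or TrainConfig()
    feats = [c for c in FEATURE_COLUMNS if c in table.columns]
    results: List[FoldResult] = []
    for i, fold in enumerate(folds):
        data = _prepare_fold(table, task, fold, feats)
        classes = data["classes"]
        if len(classes) < task.n_classes:
            warnings.warn(
                f"fold {i}: classes {sorted(set(task.classes) - set(classes))} "
                "absent from training data; model trained on present classes"
            )
        X_tr, y_tr, _ = data["train"]
        X_va, y_va, _ = data["val"]
        X_te, y_te, _ = data["test"]
        dtrain = xgb.DMatrix(X_tr, label=y_tr, weight=data["weights"], feature_names=feats)
        dval = xgb.DMatrix(X_va, label=y_va, feature_names=feats)
        rng = np.random.default_rng([seed, i])

        if cfg.n_bo_init + cfg.n_bo_iter > 0:
            def objective(params):
                bst = _fit_booster(params, dtrain, dval, cfg, len(classes), seed)
                return bst.best_score

            best_params = _bayes_opt(objective, cfg.n_bo_init, cfg.n_bo_iter, rng)
        else:
            best_params = dict(cfg.base_params)
        booster = _fit_booster(best_params, dtrain, dval, cfg, len(classes), seed)
        it = (0, booster.best_iteration + 1) if booster.best_iteration is not None else None
        dtest = xgb.DMatrix(X_te, feature_names=feats)
        prob = booster.predict(dtest, iteration_range=it)
        pred = np.array([classes[j] for j in prob.argmax(axis=1)])
        truth = np.array([classes[j] for j in y_te])
        acc, kap, cm = evaluate(pred, truth, task)
        imp = None
        if compute_importance:
            imp = feature_importance(booster, X_te, feats, classes, iteration_range=it)
        results.append(
            FoldResult(acc, kap, cm, pred, truth, fold["test"], best_params, imp)
        )
    return results


def feature_importance(
    booster: xgb.Booster,
    X: np.ndarray,
    feature_names: Sequence[str],
    classes: Sequence[str],
    iteration_range=None,
) -> pd.DataFrame:
    """Mean |Shapley value| per feature per class on the given data.

    Uses the ensemble's exact TreeSHAP attributions.  Rows are features
    sorted by total importance (descending); columns are classes.
    """
    dmat = xgb.DMatrix(np.asarray(X, dtype=float), feature_names=list(feature_names))
    kwargs = {"iteration_range": iteration_range} if iteration_range else {}
    contrib = booster.predict(dmat, pred_contribs=True, **kwargs)
    if contrib.ndim == 2:  # binary/single-class edge: (n, nfeat + 1)
        contrib = contrib[:, None, :]
    vals = np.abs(contrib[:, :, : len(feature_names)]).mean(axis=0).T
    df = pd.DataFrame(vals, index=list(feature_names), columns=list(classes))
    return df.loc[df.sum(axis=1).sort_values(ascending=False).index]


# ---------------------------------------------------------------------------
# full experiment grid
# ---------------------------------------------------------------------------

@dataclass
class CVResults:
    """Cross-validated metrics for one scheme x task x ablation cell."""

    scheme: str
    n_classes: int
    linear_only: bool
    fold_acc: np.ndarray
    fold_kappa: np.ndarray
    importance: Optional[pd.DataFrame] = None

    @property
    def acc_mean(self) -> float:
        return float(np.mean(self.fold_acc))

    @property
    def acc_sd(self) -> float:
        return float(np.std(self.fold_acc, ddof=1))

    @property
    def kappa_mean(self) -> float:
        return float(np.nanmean(self.fold_kappa))

    @property
    def kappa_sd(self) -> float:
        return float(np.nanstd(self.fold_kappa, ddof=1))


def run_experiment(
    cohort,
    schemes: Sequence[int] = (270, 300),
    tasks: Sequence[int] = (5, 4, 3),
    ablations: Sequence[bool] = (False, True),
    seed: int = 0,
    cfg: TrainConfig | None = None,
    entropy_params: EntropyParams | None = None,
    compute_importance: bool = False,
    k_folds: int = 8,
) -> Dict:
    """The full grid: schemes x tasks x (with / without entropy features).

    Returns ``{"cells": {(scheme, n_classes, linear_only): CVResults},
    "comparisons": {...}}`` where comparisons carries per-fold paired
    Wilcoxon signed-rank p-values of kappa between the two schemes (and
    between ablation arms), reported but never gated on.
    """
    from scipy.stats import wilcoxon

    cfg = cfg or TrainConfig()
    cells: Dict[Tuple, CVResults] = {}
    for wl in schemes:
        table_full = compute_feature_table(
            cohort, EpochScheme(window_len=wl), entropy_params=entropy_params
        )
        subjects = table_full["subject_id"].unique()
        folds = make_subject_folds(subjects, k=k_folds, seed=seed)
        for linear_only in ablations:
            table = (
                table_full.drop(columns=list(ENTROPY_FEATURES))
                if linear_only
                else table_full
            )
            for n_classes in tasks:
                task = make_task(n_classes)
                res = train_and_predict(
                    table, task, folds, cfg, seed=seed,
                    compute_importance=compute_importance,
                )
                imp = None
                if compute_importance:
                    imp = sum(r.importance for r in res) / len(res)
                cells[(str(wl), n_classes, linear_only)] = CVResults(
                    scheme=str(wl),
                    n_classes=n_classes,
                    linear_only=linear_only,
                    fold_acc=np.array([r.acc for r in res]),
                    fold_kappa=np.array([r.kappa for r in res]),
                    importance=imp,
                )
    comparisons: Dict = {}
    if len(schemes) == 2:
        a, b = (str(s) for s in schemes)
        for n_classes in tasks:
            for linear_only in ablations:
                ka = cells[(a, n_classes, linear_only)].fold_kappa
                kb = cells[(b, n_classes, linear_only)].fold_kappa
                if len(ka) == len(kb) and not np.allclose(ka, kb):
                    stat = wilcoxon(ka, kb)
                    comparisons[(f"{a}_vs_{b}", n_classes, linear_only)] = float(
                        stat.pvalue
                    )
    return {"cells": cells, "comparisons": comparisons}
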