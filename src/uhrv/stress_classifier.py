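"""Person-independent stress-detection harness.

The evaluation protocol is leakage-free by construction: subjects are split
60/40 into folder 1 (feature selection, training, 3-fold person-independent
cross-validation) and folder 2 (testing only), with both conditions of a
subject always in the same folder. Feature selection runs on folder-1 5-min
features only: a relevance step (paired Wilcoxon signed-rank, p < alpha)
followed by a redundancy step that keeps one representative per cluster of
mutually correlated features (|Spearman rho| > 0.7, connected components).

Five model families are searched (k-nearest neighbours, linear discriminant
analysis, an entropy-criterion decision tree, a polynomial-kernel SVM and a
one-hidden-layer perceptron); the grid winner is the highest mean
cross-validated AUC, ties broken by accuracy and then by the simpler model.
The winner is trained once on folder-1 5-min features, frozen, and assessed
on folder-2 features at every retained time scale, plus consecutive
non-overlapping windows at the shortest scale.

Features are z-scored with training-fold statistics inside every fit (kNN,
SVM, LDA and the perceptron are scale-sensitive). The positive class is
stress; hard labels use a 0.5 threshold on probability-like scores and 0 on
discriminant scores.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .surrogate_stats import spearman, wilcoxon_signed_rank

POSITIVE_CLASS = "stress"
META_COLUMNS = ("subject", "condition", "scale_s", "window_index")

# families ordered simplest-first for tie-breaking
_FAMILY_SIMPLICITY = {"lda": 0, "knn": 1, "tree": 2, "svm_poly": 3, "mlp": 4}


@dataclass(frozen=True)
class SubjectSplit:
    """Disjoint person-independent train/test folders of subject ids."""

    folder1: tuple[str, ...]
    folder2: tuple[str, ...]
    seed: int

    def __post_init__(self):
        if set(self.folder1) & set(self.folder2):
            raise ValueError("folders must be disjoint")


@dataclass(frozen=True)
class ModelSpec:
    """One point of the model grid."""

    family: str  # knn | lda | tree | svm_poly | mlp
    params: tuple[tuple[str, float], ...] = ()

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def simplicity_key(self):
        # fewer effective parameters first: family rank, then the raw
        # hyperparameter tuple (smaller values = simpler within a family)
        return (_FAMILY_SIMPLICITY[self.family], self.params)


@dataclass(frozen=True)
class EvalMetrics:
    """Binary performance of a model at one test time scale."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    scale_s: int

    def as_dict(self) -> dict:
        return {
            "scale_s": self.scale_s,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def default_model_grid(seed: int = 0) -> list[ModelSpec]:
    """The search grid over the five families."""
    grid: list[ModelSpec] = [ModelSpec("lda")]
    grid += [ModelSpec("knn", (("k", k),)) for k in (1, 3, 5)]
    grid += [ModelSpec("svm_poly", (("degree", d),)) for d in range(1, 6)]
    grid += [
        ModelSpec("tree", (("ccp_alpha", a), ("min_leaf", ml)))
        for a, ml in itertools.product((0.0, 0.01, 0.02), (2, 5, 10, 20))
    ]
    grid += [
        ModelSpec("mlp", (("lr", lr), ("momentum", mom)))
        for lr, mom in itertools.product((0.3, 0.6, 0.9), (0.2, 0.6, 1.0))
    ]
    return grid


def build_estimator(spec: ModelSpec, seed: int = 0) -> Pipeline:
    """sklearn pipeline for a grid point; z-scoring happens inside the fit."""
    p = spec.param_dict
    if spec.family == "knn":
        clf = KNeighborsClassifier(n_neighbors=int(p["k"]))
    elif spec.family == "lda":
        clf = LinearDiscriminantAnalysis()
    elif spec.family == "tree":
        clf = DecisionTreeClassifier(
            criterion="entropy",
            min_samples_leaf=int(p["min_leaf"]),
            ccp_alpha=float(p["ccp_alpha"]),
            random_state=seed,
        )
    elif spec.family == "svm_poly":
        clf = SVC(kernel="poly", degree=int(p["degree"]), coef0=1.0, C=1.0)
    elif spec.family == "mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=(3,),
            solver="sgd",
            learning_rate_init=float(p["lr"]),
            momentum=float(p["momentum"]),
            max_iter=2000,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown family {spec.family!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_subjects(subject_ids, fraction: float = 0.6, seed: int = 0) -> SubjectSplit:
    """Random per-subject 60/40 split; both conditions of a subject co-locate."""
    ids = sorted(set(map(str, subject_ids)))
    if len(ids) < 10:
        raise ValueError("need at least 10 subjects")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    n1 = int(round(fraction * len(ids)))
    return SubjectSplit(
        folder1=tuple(sorted(perm[:n1])),
        folder2=tuple(sorted(perm[n1:])),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def features_to_wide(long_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long feature table to one row per instance.

    Input columns: subject, condition, scale_s, window_index (NaN for the
    central placement), feature, value. Output: the four metadata columns
    followed by one column per feature.
    """
    df = long_df.copy()
    if "window_index" not in df:
        df["window_index"] = np.nan
    wide = df.pivot_table(
        index=["subject", "condition", "scale_s", "window_index"],
        columns="feature", values="value", aggfunc="first", dropna=False,
    ).reset_index()
    wide.columns.name = None
    return wide


def _select_rows(
    wide: pd.DataFrame, subjects, scale_s: int, window_index=None
) -> pd.DataFrame:
    m = wide["subject"].isin(subjects) & (wide["scale_s"] == scale_s)
    if window_index is None:
        m &= wide["window_index"].isna()
    else:
        m &= wide["window_index"] == window_index
    return wide[m]


def _xy(rows: pd.DataFrame, feature_names):
    X = rows[list(feature_names)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        bad = rows.index[~np.isfinite(X).any(axis=1)]
        raise ValueError(f"non-finite feature value in instances {list(bad)[:5]}")
    y = (rows["condition"] == POSITIVE_CLASS).to_numpy(dtype=int)
    groups = rows["subject"].to_numpy()
    return X, y, groups


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def select_features(
    folder1_wide: pd.DataFrame,
    candidates,
    alpha: float = 0.05,
    redundancy_rho: float = 0.7,
) -> list[str]:
    """Relevance (paired Wilcoxon) then redundancy (correlation clusters).

    Works on folder-1 5-min central-window features. Relevant candidates
    whose within-condition |Spearman rho| (averaged over rest and stress)
    exceeds redundancy_rho are linked into clusters (connected components);
    the representative of each cluster is the feature with the lowest
    relevance p-value, ties broken lexicographically.
    """
    candidates = list(candidates)
    rows = folder1_wide[
        (folder1_wide["scale_s"] == 300) & folder1_wide["window_index"].isna()
    ]
    rest = rows[rows["condition"] == "rest"].set_index("subject")
    stress = rows[rows["condition"] == "stress"].set_index("subject")
    common = rest.index.intersection(stress.index)
    p_values: dict[str, float] = {}
    for feat in candidates:
        paired = pd.DataFrame(
            {"rest": rest.loc[common, feat], "stress": stress.loc[common, feat]}
        ).dropna()
        p_values[feat] = wilcoxon_signed_rank(
            paired["rest"].values, paired["stress"].values
        )
    relevant = [f for f in candidates if p_values[f] < alpha]
    if not relevant:
        raise ValueError("no relevant features at the chosen alpha")

    # redundancy graph: correlation computed within each condition (pooling
    # conditions would let the stress shift itself link unrelated features)
    parent = {f: f for f in relevant}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for f1, f2 in itertools.combinations(relevant, 2):
        rhos = []
        for cond in ("rest", "stress"):
            vals = rows[rows["condition"] == cond][[f1, f2]].dropna()
            rho, _ = spearman(vals[f1], vals[f2])
            if rho is not None:
                rhos.append(abs(rho))
        if rhos and float(np.mean(rhos)) > redundancy_rho:
            parent[find(f1)] = find(f2)

    clusters: dict[str, list[str]] = {}
    for f in relevant:
        clusters.setdefault(find(f), []).append(f)
    chosen = [
        min(members, key=lambda f: (p_values[f], f))
        for members in clusters.values()
    ]
    return sorted(chosen, key=lambda f: (p_values[f], f))


# ---------------------------------------------------------------------------
# model selection and evaluation
# ---------------------------------------------------------------------------

def _person_folds(subjects, k: int, seed: int):
    """Partition unique subjects into k folds, shuffled by seed."""
    uniq = np.array(sorted(set(subjects)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    return np.array_split(perm, k)


def fit_predict(spec: ModelSpec, X_train, y_train, X_test, seed: int = 0):
    """Fit a grid point and score test instances.

    Returns (scores, labels): probability-like scores in [0, 1] for kNN,
    tree and the perceptron (stress-class probability) with labels at 0.5;
    discriminant values for LDA and the SVM margin, with labels at 0.
    """
    est = build_estimator(spec, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence noise on tiny folds
        est.fit(X_train, y_train)
    if spec.family in ("lda", "svm_poly"):
        scores = est.decision_function(X_test)
        labels = (scores >= 0.0).astype(int)
    else:
        scores = est.predict_proba(X_test)[:, 1]
        labels = (scores >= 0.5).astype(int)
    return np.asarray(scores, dtype=float), labels


def evaluate_binary(scores, labels, truth, scale_s: int = 300) -> EvalMetrics:
    """Sensitivity/specificity/accuracy from hard labels, AUC from scores.

    Stress (1) is the positive class; AUC is the rank statistic (probability
    a stress instance outscores a rest instance).
    """
    truth = np.asarray(truth, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(truth)) < 2:
        raise ValueError("truth must contain both classes")
    tp = int(np.sum((labels == 1) & (truth == 1)))
    fn = int(np.sum((labels == 0) & (truth == 1)))
    tn = int(np.sum((labels == 0) & (truth == 0)))
    fp = int(np.sum((labels == 1) & (truth == 0)))
    return EvalMetrics(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / len(truth),
        auc=float(roc_auc_score(truth, scores)),
        scale_s=scale_s,
    )


def cross_validate_select(
    X, y, groups, grid=None, k: int = 3, seed: int = 0
) -> tuple[ModelSpec, float]:
    """Pick the grid point with the highest mean person-independent CV AUC.

    Folds partition subjects, never instances. Ties go to higher mean
    accuracy, then to the simpler model. Degenerate folds (a single class)
    are refolded with a new seed, with a warning.
    """
    grid = default_model_grid(seed) if grid is None else list(grid)
    if not grid:
        raise ValueError("empty model grid")
    groups = np.asarray(groups)
    y = np.asarray(y, dtype=int)
    X = np.asarray(X, dtype=float)

    folds = _person_folds(groups, k, seed)
    for attempt in range(20):
        ok = True
        for fold_subjects in folds:
            te = np.isin(groups, fold_subjects)
            if len(np.unique(y[te])) < 2 or len(np.unique(y[~te])) < 2:
                ok = False
                break
        if ok:
            break
        warnings.warn("degenerate CV fold; refolding with a new seed")
        folds = _person_folds(groups, k, seed + attempt + 1)

    results = []
    for spec in grid:
        aucs, accs = [], []
        for fold_subjects in folds:
            te = np.isin(groups, fold_subjects)
            scores, labels = fit_predict(spec, X[~te], y[~te], X[te], seed)
            m = evaluate_binary(scores, labels, y[te])
            aucs.append(m.auc)
            accs.append(m.accuracy)
        results.append((float(np.mean(aucs)), float(np.mean(accs)), spec))
    # highest AUC, then highest accuracy, then the simpler model
    best = min(
        results,
        key=lambda r: (-r[0], -r[1], r[2].simplicity_key()),
    )
    return best[2], best[0]


def multiscale_assessment(
    spec: ModelSpec,
    wide: pd.DataFrame,
    split: SubjectSplit,
    feature_names,
    scales=(300, 180, 120, 60),
    consecutive_scale: int = 60,
    seed: int = 0,
) -> dict:
    """Train once on folder-1 5-min features, test across time scales.

    The frozen model is evaluated on folder-2 central windows at each scale
    and on the consecutive non-overlapping windows at ``consecutive_scale``
    (per-window metrics plus their mean and SD). Scales where a required
    feature is masked are skipped with a warning.
    """
    train_rows = _select_rows(wide, split.folder1, 300)
    X_tr, y_tr, _ = _xy(train_rows, feature_names)

    per_scale: dict[int, EvalMetrics] = {}
    for scale in scales:
        rows = _select_rows(wide, split.folder2, scale)
        if rows.empty or rows[list(feature_names)].isna().any().any():
            warnings.warn(f"scale {scale}s skipped: required feature masked")
            continue
        X_te, y_te, _ = _xy(rows, feature_names)
        scores, labels = fit_predict(spec, X_tr, y_tr, X_te, seed)
        per_scale[scale] = evaluate_binary(scores, labels, y_te, scale)

    windows: list[EvalMetrics] = []
    k = 0
    while True:
        rows = _select_rows(wide, split.folder2, consecutive_scale, window_index=k)
        if rows.empty:
            break
        if rows[list(feature_names)].isna().any().any():
            warnings.warn(f"window {k} skipped: required feature masked")
            k += 1
            continue
        X_te, y_te, _ = _xy(rows, feature_names)
        scores, labels = fit_predict(spec, X_tr, y_tr, X_te, seed)
        windows.append(evaluate_binary(scores, labels, y_te, consecutive_scale))
        k += 1

    summary = {}
    if windows:
        for key in ("sensitivity", "specificity", "accuracy", "auc"):
            vals = np.array([getattr(w, key) for w in windows])
            summary[key] = {
                "mean": float(vals.mean()), "sd": float(vals.std(ddof=1))
            }
    return {"per_scale": per_scale, "consecutive": windows,
            "consecutive_summary": summary}


def run_classification(
    features_long: pd.DataFrame,
    candidates,
    seed: int = 0,
    scales=(300, 180, 120, 60),
    consecutive_scale: int = 60,
    grid=None,
) -> dict:
    """Full harness: split, select features, pick a model by CV, assess.

    ``features_long`` is the long-format feature table of the whole cohort;
    ``candidates`` the surrogate-gate survivors eligible for selection.
    """
    wide = features_to_wide(features_long)
    split = split_subjects(wide["subject"].unique(), seed=seed)
    folder1 = _select_rows(wide, split.folder1, 300)
    selected = select_features(wide[wide["subject"].isin(split.folder1)], candidates)
    X, y, groups = _xy(folder1, selected)
    spec, cv_auc = cross_validate_select(X, y, groups, grid=grid, seed=seed)
    assessment = multiscale_assessment(
        spec, wide, split, selected, scales, consecutive_scale, seed
    )
    return {
        "split": split,
        "selected_features": selected,
        "model": spec,
        "cv_auc": cv_auc,
        "assessment": assessment,
    }
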