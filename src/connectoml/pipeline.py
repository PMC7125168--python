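"""The core classification procedure: stratified 80/20 split, 10-fold
cross-validation with nested recursive random-forest feature selection
(CV-SVM-rRF-FS), consensus edge list, final SVM with internal CV accuracy,
label-permutation significance test, and external ROC/AUC.

Leakage discipline: the external test subjects are split off before any
feature selection, model fitting or standardisation; every statistic used to
transform the test set is estimated on the training set alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset import CASE, CONTROL, ConnectomeDataset
from .rng import derive_int_seed, derive_rng
from .univariate import edge_ttest

__all__ = [
    "PipelineConfig",
    "SplitSpec",
    "stratified_split",
    "RRFResult",
    "rrf_fs",
    "FeatureSelectionResult",
    "cv_svm_rrf_fs",
    "filtered_training_space",
    "FinalModel",
    "train_final_svm",
    "PermutationResult",
    "permutation_test",
    "mann_whitney_auc",
    "roc_points",
    "EvaluationResult",
    "evaluate_test",
]


@dataclass
class PipelineConfig:
    """Every knob of the procedure, defaulting to the study settings.

    alpha 0.01 (raw p), 80/20 participant split, k = 10 folds, consensus at
    >= 5/10 folds, B = 99 permutations. The random-forest elimination uses
    300 trees — at ~30 training subjects every sample is out-of-bag in about
    a third of them, enough for a stable OOB ranking — drops the worst 20%
    of features per round down to a floor of 2, and keeps the set with
    minimal out-of-bag error (ties -> fewest features). The SVM is RBF with a small C x gamma grid chosen by inner CV
    on the training set.
    """

    alpha: float = 0.01
    fdr: bool = False
    test_fraction: float = 0.2
    k_folds: int = 10
    filter_scope: str = "train"  # "train" (leakage-safe) or "full"
    # recursive random-forest feature selection
    rf_trees: int = 300
    rf_drop_fraction: float = 0.2
    rf_floor: int = 2
    rf_importance: str = "gini"  # or "permutation"
    rf_perm_repeats: int = 5
    # consensus threshold in folds; None -> majority, i.e. ceil(k/2) (5 of 10)
    consensus_min_folds: int | None = None
    # final SVM
    svm_kernel: str = "rbf"
    svm_c_grid: tuple = (0.1, 1.0, 10.0)
    svm_gamma_grid: tuple = ("auto_inv", 0.01, 0.1)  # "auto_inv" -> 1 / n_features
    grid_folds: int = 5
    # permutation test
    n_permutations: int = 99

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2 (a single fold is degenerate)")
        if self.filter_scope not in ("train", "full"):
            raise ValueError("filter_scope must be 'train' or 'full'")
        if self.rf_importance not in ("gini", "permutation"):
            raise ValueError("rf_importance must be 'gini' or 'permutation'")
        if not 0 < self.rf_drop_fraction < 1:
            raise ValueError("rf_drop_fraction must lie in (0, 1)")
        if self.rf_floor < 1:
            raise ValueError("rf_floor must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if self.consensus_min_folds is not None and not (
            1 <= self.consensus_min_folds <= self.k_folds
        ):
            raise ValueError("consensus_min_folds must lie in [1, k_folds]")

    @property
    def consensus_threshold(self) -> int:
        if self.consensus_min_folds is not None:
            return self.consensus_min_folds
        return (self.k_folds + 1) // 2

    def to_dict(self) -> dict:
        return asdict(self)


# -- split -------------------------------------------------------------------


@dataclass
class SplitSpec:
    """A participant-level train/test partition."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    test_fraction: float

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test subjects overlap")


def stratified_split(
    dataset: ConnectomeDataset, test_fraction: float = 0.2, seed: int = 0
) -> SplitSpec:
    """Stratified participant split: round(f·n) test subjects overall,
    apportioned to classes by largest fractional remainder (23 + 21 subjects
    at f = 0.2 gives 5 case + 4 control in the test set)."""
    n = dataset.n_subjects
    n_test_total = int(round(test_fraction * n))
    if n_test_total < 2 or n - n_test_total < 2:
        raise ValueError(f"test fraction {test_fraction} infeasible for n={n}")
    rng = derive_rng(seed, "split")
    ids = np.array(dataset.subject_ids)
    per_class = {}
    for cls in (CONTROL, CASE):
        members = ids[dataset.labels == cls]
        if len(members) < 2:
            raise ValueError("each class needs >= 2 subjects to be split")
        per_class[cls] = members
    ideal = {cls: test_fraction * len(m) for cls, m in per_class.items()}
    base = {cls: int(np.floor(v)) for cls, v in ideal.items()}
    short = n_test_total - sum(base.values())
    order = sorted(per_class, key=lambda c: ideal[c] - base[c], reverse=True)
    for cls in order[:short]:
        base[cls] += 1
    for cls, take in base.items():
        if take == 0 or take >= len(per_class[cls]):
            raise ValueError(f"class {cls} cannot supply {take} test subjects")
    test_ids: list[str] = []
    for cls in (CONTROL, CASE):
        members = per_class[cls].copy()
        rng.shuffle(members)
        test_ids.extend(members[: base[cls]])
    test_set = set(test_ids)
    train_ids = [s for s in dataset.subject_ids if s not in test_set]
    test_ids = [s for s in dataset.subject_ids if s in test_set]
    return SplitSpec(train_ids=train_ids, test_ids=test_ids, seed=seed, test_fraction=test_fraction)


# -- recursive random-forest feature selection -------------------------------


@dataclass
class RRFResult:
    """One elimination run: the surviving set and the OOB-error path."""

    selected: np.ndarray  # column indices into the input X
    path_sizes: list[int]
    path_oob_error: list[float]
    path_features: list[np.ndarray]


def _importance(rf, X, y, config: PipelineConfig, seed: int) -> np.ndarray:
    if config.rf_importance == "gini":
        return rf.feature_importances_
    r = permutation_importance(
        rf, X, y, n_repeats=config.rf_perm_repeats, random_state=seed, n_jobs=1
    )
    return r.importances_mean


def rrf_fs(X, y, config: PipelineConfig | None = None, seed: int = 0) -> RRFResult:
    """Recursive random-forest elimination guided by out-of-bag error.

    Fit a forest on the current feature set, record its OOB error, drop the
    lowest-importance ``rf_drop_fraction`` of features, repeat until the
    floor; return the path point with minimal OOB error, breaking ties
    toward the smaller set.
    """
    config = config or PipelineConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if X.shape[1] < 2:
        raise ValueError("feature elimination needs at least 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    feats = np.arange(X.shape[1])
    sizes: list[int] = []
    errors: list[float] = []
    featsets: list[np.ndarray] = []
    round_no = 0
    while True:
        rs = derive_int_seed(seed, "rrf", f"round{round_no}")
        rf = RandomForestClassifier(
            n_estimators=config.rf_trees,
            oob_score=True,
            bootstrap=True,
            random_state=rs,
            n_jobs=1,
        )
        rf.fit(X[:, feats], y)
        sizes.append(len(feats))
        errors.append(1.0 - rf.oob_score_)
        featsets.append(feats.copy())
        if len(feats) <= config.rf_floor:
            break
        imp = _importance(rf, X[:, feats], y, config, rs)
        n_drop = max(1, int(round(len(feats) * config.rf_drop_fraction)))
        keep = max(config.rf_floor, len(feats) - n_drop)
        feats = np.sort(feats[np.argsort(imp)[::-1][:keep]])
        round_no += 1
    best = min(range(len(sizes)), key=lambda i: (errors[i], sizes[i]))
    return RRFResult(
        selected=featsets[best],
        path_sizes=sizes,
        path_oob_error=errors,
        path_features=featsets,
    )


# -- fold-level FS and consensus ---------------------------------------------


@dataclass
class FeatureSelectionResult:
    """Fold-level selections, per-edge frequencies and the consensus list."""

    fold_selections: list[np.ndarray]  # global edge ids per fold
    fold_oob_paths: list[tuple[list[int], list[float]]]
    selection_frequency: dict[int, int]  # global edge id -> folds selected
    consensus_edges: np.ndarray  # global edge ids, sorted
    input_space: str  # "all_edges" | "significant_edges"
    input_edge_ids: np.ndarray


def cv_svm_rrf_fs(
    train: ConnectomeDataset,
    config: PipelineConfig | None = None,
    seed: int = 0,
    input_space: str = "significant_edges",
) -> FeatureSelectionResult:
    """k-fold cross-validated recursive feature selection with consensus.

    Folds are stratified by class. In each fold the elimination runs on the
    fold-training portion only; the consensus list keeps edges selected in
    at least ``consensus_min_folds`` of the k folds.
    """
    config = config or PipelineConfig()
    y = train.labels
    if train.n_edges < 2:
        raise ValueError("feature selection needs at least 2 input edges")
    skf = StratifiedKFold(
        n_splits=config.k_folds, shuffle=True, random_state=derive_int_seed(seed, "folds")
    )
    fold_selections: list[np.ndarray] = []
    fold_paths: list[tuple[list[int], list[float]]] = []
    freq: dict[int, int] = {}
    for fold, (tr, _) in enumerate(skf.split(train.X, y)):
        res = rrf_fs(train.X[tr], y[tr], config, seed=derive_int_seed(seed, f"fold{fold}"))
        edge_ids = np.sort(train.edge_ids[res.selected])
        fold_selections.append(edge_ids)
        fold_paths.append((res.path_sizes, res.path_oob_error))
        for e in edge_ids:
            freq[int(e)] = freq.get(int(e), 0) + 1
    consensus = np.array(
        sorted(e for e, c in freq.items() if c >= config.consensus_threshold), dtype=int
    )
    return FeatureSelectionResult(
        fold_selections=fold_selections,
        fold_oob_paths=fold_paths,
        selection_frequency=freq,
        consensus_edges=consensus,
        input_space=input_space,
        input_edge_ids=train.edge_ids.copy(),
    )


def filtered_training_space(
    dataset: ConnectomeDataset,
    split: SplitSpec,
    config: PipelineConfig,
) -> ConnectomeDataset:
    """The training dataset restricted to the univariate filter's edges.

    With ``filter_scope='train'`` (default) the filter is recomputed on the
    training subjects only; ``'full'`` reproduces the descriptive full-sample
    filter for comparison.
    """
    train = dataset.select_subjects(split.train_ids)
    source = dataset if config.filter_scope == "full" else train
    res = edge_ttest(source, alpha=config.alpha, fdr=config.fdr)
    sig = res.significant_edges()
    return train.select_edges(sig)


# -- final SVM ----------------------------------------------------------------


@dataclass
class FinalModel:
    """The consensus-edge SVM with its internal CV evaluation."""

    consensus_edges: np.ndarray
    scaler: StandardScaler | None
    svm: SVC | None
    c: float | None
    gamma: float | None
    cv_accuracies: np.ndarray
    cv_mean: float
    cv_sd: float
    n_support_vectors: int
    no_signal: bool = False


def _gamma_value(g, n_features: int) -> float:
    return 1.0 / n_features if g == "auto_inv" else float(g)


def _make_svc(config: PipelineConfig, c: float, gamma: float) -> SVC:
    return SVC(kernel=config.svm_kernel, C=c, gamma=gamma)


def _grid_search(Xs, y, config: PipelineConfig, seed: int) -> tuple[float, float]:
    """Small inner grid over (C, gamma) by stratified CV accuracy."""
    n_splits = min(config.grid_folds, int(np.bincount(y).min()))
    n_splits = max(2, n_splits)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=derive_int_seed(seed, "grid"))
    best = None
    for c in config.svm_c_grid:
        for g in config.svm_gamma_grid:
            gamma = _gamma_value(g, Xs.shape[1])
            acc = cross_val_score(_make_svc(config, c, gamma), Xs, y, cv=skf).mean()
            key = (acc, -c, -gamma)  # ties -> smaller C then smaller gamma
            if best is None or key > best[0]:
                best = (key, c, gamma)
    return best[1], best[2]


def train_final_svm(
    train: ConnectomeDataset,
    consensus_edges,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> FinalModel:
    """Fit the final SVM on the consensus edges of the training set.

    Features are z-standardised with training statistics; hyperparameters
    come from a small inner grid; the internal evaluation is stratified
    k-fold CV accuracy (mean ± SD over folds) with the chosen
    hyperparameters. An empty consensus yields an explicit no-signal model.
    """
    config = config or PipelineConfig()
    consensus_edges = np.asarray(sorted(set(int(e) for e in consensus_edges)), dtype=int)
    if len(consensus_edges) == 0:
        return FinalModel(
            consensus_edges=consensus_edges,
            scaler=None,
            svm=None,
            c=None,
            gamma=None,
            cv_accuracies=np.array([]),
            cv_mean=0.5,
            cv_sd=0.0,
            n_support_vectors=0,
            no_signal=True,
        )
    sub = train.select_edges(consensus_edges)
    y = sub.labels
    scaler = StandardScaler().fit(sub.X)
    Xs = scaler.transform(sub.X)
    c, gamma = _grid_search(Xs, y, config, seed)
    svm = _make_svc(config, c, gamma).fit(Xs, y)
    skf = StratifiedKFold(
        n_splits=config.k_folds, shuffle=True, random_state=derive_int_seed(seed, "internal_cv")
    )
    accs = cross_val_score(
        Pipeline([("scale", StandardScaler()), ("svc", _make_svc(config, c, gamma))]),
        sub.X,
        y,
        cv=skf,
    )
    return FinalModel(
        consensus_edges=consensus_edges,
        scaler=scaler,
        svm=svm,
        c=c,
        gamma=gamma,
        cv_accuracies=accs,
        cv_mean=float(accs.mean()),
        cv_sd=float(accs.std(ddof=1)),
        n_support_vectors=int(svm.n_support_.sum()),
        no_signal=False,
    )


# -- permutation test ---------------------------------------------------------


@dataclass
class PermutationResult:
    observed: float
    null_accuracies: np.ndarray
    p_value: float
    n_permutations: int


def permutation_test(
    train: ConnectomeDataset,
    model: FinalModel,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation significance of the final model.

    The training labels are shuffled B times; for each shuffle the fixed
    model configuration (consensus edges, kernel, C, gamma) is refit and its
    internal CV accuracy recomputed. The add-one estimate
    ``p = (1 + #{null >= observed}) / (B + 1)`` has an attainable floor of
    exactly 1/(B+1) — 0.01 at the default B = 99.
    """
    config = config or PipelineConfig()
    if model.no_signal:
        raise ValueError("cannot permutation-test a no-signal model")
    sub = train.select_edges(model.consensus_edges)
    y = sub.labels
    rng = derive_rng(seed, "permutation")
    observed = model.cv_mean
    nulls = np.empty(config.n_permutations)
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svc", _make_svc(config, model.c, model.gamma))]
    )
    for b in range(config.n_permutations):
        y_perm = rng.permutation(y)
        if len(np.unique(y_perm)) < 2:  # cannot happen for a 2-class permutation
            nulls[b] = 0.5
            continue
        skf = StratifiedKFold(
            n_splits=config.k_folds,
            shuffle=True,
            random_state=derive_int_seed(seed, "permutation", f"b{b}"),
        )
        nulls[b] = cross_val_score(pipe, sub.X, y_perm, cv=skf).mean()
    p = (1.0 + np.sum(nulls >= observed)) / (config.n_permutations + 1.0)
    return PermutationResult(
        observed=observed,
        null_accuracies=nulls,
        p_value=float(p),
        n_permutations=config.n_permutations,
    )


# -- external evaluation -------------------------------------------------------


def mann_whitney_auc(scores, y) -> float:
    """AUC as the Mann–Whitney concordance probability, ties counted 0.5."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    n1 = int((y == CASE).sum())
    n0 = int((y == CONTROL).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes in the evaluation set")
    ranks = stats.rankdata(scores)
    r1 = ranks[y == CASE].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_points(scores, y) -> np.ndarray:
    """ROC curve (FPR, TPR) at thresholds set by the distinct scores.

    Starts at (0, 0), ends at (1, 1), monotone in both coordinates; its
    trapezoidal integral equals the Mann–Whitney AUC.
    """
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    n1 = int((y == CASE).sum())
    n0 = int((y == CONTROL).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both classes")
    pts = [(0.0, 0.0)]
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        tpr = float((pred & (y == CASE)).sum()) / n1
        fpr = float((pred & (y == CONTROL)).sum()) / n0
        pts.append((fpr, tpr))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return np.array(pts)


@dataclass
class EvaluationResult:
    """External-test ROC/AUC for one trained model."""

    scores: np.ndarray  # decision values per test subject
    labels: np.ndarray
    roc: np.ndarray  # (m, 2) FPR/TPR points
    auc: float
    no_signal: bool = False


def evaluate_test(
    model: FinalModel, test: ConnectomeDataset
) -> EvaluationResult:
    """Score the held-out subjects with the trained model.

    Test features are restricted to the consensus edges and transformed with
    the *training* standardisation; a no-signal model scores every subject
    identically, which collapses to chance (AUC 0.5).
    """
    y = test.labels
    if len(np.unique(y)) < 2:
        raise ValueError("external evaluation needs both classes in the test set")
    if model.no_signal:
        scores = np.zeros(test.n_subjects)
        return EvaluationResult(
            scores=scores,
            labels=y.copy(),
            roc=roc_points(scores, y),
            auc=0.5,
            no_signal=True,
        )
    sub = test.select_edges(model.consensus_edges)
    scores = model.svm.decision_function(model.scaler.transform(sub.X))
    return EvaluationResult(
        scores=scores,
        labels=y.copy(),
        roc=roc_points(scores, y),
        auc=mann_whitney_auc(scores, y),
    )
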