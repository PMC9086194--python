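"""Selection metrics, classifier integration, cross-validation and the benchmark.

Metrics follow the usual conventions for feature-selection benchmarking on
synthetic data with known causal variables: per-replicate FDR / sensitivity /
F1, Jaccard stability across replicate pairs, per-variable empirical power, and
— for real data where ground truth is unknown — a weighted relative selection
frequency (WRF) across cross-validation folds.  The classifier stage feeds the
selected features into eight standard classifiers and reports held-out accuracy
and AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .base_selectors import SelectorConfig, run_selector
from .ensemble import EnsembleConfig, ensemble_select
from .simulation import SimulationScenario, make_replicate_pairs

__all__ = [
    "SelectionMetrics",
    "selection_metrics",
    "jaccard_index",
    "jaccard_stability",
    "empirical_power",
    "weighted_relative_frequency",
    "classify",
    "cross_validated_selection",
    "run_benchmark",
    "CLASSIFIERS",
]


@dataclass
class SelectionMetrics:
    """FDR, sensitivity, precision and F1 of one selected set vs. ground truth."""

    fdr: float
    sensitivity: float
    precision: float
    f1: float
    n_selected: int
    n_causal: int


def selection_metrics(selected, causal, G: int) -> SelectionMetrics:
    """Score a selected feature set against the known causal set.

    FDR = false positives / selected (0 for an empty selection, by convention);
    sensitivity = true positives / causal; precision = 1 - FDR;
    F1 = harmonic mean of precision and sensitivity (0 when both are 0).
    """
    selected = set(map(int, selected))
    causal = set(map(int, causal))
    if not causal:
        raise ValueError("causal set must be nonempty")
    if selected and (min(selected) < 0 or max(selected) >= G):
        raise IndexError("selected indices out of range 0..G-1")
    if selected:
        tp = len(selected & causal)
        fdr = (len(selected) - tp) / len(selected)
        sens = tp / len(causal)
    else:
        fdr, sens = 0.0, 0.0
    prec = 1.0 - fdr
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) > 0 else 0.0
    return SelectionMetrics(
        fdr=fdr, sensitivity=sens, precision=prec, f1=f1,
        n_selected=len(selected), n_causal=len(causal),
    )


def jaccard_index(a, b) -> float:
    """|A n B| / |A u B|; two empty sets count as perfectly stable (1)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


@dataclass
class StabilityReport:
    pairwise: np.ndarray
    mean: float


def jaccard_stability(selection_pairs: list[tuple[set, set]]) -> StabilityReport:
    """Mean Jaccard index over (replicate, paired replicate) selections."""
    if not selection_pairs:
        raise ValueError("need at least one selection pair")
    vals = np.array([jaccard_index(a, b) for a, b in selection_pairs])
    return StabilityReport(pairwise=vals, mean=float(vals.mean()))


def empirical_power(selections: list, causal) -> pd.Series:
    """Per causal variable: fraction of replicates in which it was selected."""
    causal = sorted(set(map(int, causal)))
    if not selections:
        raise ValueError("need at least one replicate selection")
    counts = {c: 0 for c in causal}
    for sel in selections:
        s = set(map(int, sel))
        for c in causal:
            if c in s:
                counts[c] += 1
    return pd.Series(
        {c: counts[c] / len(selections) for c in causal}, name="power"
    )


def weighted_relative_frequency(fold_selections: list, G: int | None = None) -> dict:
    """WRF_j = sum over folds of (membership of j) / (fold selection size).

    Features carrying weight only through folds that selected them; an empty
    fold contributes nothing.  Returns {feature: WRF} for every feature that
    appears in at least one fold (absent features have WRF 0), plus zeros for
    0..G-1 when ``G`` is given.
    """
    if not fold_selections:
        raise ValueError("need at least one fold selection")
    wrf: dict = {}
    if G is not None:
        wrf = {j: 0.0 for j in range(G)}
    for fold in fold_selections:
        fold = list(fold)
        if not fold:
            continue
        w = 1.0 / len(fold)
        for f in fold:
            wrf[f] = wrf.get(f, 0.0) + w
    return wrf


# ---------------------------------------------------------------------------
# classifiers


def _classifier_grid(method: str, seed: int):
    """Estimator + small hyperparameter grid for one of the eight classifiers."""
    if method == "svm_linear":
        return SVC(kernel="linear"), {"C": [0.1, 1, 10]}
    if method == "svm_poly":
        return SVC(kernel="poly", degree=3), {"C": [0.1, 1, 10]}
    if method == "svm_rbf":
        return SVC(kernel="rbf"), {"C": [0.1, 1, 10], "gamma": ["scale"]}
    if method == "knn":
        return KNeighborsClassifier(), {"n_neighbors": [3, 5, 7]}
    if method == "rf":
        return (
            RandomForestClassifier(n_estimators=300, random_state=seed),
            {"max_features": ["sqrt", None]},
        )
    if method == "xgb":
        from xgboost import XGBClassifier

        return (
            XGBClassifier(
                n_estimators=100, verbosity=0, random_state=seed,
                eval_metric="logloss",
            ),
            {"max_depth": [2, 4]},
        )
    if method == "ridge":
        return (
            LogisticRegression(l1_ratio=0.0, solver="lbfgs", max_iter=2000),
            {"C": [0.01, 0.1, 1, 10]},
        )
    if method == "lasso":
        return (
            LogisticRegression(l1_ratio=1.0, solver="liblinear", max_iter=2000),
            {"C": [0.01, 0.1, 1, 10]},
        )
    raise KeyError(f"unknown classifier {method!r}")


CLASSIFIERS = (
    "svm_linear", "svm_poly", "svm_rbf", "knn", "rf", "xgb", "ridge", "lasso",
)


def _scores(clf, X) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


def classify(
    X_train, y_train, X_test, y_test, features, method: str, seed: int = 0,
    cv_folds: int = 5,
) -> dict:
    """Fit one classifier on the selected features and score the held-out data.

    Hyperparameters are tuned by a small stratified CV grid on the training
    data.  Accuracy uses a 0.5 score cutoff (the classifier's label rule);
    AUC uses continuous scores with midrank tie handling.  An empty feature
    set degrades to a majority-class prediction with a warning.
    """
    y_train = np.asarray(y_train).astype(int).ravel()
    y_test = np.asarray(y_test).astype(int).ravel()
    features = np.asarray(sorted(set(map(int, features))), dtype=int)
    if features.size == 0:
        warnings.warn("empty feature set: falling back to majority class")
        maj = int(np.bincount(y_train).argmax())
        acc = float((y_test == maj).mean())
        return {"classifier": method, "accuracy": acc, "auc": 0.5, "n_features": 0}
    Xtr = np.asarray(X_train, dtype=float)[:, features]
    Xte = np.asarray(X_test, dtype=float)[:, features]
    est, grid = _classifier_grid(method, seed)
    n_splits = min(cv_folds, int(np.bincount(y_train).min()))
    if n_splits >= 2 and sum(len(v) for v in grid.values()) > len(grid):
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        search = GridSearchCV(est, grid, cv=cv, scoring="accuracy", n_jobs=1)
        search.fit(Xtr, y_train)
        clf = search.best_estimator_
    else:
        clf = est
        clf.fit(Xtr, y_train)
    pred = clf.predict(Xte)
    acc = float((pred == y_test).mean())
    if len(np.unique(y_test)) < 2:
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y_test, _scores(clf, Xte)))
    return {
        "classifier": method, "accuracy": acc, "auc": auc,
        "n_features": int(features.size),
    }


# ---------------------------------------------------------------------------
# cross-validated selection on real-style data


def _run_any_selector(name, X, y, seed, selector_config, ensemble_config):
    if name == "ensemble":
        res = ensemble_select(X, y, config=ensemble_config, seed=seed)
        return set(map(int, res.selected_features))
    out = run_selector(name, X, y, cfg=selector_config, seed=seed)
    return out.selected_set


def cross_validated_selection(
    X,
    y,
    selector: str = "ensemble",
    folds: int = 5,
    seed: int = 0,
    selector_config: SelectorConfig | None = None,
    ensemble_config: EnsembleConfig | None = None,
    classifiers: tuple[str, ...] = (),
    min_fold_count: int = 2,
) -> dict:
    """Stratified k-fold pipeline: select on k-1 folds, score on the held-out fold.

    Returns fold selections, the WRF table, a headline set of features selected
    in at least ``min_fold_count`` folds, and (optionally) per-classifier
    held-out accuracy/AUC averaged over folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    selector_config = selector_config or SelectorConfig()
    ensemble_config = ensemble_config or EnsembleConfig(selector=selector_config)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(folds)]

    fold_selections: list[set[int]] = []
    pred_rows = []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        sel = _run_any_selector(
            selector, X[tr], y[tr], fold_seeds[f], selector_config, ensemble_config
        )
        fold_selections.append(sel)
        for clf in classifiers:
            row = classify(
                X[tr], y[tr], X[te], y[te], sorted(sel), clf, seed=fold_seeds[f]
            )
            row["fold"] = f
            pred_rows.append(row)

    wrf = weighted_relative_frequency(fold_selections, G=X.shape[1])
    counts = {}
    for s in fold_selections:
        for j in s:
            counts[j] = counts.get(j, 0) + 1
    headline = sorted(j for j, c in counts.items() if c >= min_fold_count)
    return {
        "selector": selector,
        "fold_selections": fold_selections,
        "wrf": wrf,
        "selected": headline,
        "predictions": pd.DataFrame(pred_rows) if pred_rows else pd.DataFrame(),
    }


# ---------------------------------------------------------------------------
# simulation benchmark harness


def run_benchmark(
    scenarios: list[SimulationScenario],
    selectors: tuple[str, ...],
    n_pairs: int,
    master_seed: int,
    classifiers: tuple[str, ...] = (),
    selector_config: SelectorConfig | None = None,
    ensemble_config: EnsembleConfig | None = None,
) -> pd.DataFrame:
    """Scenario x selector benchmark on paired synthetic replicates.

    For each pair, every selector runs on both members: the first member's
    selection is scored for FDR/sensitivity/F1 against the known causal set
    and used to train classifiers scored on the second member; the Jaccard
    index between the two members' selections measures stability.  Returns a
    long-format table (scenario, selector, classifier, replicate, metric,
    value); a failing selector yields NaN cells rather than aborting the run.
    """
    selector_config = selector_config or SelectorConfig()
    ensemble_config = ensemble_config or EnsembleConfig(selector=selector_config)
    rows = []
    ss = np.random.SeedSequence(master_seed)
    for sc in scenarios:
        sc_seq = ss.spawn(1)[0]
        pairs = make_replicate_pairs(
            sc, n_pairs, int(sc_seq.generate_state(1)[0] % 2**31)
        )
        run_seqs = sc_seq.spawn(n_pairs * len(selectors))
        k = 0
        for rep, (train, test) in enumerate(pairs):
            causal = train.causal_indices
            for name in selectors:
                seeds = [
                    int(s.generate_state(1)[0] % 2**31)
                    for s in run_seqs[k].spawn(2)
                ]
                k += 1
                try:
                    sel_a = _run_any_selector(
                        name, train.X, train.y, seeds[0],
                        selector_config, ensemble_config,
                    )
                    sel_b = _run_any_selector(
                        name, test.X, test.y, seeds[1],
                        selector_config, ensemble_config,
                    )
                except Exception as exc:  # recorded, not fatal
                    warnings.warn(f"{name} failed on {sc.label} rep {rep}: {exc}")
                    rows.append(
                        dict(scenario=sc.label, selector=name, classifier="",
                             replicate=rep, metric="error", value=np.nan)
                    )
                    continue
                m = selection_metrics(sel_a, causal, sc.G)
                jac = jaccard_index(sel_a, sel_b)
                for metric, value in (
                    ("fdr", m.fdr), ("sensitivity", m.sensitivity),
                    ("f1", m.f1), ("n_selected", m.n_selected),
                    ("stability", jac),
                ):
                    rows.append(
                        dict(scenario=sc.label, selector=name, classifier="",
                             replicate=rep, metric=metric, value=float(value))
                    )
                for j in sorted(sel_a):
                    rows.append(
                        dict(scenario=sc.label, selector=name, classifier="",
                             replicate=rep, metric="selected_feature",
                             value=float(j))
                    )
                for clf in classifiers:
                    r = classify(
                        train.X, train.y, test.X, test.y, sorted(sel_a), clf,
                        seed=seeds[0],
                    )
                    rows.append(
                        dict(scenario=sc.label, selector=name, classifier=clf,
                             replicate=rep, metric="accuracy", value=r["accuracy"])
                    )
                    rows.append(
                        dict(scenario=sc.label, selector=name, classifier=clf,
                             replicate=rep, metric="auc", value=r["auc"])
                    )
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of each metric per scenario x selector (x classifier)."""
    t = table[~table.metric.isin(["selected_feature", "error"])]
    return (
        t.groupby(["scenario", "selector", "classifier", "metric"])["value"]
        .mean()
        .unstack("metric")
        .reset_index()
    )
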