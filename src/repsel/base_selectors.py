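"""Six classical feature selectors emitting a standardized output.

Each selector consumes a numeric feature matrix ``X`` (n samples x G features)
and a binary label vector ``y`` and returns a :class:`SelectorOutput` that is
either a subset of feature indices, an ordered subset, or a full ranking.  The
standardization is what lets heterogeneous selectors feed a rank-aggregation
ensemble.

The roster: information gain (univariate filter), correlation-based feature
selection / CFS (multivariate filter), SVM-RFE (wrapper), Boruta and Vita
(random-forest wrappers), and the lasso (embedded).  Boruta, Vita, CFS and
multi-fold SVM-RFE are implemented here on top of scikit-learn primitives;
the aim is contract-level equivalence with the well-known R implementations,
not byte-level reproduction of their internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "SelectorOutput",
    "SelectorConfig",
    "info_gain_rank",
    "cfs_select",
    "svm_rfe_rank",
    "boruta_select",
    "vita_select",
    "lasso_select",
    "SELECTORS",
    "run_selector",
]


@dataclass
class SelectorOutput:
    """Standardized result of one base selector.

    ``output_type`` is one of ``subset`` (unordered feature set), ``ordered_subset``
    (best-first order meaningful) or ``ranking`` (full rank vector, 1 = best).
    ``selected`` holds 0-based feature indices.  A ranking selector may also
    expose its top slice through ``selected``.
    """

    method: str
    output_type: str
    G: int
    selected: np.ndarray | None = None
    ranks: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.output_type not in ("subset", "ordered_subset", "ranking"):
            raise ValueError(f"unknown output_type {self.output_type!r}")
        if self.selected is not None:
            self.selected = np.asarray(self.selected, dtype=np.int64)
            if self.selected.size and (
                self.selected.min() < 0 or self.selected.max() >= self.G
            ):
                raise ValueError("selected indices out of range 0..G-1")
        if self.ranks is not None:
            self.ranks = np.asarray(self.ranks, dtype=np.int64)
            if self.ranks.shape != (self.G,):
                raise ValueError("ranks must have length G")
            if self.ranks.size and (self.ranks.min() < 1 or self.ranks.max() > self.G):
                raise ValueError("ranks must lie in 1..G")
        if self.output_type == "ranking" and self.ranks is None:
            raise ValueError("ranking output requires ranks")
        if self.output_type in ("subset", "ordered_subset") and self.selected is None:
            raise ValueError("subset output requires selected")

    @property
    def selected_set(self) -> set[int]:
        return set() if self.selected is None else set(self.selected.tolist())

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "output_type": self.output_type,
            "G": self.G,
            "selected": None if self.selected is None else self.selected.tolist(),
            "ranks": None if self.ranks is None else self.ranks.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectorOutput":
        return cls(
            method=d["method"],
            output_type=d["output_type"],
            G=d["G"],
            selected=None if d.get("selected") is None else np.asarray(d["selected"]),
            ranks=None if d.get("ranks") is None else np.asarray(d["ranks"]),
        )


@dataclass
class SelectorConfig:
    """Tunables for the base selectors.

    ``top_fraction`` drives the information-gain and SVM-RFE subset size
    (0.05 x G); ``cv_folds`` the Vita / SVM-RFE fold count; the lasso grid is
    10^(-10, -9.9, ..., 10).  Random-forest sizes and the Boruta iteration cap
    are compute knobs: 500 trees / 100 iterations mirror common defaults, while
    benchmark harnesses may pass lighter values.
    """

    top_fraction: float = 0.05
    cv_folds: int = 5
    n_bins: int = 10  # info-gain discretization (equal-frequency)
    rf_trees: int = 500
    boruta_max_iter: int = 100
    boruta_alpha: float = 0.01
    boruta_keep_tentative: bool = True
    vita_p_threshold: float = 0.0
    lasso_grid_exponents: tuple[float, float, float] = (-10.0, 10.0, 0.1)
    lasso_grid_floor_ratio: float = 1e-4
    svm_C: float = 1.0
    rfe_step_fraction: float = 0.10
    cfs_max_fails: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def top_k(self, G: int) -> int:
        return max(1, int(round(self.top_fraction * G)))


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(np.int64).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y disagree on the number of samples")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    return X, y


def _rng(cfg: SelectorConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(cfg.seed if seed is None else seed)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# information gain


def info_gain_rank(X, y, cfg: SelectorConfig | None = None, seed: int | None = None) -> SelectorOutput:
    """Rank features by information gain H(y) - H(y | binned feature).

    Features are discretized into equal-frequency bins (duplicate bin edges
    collapsed, so constant features land in a single bin and score 0).  The top
    ``top_fraction x G`` features are also exposed as an ordered subset.
    """
    cfg = cfg or SelectorConfig()
    X, y = _check_xy(X, y)
    n, G = X.shape
    h_y = _entropy(np.bincount(y))
    gains = np.empty(G)
    qs = np.linspace(0, 1, cfg.n_bins + 1)[1:-1]
    for j in range(G):
        edges = np.unique(np.quantile(X[:, j], qs))
        bins = np.searchsorted(edges, X[:, j], side="right")
        h_cond = 0.0
        for b in np.unique(bins):
            m = bins == b
            h_cond += m.mean() * _entropy(np.bincount(y[m]))
        gains[j] = h_y - h_cond
    # rank 1 = highest gain; stable tie-break by index
    order = np.lexsort((np.arange(G), -gains))
    ranks = np.empty(G, dtype=np.int64)
    ranks[order] = np.arange(1, G + 1)
    k = cfg.top_k(G)
    return SelectorOutput(
        method="info_gain", output_type="ranking", G=G,
        ranks=ranks, selected=order[:k],
    )


# ---------------------------------------------------------------------------
# CFS


def _cfs_merit(k: int, mean_fy: float, mean_ff: float) -> float:
    denom = np.sqrt(k + k * (k - 1) * mean_ff)
    return k * mean_fy / denom if denom > 0 else 0.0


def cfs_select(X, y, cfg: SelectorConfig | None = None, seed: int | None = None) -> SelectorOutput:
    """Correlation-based feature selection with greedy best-first search.

    Maximizes merit = k * mean|corr(f, y)| / sqrt(k + k (k-1) * mean|corr(f, f')|):
    features individually correlated with the label but mutually uncorrelated.
    Search stops after ``cfs_max_fails`` consecutive non-improving additions.
    Zero-variance features are skipped.
    """
    cfg = cfg or SelectorConfig()
    X, y = _check_xy(X, y)
    n, G = X.shape
    sd = X.std(axis=0)
    usable = np.flatnonzero(sd > 0)
    Xs = (X[:, usable] - X[:, usable].mean(axis=0)) / sd[usable]
    yc = y - y.mean()
    ysd = yc.std()
    r_fy = np.abs(Xs.T @ yc / (n * ysd)) if ysd > 0 else np.zeros(len(usable))

    selected: list[int] = []
    sum_fy = 0.0
    sum_ff = 0.0  # sum over unordered selected pairs of |corr|
    best_merit = 0.0
    fails = 0
    remaining = set(range(len(usable)))
    corr_cache: dict[int, np.ndarray] = {}

    while remaining and fails < cfg.cfs_max_fails:
        best_j, best_m = -1, -np.inf
        for j in remaining:
            k = len(selected) + 1
            add_ff = 0.0
            if selected:
                if j not in corr_cache:
                    corr_cache[j] = np.abs(Xs.T @ Xs[:, j]) / n
                add_ff = float(corr_cache[j][selected].sum())
            mean_fy = (sum_fy + r_fy[j]) / k
            n_pairs = k * (k - 1) / 2
            mean_ff = (sum_ff + add_ff) / n_pairs if n_pairs else 0.0
            m = _cfs_merit(k, mean_fy, mean_ff)
            if m > best_m:
                best_m, best_j = m, j
        if best_m > best_merit + 1e-12:
            best_merit = best_m
            if selected:
                if best_j not in corr_cache:
                    corr_cache[best_j] = np.abs(Xs.T @ Xs[:, best_j]) / n
                sum_ff += float(corr_cache[best_j][selected].sum())
            sum_fy += r_fy[best_j]
            selected.append(best_j)
            remaining.discard(best_j)
            fails = 0
        else:
            fails += 1
            remaining.discard(best_j)
    return SelectorOutput(
        method="cfs", output_type="ordered_subset", G=G,
        selected=usable[np.asarray(selected, dtype=np.int64)] if selected else np.empty(0, np.int64),
    )


# ---------------------------------------------------------------------------
# SVM-RFE


def svm_rfe_rank(X, y, cfg: SelectorConfig | None = None, seed: int | None = None) -> SelectorOutput:
    """Multi-fold SVM recursive feature elimination.

    At each step a linear SVM is fitted on each of ``cv_folds`` stratified folds
    (on the fold's training part); the squared weights, normalized per fold,
    are averaged and the lowest-scoring ``rfe_step_fraction`` of the surviving
    features is dropped — one at a time once fewer than ``2 * top_k`` remain.
    The elimination order defines the ranking (last survivor = rank 1); ties
    within an eliminated chunk are ordered by score.
    """
    cfg = cfg or SelectorConfig()
    X, y = _check_xy(X, y)
    rng = _rng(cfg, seed)
    n, G = X.shape
    k_top = cfg.top_k(G)
    skf = StratifiedKFold(
        n_splits=min(cfg.cv_folds, int(np.bincount(y).min())),
        shuffle=True, random_state=int(rng.integers(2**31)),
    )
    folds = [tr for tr, _ in skf.split(X, y)]

    surviving = np.arange(G)
    elim_order: list[np.ndarray] = []  # chunks, first eliminated first
    while surviving.size > 1:
        scores = np.zeros(surviving.size)
        for tr in folds:
            svm = SVC(kernel="linear", C=cfg.svm_C)
            svm.fit(X[np.ix_(tr, surviving)], y[tr])
            w2 = np.ravel(np.asarray(svm.coef_)) ** 2
            norm = w2.sum()
            scores += w2 / norm if norm > 0 else w2
        scores /= len(folds)
        if surviving.size > 2 * k_top:
            n_drop = max(1, int(np.floor(cfg.rfe_step_fraction * surviving.size)))
            n_drop = min(n_drop, surviving.size - 2 * k_top) or 1
        else:
            n_drop = 1
        # drop lowest scores; ties broken by feature index for determinism
        order = np.lexsort((surviving, scores))
        drop = order[:n_drop]
        # within the chunk, worse score = eliminated "earlier" = worse rank
        elim_order.append(surviving[drop])
        surviving = np.delete(surviving, drop)
    elim_order.append(surviving)

    ranks = np.empty(G, dtype=np.int64)
    pos = G
    for chunk in elim_order:
        for f in chunk:
            ranks[f] = pos
            pos -= 1
    order = np.argsort(ranks, kind="stable")
    return SelectorOutput(
        method="svm_rfe", output_type="ranking", G=G,
        ranks=ranks, selected=order[:k_top],
    )


# ---------------------------------------------------------------------------
# Boruta


def boruta_select(X, y, cfg: SelectorConfig | None = None, seed: int | None = None) -> SelectorOutput:
    """Boruta: shadow-feature relevance testing with random forests.

    Each iteration appends a column-shuffled ("shadow") copy of every still-
    undecided-or-confirmed feature, fits a random forest, and scores a "hit"
    for features whose impurity importance exceeds the best shadow importance.
    Sequential two-sided binomial tests at ``boruta_alpha`` confirm or reject;
    whatever remains undecided at the iteration cap is Tentative.  The returned
    subset is Confirmed plus (by default) Tentative.
    """
    cfg = cfg or SelectorConfig()
    X, y = _check_xy(X, y)
    rng = _rng(cfg, seed)
    n, G = X.shape

    CONFIRMED, REJECTED, UNDECIDED = 1, -1, 0
    status = np.zeros(G, dtype=np.int64)
    hits = np.zeros(G, dtype=np.int64)
    trials = 0
    for _ in range(cfg.boruta_max_iter):
        active = np.flatnonzero(status != REJECTED)
        if not np.any(status == UNDECIDED):
            break
        Xa = X[:, active]
        shadow = Xa.copy()
        for c in range(shadow.shape[1]):
            rng.shuffle(shadow[:, c])
        rf = RandomForestClassifier(
            n_estimators=cfg.rf_trees,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        rf.fit(np.hstack([Xa, shadow]), y)
        imp = rf.feature_importances_
        real_imp, shadow_max = imp[: active.size], imp[active.size:].max()
        hits[active[real_imp > shadow_max]] += 1
        trials += 1
        und = np.flatnonzero(status == UNDECIDED)
        p_hi = stats.binom.sf(hits[und] - 1, trials, 0.5)   # P(>= hits)
        p_lo = stats.binom.cdf(hits[und], trials, 0.5)      # P(<= hits)
        status[und[p_hi < cfg.boruta_alpha / 2]] = CONFIRMED
        status[und[p_lo < cfg.boruta_alpha / 2]] = REJECTED

    keep = status == CONFIRMED
    if cfg.boruta_keep_tentative:
        keep |= status == UNDECIDED
    return SelectorOutput(
        method="boruta", output_type="subset", G=G, selected=np.flatnonzero(keep),
    )


# ---------------------------------------------------------------------------
# Vita


def vita_select(X, y, cfg: SelectorConfig | None = None, seed: int | None = None) -> SelectorOutput:
    """Vita: cross-validated permutation importance with a mirrored empirical null.

    A random forest is fitted on each of ``cv_folds`` training portions and each
    feature's importance is the drop in held-out correct-class probability when
    that feature is permuted in the held-out fold, summed over folds (the
    probability scale keeps the importance continuous even on small held-out
    folds).  The null distribution is the non-positive importances mirrored
    about zero; features whose empirical p-value equals the configured
    threshold (0: importance strictly above every null value) are selected.
    """
    cfg = cfg or SelectorConfig()
    X, y = _check_xy(X, y)
    rng = _rng(cfg, seed)
    n, G = X.shape
    skf = StratifiedKFold(
        n_splits=min(cfg.cv_folds, int(np.bincount(y).min())),
        shuffle=True, random_state=int(rng.integers(2**31)),
    )
    importance = np.zeros(G)
    for tr, te in skf.split(X, y):
        rf = RandomForestClassifier(
            n_estimators=cfg.rf_trees,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        rf.fit(X[tr], y[tr])
        Xte, yte = X[te], y[te]
        base_score = rf.predict_proba(Xte)[np.arange(te.size), yte].mean()
        m = te.size
        # one stacked predict per chunk of features instead of G separate calls
        chunk = max(1, min(G, int(5e6 / (m * G))))
        for start in range(0, G, chunk):
            js = range(start, min(start + chunk, G))
            big = np.repeat(Xte[None, :, :], len(js), axis=0)  # (c, m, G)
            for t, j in enumerate(js):
                big[t, :, j] = Xte[rng.permutation(m), j]
            prob = rf.predict_proba(big.reshape(-1, G))[:, 1].reshape(len(js), m)
            correct = np.where(yte[None, :] == 1, prob, 1.0 - prob).mean(axis=1)
            importance[list(js)] += base_score - correct

    nonpos = importance[importance <= 0]
    null = np.concatenate([nonpos, -nonpos])
    if null.size == 0:
        pvals = np.zeros(G)
    else:
        # empirical p: fraction of null values >= importance
        pvals = np.searchsorted(np.sort(null), importance, side="left")
        pvals = 1.0 - pvals / null.size
    selected = np.flatnonzero((pvals <= cfg.vita_p_threshold) & (importance > 0))
    return SelectorOutput(method="vita", output_type="subset", G=G, selected=selected)


# ---------------------------------------------------------------------------
# lasso


def lasso_grid(cfg: SelectorConfig) -> np.ndarray:
    lo, hi, step = cfg.lasso_grid_exponents
    exps = np.arange(lo, hi + step / 2, step)
    return 10.0 ** exps


def lasso_select(X, y, cfg: SelectorConfig | None = None, seed: int | None = None) -> SelectorOutput:
    """L1-penalized logistic regression; lambda picked by CV binomial deviance.

    The lambda grid is 10^(-10, -9.9, ..., 10).  Grid points above the data's
    lambda_max (where the model is provably intercept-only) are collapsed into
    one representative, and points below ``lasso_grid_floor_ratio * lambda_max``
    (where the fit has saturated) are skipped, so the CV loop touches only the
    informative stretch of the grid.  The subset is the nonzero support at the
    CV-chosen lambda refitted on the full data.
    """
    cfg = cfg or SelectorConfig()
    X, y = _check_xy(X, y)
    rng = _rng(cfg, seed)
    n, G = X.shape
    grid = np.sort(lasso_grid(cfg))[::-1]  # decreasing

    ybar = y.mean()
    lam_max = np.abs(X.T @ (y - ybar)).max() / n  # glmnet-scale lambda
    active_grid = grid[(grid <= lam_max) & (grid >= cfg.lasso_grid_floor_ratio * lam_max)]
    if active_grid.size == 0:
        active_grid = grid[grid <= lam_max][:1]
    # one representative for the all-null upper stretch
    null_reps = grid[grid > lam_max][-1:]
    eval_grid = np.concatenate([null_reps, active_grid])

    skf = StratifiedKFold(
        n_splits=min(cfg.cv_folds, int(np.bincount(y).min())),
        shuffle=True, random_state=int(rng.integers(2**31)),
    )
    dev = np.zeros(eval_grid.size)
    for tr, te in skf.split(X, y):
        for i, lam in enumerate(eval_grid):
            clf = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (len(tr) * lam), solver="liblinear",
                intercept_scaling=1000.0, max_iter=1000,
            )
            clf.fit(X[tr], y[tr])
            p = np.clip(clf.predict_proba(X[te])[:, 1], 1e-12, 1 - 1e-12)
            dev[i] += -2 * np.sum(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
    best_lam = eval_grid[int(np.argmin(dev))]
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * best_lam), solver="liblinear",
        intercept_scaling=1000.0, max_iter=1000,
    )
    clf.fit(X, y)
    selected = np.flatnonzero(np.abs(np.ravel(clf.coef_)) > 0)
    return SelectorOutput(method="lasso", output_type="subset", G=G, selected=selected)


SELECTORS = {
    "info_gain": info_gain_rank,
    "cfs": cfs_select,
    "svm_rfe": svm_rfe_rank,
    "boruta": boruta_select,
    "vita": vita_select,
    "lasso": lasso_select,
}


def run_selector(name: str, X, y, cfg: SelectorConfig | None = None, seed: int | None = None) -> SelectorOutput:
    """Dispatch a base selector by name."""
    if name not in SELECTORS:
        raise KeyError(f"unknown selector {name!r}; known: {sorted(SELECTORS)}")
    return SELECTORS[name](X, y, cfg=cfg, seed=seed)
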