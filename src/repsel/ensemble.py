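"""Ensemble feature selection via permutation-assisted group lasso.

Pipeline: run a roster of base selectors, aggregate their outputs into
best-position ranks, expand the union of their picks with highly correlated
features, partition the candidate set into correlation blocks, then decide
which blocks carry signal by racing them against pseudo-variables.

One permutation round builds the augmented design ``X_A = (X, X_pi)`` — the
candidate matrix beside a row-permuted copy of itself, which preserves the
between-feature correlation but is independent of the outcome — and fits the
group-lasso path over both the B original and B mirrored pseudo blocks.  With
``R_b = sup{lambda : block b nonzero}`` as the importance of block b, the
benchmark ``T_pi = max over pseudo blocks of R_b`` is the strongest importance
a noise block achieved, and the round selects ``S_pi = {b : R_b > T_pi}``.
Over K independent permutations, blocks selected in at least a fraction tau of
rounds form the final feature set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .aggregation import (
    BlockPartition,
    RankAggregation,
    aggregate_ranks,
    expand_candidates,
    form_blocks,
)
from .base_selectors import SelectorConfig, SelectorOutput, run_selector
from .group_lasso import GroupLassoLogit

__all__ = [
    "EnsembleConfig",
    "EnsembleFeatureSelection",
    "EnsembleSelectionResults",
    "permutation_select_once",
    "ensemble_select",
    "DEFAULT_BASE_METHODS",
]

#: base-learner roster used throughout the benchmark study
DEFAULT_BASE_METHODS = ("info_gain", "svm_rfe", "vita", "boruta")


@dataclass
class EnsembleConfig:
    """Ensemble tunables: correlation threshold, permutation rounds, frequency cut.

    Defaults: within-block |correlation| threshold rho = 0.75, K = 50
    permutation rounds, selection-frequency threshold tau = 0.5.
    """

    rho: float = 0.75
    K: int = 50
    tau: float = 0.5
    base_methods: tuple[str, ...] = DEFAULT_BASE_METHODS
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    selector: SelectorConfig = field(default_factory=SelectorConfig)
    no_base_learners: bool = False
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 < self.tau <= 1:
            raise ValueError("tau must lie in (0, 1]")


def permutation_select_once(
    X: np.ndarray,
    y: np.ndarray,
    partition: BlockPartition,
    seed,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-5,
) -> tuple[set[int], float]:
    """One permutation round: returns (selected block set, benchmark T_pi).

    ``X`` is the candidate matrix (columns ordered like ``partition.candidates``
    members, i.e. ``X_full[:, partition.candidates]``).  The path fit stops as
    soon as the first pseudo block enters — every selection decision is already
    determined at that point, because only original blocks entering at a
    strictly larger lambda can beat the benchmark.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    B = partition.n_blocks
    pi = rng.permutation(n)
    X_aug = np.hstack([X, X[pi]])
    groups = np.concatenate([partition.assignment, partition.assignment + B])
    weights = np.concatenate([partition.weights, partition.weights])
    model = GroupLassoLogit(y, X_aug, groups, group_weights=weights)
    path = model.fit_path(
        n_lambdas=n_lambdas,
        min_ratio=lambda_min_ratio,
        tol=tol,
        stop_at_groups=range(B, 2 * B),
    )
    R = path.entry_lambdas
    t_pi = float(R[B:].max()) if B else 0.0
    selected = {b for b in range(B) if R[b] > t_pi}
    return selected, t_pi


class EnsembleFeatureSelection:
    """Ensemble feature-selection model over a feature matrix and binary labels.

    Parameters
    ----------
    endog : (n,) binary labels
    exog : (n, G) feature matrix
    base_outputs : optional pre-computed base-selector outputs; when omitted the
        configured ``base_methods`` are run at fit time
    config : :class:`EnsembleConfig`
    feature_names : optional column labels carried into the results

    With ``config.no_base_learners`` the rank matrix is constant and the
    candidate set is every feature: the permutation-assisted group lasso then
    acts as a stand-alone selector.
    """

    def __init__(
        self,
        endog,
        exog,
        base_outputs: list[SelectorOutput] | None = None,
        config: EnsembleConfig | None = None,
        feature_names: list[str] | None = None,
    ):
        self.endog = np.asarray(endog).astype(np.int64).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog/exog shape mismatch")
        if len(np.unique(self.endog)) < 2:
            raise ValueError("endog must contain both classes")
        self.config = config or EnsembleConfig()
        self.base_outputs = base_outputs
        self.feature_names = feature_names

    @classmethod
    def from_dataframe(cls, df, label_column: str, config: EnsembleConfig | None = None):
        """Build from a samples x features DataFrame holding the label column."""
        y = df[label_column].to_numpy()
        Xdf = df.drop(columns=[label_column])
        return cls(y, Xdf.to_numpy(dtype=float), config=config,
                   feature_names=list(Xdf.columns))

    # -----------------------------------------------------------------

    def _base_outputs(self, seed_seq: np.random.SeedSequence) -> list[SelectorOutput]:
        outs = []
        children = seed_seq.spawn(len(self.config.base_methods))
        for method, child in zip(self.config.base_methods, children):
            outs.append(
                run_selector(
                    method, self.exog, self.endog,
                    cfg=self.config.selector,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                )
            )
        return outs

    def fit(self, seed: int = 0) -> "EnsembleSelectionResults":
        cfg = self.config
        G = self.exog.shape[1]
        ss = np.random.SeedSequence(seed)
        sel_seq, perm_seq = ss.spawn(2)

        if cfg.no_base_learners:
            outputs = []
            agg = RankAggregation(
                G=G,
                agg_rank=np.ones(G, dtype=np.int64),
                base_selected=np.arange(G),
                candidates=np.arange(G),
                expanded=np.zeros(G, dtype=bool),
            )
        else:
            outputs = self.base_outputs or self._base_outputs(sel_seq)
            agg = aggregate_ranks(outputs)
            if agg.base_selected.size == 0:
                warnings.warn("no base selector picked any feature; empty result")
                return EnsembleSelectionResults(
                    model=self, aggregation=agg, partition=None,
                    iteration_sets=[], t_pi=np.empty(0),
                    block_frequencies=np.empty(0), seed=seed,
                    base_outputs=outputs,
                )
            agg = expand_candidates(agg, self.exog, cfg.rho)

        partition = form_blocks(agg, self.exog, cfg.rho)
        Xc = self.exog[:, partition.candidates]

        perm_children = perm_seq.spawn(cfg.K)

        def one(child):
            return permutation_select_once(
                Xc, self.endog, partition, child,
                n_lambdas=cfg.n_lambdas, lambda_min_ratio=cfg.lambda_min_ratio,
            )

        if cfg.n_jobs != 1:
            results = Parallel(n_jobs=cfg.n_jobs)(delayed(one)(c) for c in perm_children)
        else:
            results = [one(c) for c in perm_children]

        iteration_sets = [s for s, _ in results]
        t_pi = np.array([t for _, t in results])
        freq = np.zeros(partition.n_blocks)
        for s in iteration_sets:
            for b in s:
                freq[b] += 1
        freq /= cfg.K
        return EnsembleSelectionResults(
            model=self,
            aggregation=agg,
            partition=partition,
            iteration_sets=iteration_sets,
            t_pi=t_pi,
            block_frequencies=freq,
            seed=seed,
            base_outputs=outputs,
        )


@dataclass
class EnsembleSelectionResults:
    """Per-block selection frequencies over K permutation rounds + the final set."""

    model: EnsembleFeatureSelection
    aggregation: RankAggregation
    partition: BlockPartition | None
    iteration_sets: list[set[int]]
    t_pi: np.ndarray  # (K,) per-round benchmarks
    block_frequencies: np.ndarray  # (B,)
    seed: int
    base_outputs: list[SelectorOutput] = field(default_factory=list)

    @property
    def selected_blocks(self) -> np.ndarray:
        """Blocks whose selection frequency reaches tau (inclusive)."""
        if self.partition is None:
            return np.empty(0, dtype=np.int64)
        return np.flatnonzero(self.block_frequencies >= self.model.config.tau)

    @property
    def selected_features(self) -> np.ndarray:
        """Sorted feature indices belonging to the selected blocks."""
        if self.partition is None:
            return np.empty(0, dtype=np.int64)
        feats = [self.partition.members(b) for b in self.selected_blocks]
        if not feats:
            return np.empty(0, dtype=np.int64)
        return np.sort(np.concatenate(feats))

    @property
    def selected_feature_names(self) -> list[str]:
        names = self.model.feature_names
        idx = self.selected_features
        return [names[i] if names else str(i) for i in idx]

    def to_dict(self) -> dict:
        cfg = self.model.config
        part = self.partition
        return {
            "config": {
                "rho": cfg.rho, "K": cfg.K, "tau": cfg.tau,
                "base_methods": list(cfg.base_methods),
                "no_base_learners": cfg.no_base_learners,
            },
            "seed": self.seed,
            "candidates": [] if part is None else part.candidates.tolist(),
            "blocks": []
            if part is None
            else [part.members(b).tolist() for b in range(part.n_blocks)],
            "block_frequencies": self.block_frequencies.tolist(),
            "t_pi": self.t_pi.tolist(),
            "selected_blocks": self.selected_blocks.tolist(),
            "selected_features": self.selected_features.tolist(),
            "selected_feature_names": self.selected_feature_names,
        }

    def summary(self) -> str:
        cfg = self.model.config
        part = self.partition
        lines = [
            "Ensemble feature selection (permutation-assisted group lasso)",
            f"  rho={cfg.rho}  K={cfg.K}  tau={cfg.tau}  seed={self.seed}",
            f"  base learners: {', '.join(cfg.base_methods) if not cfg.no_base_learners else '(none; constant ranks)'}",
        ]
        if part is None:
            lines.append("  empty candidate set: nothing selected")
            return "\n".join(lines)
        lines.append(
            f"  candidates: {part.p} features in {part.n_blocks} blocks"
        )
        lines.append(f"  mean per-round benchmark T_pi: {self.t_pi.mean():.4g}")
        lines.append("  block  size  freq  selected  members")
        names = self.model.feature_names
        order = np.argsort(-self.block_frequencies, kind="stable")
        for b in order:
            mem = part.members(int(b))
            label = ",".join(names[i] for i in mem) if names else ",".join(map(str, mem))
            if len(label) > 48:
                label = label[:45] + "..."
            mark = "*" if self.block_frequencies[b] >= cfg.tau else ""
            lines.append(
                f"  {b:5d}  {mem.size:4d}  {self.block_frequencies[b]:.2f}  {mark:^8}  {label}"
            )
        return "\n".join(lines)


def ensemble_select(
    X,
    y,
    base_outputs: list[SelectorOutput] | None = None,
    config: EnsembleConfig | None = None,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> EnsembleSelectionResults:
    """Convenience wrapper: build the model and fit in one call."""
    model = EnsembleFeatureSelection(
        y, X, base_outputs=base_outputs, config=config, feature_names=feature_names
    )
    return model.fit(seed=seed)
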