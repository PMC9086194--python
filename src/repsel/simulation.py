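"""Synthetic benchmark data with grouped, correlated predictors and a logistic outcome.

The generator emulates a high-dimensional gene-expression-like design in which a
handful of latent "base" signals drive both the binary outcome and small groups of
observable, mutually correlated features.  Six latent base variables
``x_1 .. x_6 ~ iid Uniform(0, 1)`` are drawn per subject; the outcome follows

    logit P(Y = 1) = beta_0 + beta_1 x_1 + beta_2 x_2 + beta_3 x_3,

so only the first three base variables are causal.  Each base variable spawns a
group of observable proxies

    v_i(j) = x_i + (0.01 + 0.5 (j - 1) / (g_i - 1)) * eps,   eps ~ Normal(0, sd 0.3),

with fresh noise for every entry, so the correlation between x_i and v_i(j)
decays as j increases.  The remaining ``G - sum(g_i)`` features are independent
Uniform(0, 1) distractors.  The latent x_i themselves are withheld from the
feature matrix: the 30 proxies of x_1..x_3 are the causal features a selector
should recover, the 30 proxies of x_4..x_6 are correlated decoys, and the rest
is noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimulationScenario",
    "SimulatedDataset",
    "scenario_registry",
    "get_scenario",
    "simulate_dataset",
    "make_replicate_pairs",
    "marginal_prevalence",
]

#: per-group sizes g_1..g_6 used by every registered scenario
DEFAULT_GROUP_SIZES = (10, 10, 10, 10, 10, 10)

#: standard deviation of the proxy noise eps
NOISE_SD = 0.3


@dataclass(frozen=True)
class SimulationScenario:
    """One benchmark condition: sample size, dimension, prevalence and effect sizes."""

    label: str
    n: int
    G: int
    prevalence: float
    beta: tuple[float, float, float, float]  # (beta0, beta1, beta2, beta3)
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    noise_sd: float = NOISE_SD
    seed: int | None = None

    @property
    def n_causal(self) -> int:
        return int(sum(self.group_sizes[:3]))

    @property
    def sparsity(self) -> float:
        return self.n_causal / self.G

    def __post_init__(self) -> None:
        if any(g < 2 for g in self.group_sizes):
            raise ValueError(
                "group sizes must be >= 2: the proxy-noise coefficient divides "
                f"by (g_i - 1); got {self.group_sizes}"
            )
        if sum(self.group_sizes) > self.G:
            raise ValueError("sum of group sizes exceeds total feature count G")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass
class SimulatedDataset:
    """A drawn feature matrix + outcome, with causal bookkeeping retained."""

    X: np.ndarray  # (n, G)
    y: np.ndarray  # (n,) of {0, 1}
    causal: np.ndarray  # (G,) bool
    group_labels: np.ndarray  # (G,) int; 1..6 for proxy groups, 0 for distractors
    feature_names: list[str]
    base_variables: np.ndarray  # (n, 6) latent x_i, diagnostics only
    scenario: SimulationScenario
    seed: int | None = None

    @property
    def causal_indices(self) -> np.ndarray:
        return np.flatnonzero(self.causal)


def _registry_rows() -> list[SimulationScenario]:
    rows = []
    for n in (50, 100):
        for G in (600, 1200):
            rows.append(
                SimulationScenario(
                    label=f"n{n}_G{G}_eta0.5",
                    n=n, G=G, prevalence=0.5, beta=(0.0, -9.0, 6.0, 3.0),
                )
            )
    for n in (50, 100):
        for G in (600, 1200):
            rows.append(
                SimulationScenario(
                    label=f"n{n}_G{G}_eta0.25",
                    n=n, G=G, prevalence=0.25, beta=(0.0, -14.0, 12.0, -6.0),
                )
            )
    return rows


def scenario_registry() -> dict[str, SimulationScenario]:
    """The eight benchmark scenarios, keyed by label.

    Prevalence 0.5 scenarios use effects (-9, 6, 3); prevalence 0.25 scenarios
    use (-14, 12, -6).  The intercept is 0 throughout: by symmetry of the
    linear predictor the first family has marginal prevalence exactly 0.5, and
    Monte Carlo puts the second near 0.26.
    """
    return {sc.label: sc for sc in _registry_rows()}


def get_scenario(label: str, **overrides) -> SimulationScenario:
    """Look up a registered scenario, optionally overriding fields."""
    reg = scenario_registry()
    if label not in reg:
        raise KeyError(f"unknown scenario {label!r}; known: {sorted(reg)}")
    sc = reg[label]
    return replace(sc, **overrides) if overrides else sc


def _feature_names(sc: SimulationScenario) -> list[str]:
    names = [
        f"v{i + 1}({j + 1})"
        for i, g in enumerate(sc.group_sizes)
        for j in range(g)
    ]
    names += [f"w{k + 1}" for k in range(sc.G - sum(sc.group_sizes))]
    return names


def simulate_dataset(sc: SimulationScenario, seed: int | None = None) -> SimulatedDataset:
    """Draw one dataset under scenario ``sc``.

    Columns are ordered proxy groups first (v1(1)..v6(g6)) then distractors
    (w1..).  ``seed`` overrides ``sc.seed``; one of the two should be set for
    reproducibility.
    """
    if seed is None:
        seed = sc.seed
    rng = np.random.default_rng(seed)
    n, G = sc.n, sc.G
    n_groups = len(sc.group_sizes)
    base = rng.uniform(size=(n, n_groups))

    cols: list[np.ndarray] = []
    group_labels: list[int] = []
    for i, g in enumerate(sc.group_sizes):
        j = np.arange(g)
        scale = 0.01 + 0.5 * j / (g - 1)  # (g,)
        eps = rng.normal(scale=sc.noise_sd, size=(n, g))
        cols.append(base[:, [i]] + scale[None, :] * eps)
        group_labels += [i + 1] * g
    n_noise = G - sum(sc.group_sizes)
    cols.append(rng.uniform(size=(n, n_noise)))
    group_labels += [0] * n_noise
    X = np.concatenate(cols, axis=1)

    beta0, b1, b2, b3 = sc.beta
    eta = beta0 + base[:, :3] @ np.array([b1, b2, b3])
    y = (rng.uniform(size=n) < _sigmoid(eta)).astype(np.int64)

    causal = np.zeros(G, dtype=bool)
    causal[: sc.n_causal] = True
    return SimulatedDataset(
        X=X,
        y=y,
        causal=causal,
        group_labels=np.asarray(group_labels),
        feature_names=_feature_names(sc),
        base_variables=base,
        scenario=sc,
        seed=seed,
    )


def make_replicate_pairs(
    sc: SimulationScenario, n_pairs: int, master_seed: int
) -> list[tuple[SimulatedDataset, SimulatedDataset]]:
    """Independent (train, test) dataset pairs with per-pair derived seeds.

    The first member of each pair is meant for feature selection / training, the
    second for stability and prediction assessment.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(2 * n_pairs)
    pairs = []
    for k in range(n_pairs):
        a = simulate_dataset(sc, seed=children[2 * k])
        b = simulate_dataset(sc, seed=children[2 * k + 1])
        pairs.append((a, b))
    return pairs


def marginal_prevalence(
    beta: tuple[float, float, float, float], n_draws: int = 200_000, seed: int = 0
) -> float:
    """Monte Carlo estimate of P(Y = 1) under the logistic model on uniform bases."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(size=(n_draws, 3))
    beta0, b1, b2, b3 = beta
    return float(np.mean(_sigmoid(beta0 + x @ np.array([b1, b2, b3]))))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
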